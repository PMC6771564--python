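# Methods

## Ergodic age distribution and the marker-window estimator

The population model is an exponentially growing, non-interacting culture in
which every cell divides into two at the end of a unit cell cycle. At steady
state the cumulative distribution of cell age `x` (progress through the unit
cycle) is `Φ(x) = 2 − 2^(1−x)`, with density `φ(x) = 2 ln2 · 2^(−x)`: births
outpace every older age class, biasing a snapshot toward early stages. Cell
death and arrest are assumed negligible.

A flagella-connector-remnant marker sits on exactly one of the two daughters
of each division and is removed within a window `w` after cytokinesis. Cells
younger than `w` form a fraction `Φ(w)` of the population, and half of them
carry any given remnant, so a count of `n` marked cells among `N` total
implies an effective cumulative fraction `F = (2/daughters_marked) · n/N`
and

    w = (1 − log2(2 − F)) · T_unit.

The factor 2 is exposed as `daughters_marked` because it is the estimator's
key structural assumption; it is validated in-package by the simulation
oracle (a population with one marked daughter per division, generated by
`synth`, returns the generating window within binomial error). The
denominator `N` is the all-category count: the ergodic mapping is defined
over the whole population, not over 1F1K1N cells alone.

Defaults: stage boundaries 0.596 / 0.852 / 0.942 u (second flagellum,
kinetoplast division, mitosis) and `T_unit` = 8.9 h, the standard procyclic
culture values. Windows are reported both raw and rounded to the nearest
minute. A window larger than the 1F1K1N span (0.596 u) triggers a warning
rather than an error: the estimate is still defined, but the assumption that
marked cells are 1F1K1N no longer holds. Confidence intervals propagate a
95% Wilson interval on `n/N` through the (monotone) inversion.

The observed 1F1K1N share of a real snapshot need not match `Φ(b_2f)`
(boundaries come from independent datasets); the package treats the
boundaries as given constants and does not reconcile the two.

## Label-inheritance simulation

Agents carry progress `u ∈ [0, 1)`, an old-flagellum label (full / partial /
unlabelled), a new-flagellum label (none below `b_2f`), and an inheritance
flag (OFD / NFD). Defaults follow the study conditions: 10,000 agents,
step 0.01 u, reports every 0.05 u, RNAi induction effective at 0.3 u,
duration 1.8 u. Initial ages are drawn from `Φ` by inverse-CDF sampling;
initial inheritance flags are 50/50 at random (the steady state of a process
producing one of each per division; an alternating assignment is available).

Per step, each agent advances by the increment of its inheritance class
(0.01 u, or 0.009 u for a class progressing "10% slower" — implemented
literally as the stated increment, an 11.1% longer cycle after step
quantisation). An agent crossing `b_2f` starts a new flagellum: fully
labelled before induction, unlabelled after. At the single step containing
the induction time, every new flagellum in cells beyond `b_2f` becomes
partially labelled. At `u ≥ 1` the agent divides: the original slot keeps
the old flagellum with progress reset to exactly 0 (overshoot up to one
increment is discarded — a known quantisation), and a new agent inherits the
parent's new-flagellum label as its old flagellum. One seeded generator
drives the whole run; identical seeds give bit-identical reports.

### Plateau readout

The readout is the fully-labelled share of the 1K1N pool (1F1K1N + 2F1K1N
pooled, because experimental categorisation uses kinetoplast/nucleus counts
only). After induction the number of fully-labelled old flagella is
constant — every division of a fully-labelled cell yields exactly one
fully-labelled OFD — while the population keeps doubling, so the share
declines overall. But there is an exactly flat stretch: once every lineage
present at induction has divided exactly once and no lineage has divided
twice (roughly `b_2k` to 1.0 u post-induction under equal rates), each
division has contributed one fully-labelled and one affected cell at
identical progress, making the pooled 1K1N counts *exactly* equal — the 50%
plateau. After that, second-generation affected daughters dilute the pool
and the share falls again.

`plateau_fraction` therefore detects the plateau as the flattest stretch of
consecutive reports (default width 0.15 u, searched from 0.8 u
post-induction, minimising max−min), rather than fixing a time window;
an explicit window remains available for comparisons against experimental
time courses, whose plateau appears later than the model's because real
RNAi takes effect gradually rather than at a sharp induction time.

With a 10% rate difference the plateau splits by about ±2 pp. Direction: a
slower daughter class spends more real time traversing the fixed 1K1N
progress span `[0, b_2k)` and is therefore *over-represented* in the 1K1N
pool; with slower NFDs the affected (NFD-side) share at the plateau is ~52%
and the fully-labelled share ~48%, and the mirrored scenario reverses the
proportions. The magnitude, not the sign, is the assay's sensitivity
measure: an observed plateau at 50% excludes rate differences of this size.

Not modelled: axonemal defects from the knock-down itself, gradual protein
depletion (only the single effective induction time), and cell death.

## Cohort morphometrics

1F1K1N cells are classified NFD (tip remnant), OFD (mid-flagellum remnant)
or no-FCR (neither); other F/K/N configurations are left unclassified. A
1F1K1N record with both markers is rejected as a data error. Summaries are
mean ± sample s.d. (n−1), missing values excluded per parameter; marker
tallies are printed as half-up percentages with one decimal.

The two-sample test defaults to Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom — the printed anterior-angle spreads
(9.3° vs 3.0°) make the pooled-variance assumption untenable — with
Student's pooled test as an option. No multiple-testing correction is
applied; each parameter is reported at its own P < 0.05, and the per-test
size is verified by a 1000-replicate null calibration in the suite.

## Mesh caliber

The anterior caliber is measured by walking a given on-surface polyline
(the contour along the flagellum-attachment side, supplied by the user or
the tube generator — the azimuth of that contour is an input, not inferred)
to 2 µm arclength, then expanding a sphere at that point until it reaches
the opposite wall. Implementation: one ray cast from the point along the
inward surface normal; the first hit farther than an exclusion radius
(default 300 nm, masking the local wall) is the caliber. On a cylinder or
sphere of radius R this gives exactly 2R; on a cone of slope `k` it gives
`2r(1 + O(k²))`, within 0.2% for the tapers used here. A tangency
fixed-point refinement (re-aiming the ray along the hit normal) was
evaluated and rejected: it is unstable on concave-inward surfaces, where the
angular error doubles per iteration. Non-watertight meshes are rejected, not
repaired; the measurement is invariant under rigid motion by construction.

The quantity returned is the sphere radius, i.e. the chord to the opposite
wall, which equals the local diameter on a tube; it is called "caliber" to
avoid the radius/diameter ambiguity.

## Synthetic generators

Snapshots: ages from `Φ` by inverse CDF; each cell is an NFD or OFD of its
last division with probability ½; markers set while age is inside the
respective window (sharp cutoff — real remnant removal is likely gradual, so
a detection-sensitivity decay is deliberately not modelled); measurements
from cohort-specific Gaussians truncated at zero, independent across
parameters (no covariance is published; an optional flagellum–FAZ
correlation exists for robustness checks), free flagellum clipped to the
flagellum length. Default windows 0.063 / 0.020 u reproduce the expected
22 / 7 marked cells in a 515-cell sample. Means for anterior angle
(29.5 ± 9.3° NFD vs 12.3 ± 3.0° OFD), FAZ (13.2 vs 17.2 µm) and flagellum
(20.1 vs 22.8 µm) are study text values; the remaining means and all s.d.s
are fixture choices that reproduce the qualitative cohort ordering (NFD
shorter flagellum / cell body / FAZ / kinetoplast–nucleus distance, longer
free flagellum). Passing tests on these data show the pipeline recovers
what the generator encodes; they do not validate the measurement process or
the published effect sizes themselves.

Time courses subsample the simulator's per-report counts without replacement
(multivariate hypergeometric, 500 cells by default) to emulate observer
counting noise.

Tube meshes are watertight surfaces of revolution with capped ends and a
meridian path from the tip; the analytic profile is retained so tests can
compare measured against expected calibers. The `nfd_like` / `ofd_like`
presets are synthetic fixtures whose 2 µm calibers sit near 908 and 403 nm,
the blunt and tapered anterior ends.

## Problem sizes and numerical choices

The suite runs simulations at 1,000–10,000 agents and snapshots up to
100,000 cells; the acceptance script uses the full 10,000-agent study
condition. Mesh fixtures use 64–96 azimuthal segments, where tessellation
error on the caliber is below 0.15%. Report times are step-exact multiples
of the report interval; stage boundaries are compared strictly (`<`), and
induction applies at the first step whose end time reaches the induction
time. Percentages are rounded half-up (not banker's) to match conventional
reporting.

## Known limitations

* The simulation's plateau is transient (exact only until second-generation
  divisions); the detector finds it reliably under the default scenarios but
  very short durations or coarse report intervals can leave too few points.
* The caliber ray method assumes the opposite wall is roughly parallel to
  the local wall (true for tubular cells); it will underestimate calibers at
  strongly kinked geometries.
* The ergodic estimator assumes sharp marker loss; gradual loss would make
  the estimate detection-sensitivity dependent.
* Morphometric synthetic data are independent Gaussians per cohort; real
  measurements are correlated within cells.
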