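# trypocycle

Cell-cycle timing and daughter-cell asymmetry analysis for *Trypanosoma
brucei* populations.

A proliferative division of a procyclic trypanosome produces two daughters
that look alike but are not equivalent: one inherits the flagellum built in
the current cycle (the new-flagellum daughter, NFD), the other a flagellum
built in an earlier cycle (the old-flagellum daughter, OFD). Severing of the
flagella connector at cytokinesis leaves a short-lived remnant on each
daughter — at the new flagellum's tip on the NFD and halfway along the old
flagellum on the OFD — so the two can be told apart for a brief window after
birth. This package implements the quantitative machinery for studying that
asymmetry from microscopy-style data:

* **Ergodic timing** (`trypocycle.ergodic`). In an exponentially growing
  binary-fission culture the cumulative age distribution is
  `Φ(x) = 2 − 2^(1−x)` over the unit cell cycle. A marker carried by one
  daughter per division and seen on `n` of `N` counted cells therefore
  persists for

      w = (1 − log2(2 − 2 n/N)) · T_unit

  after cytokinesis (`T_unit` = 8.9 h here). `MarkerWindowModel.fit()`
  returns the window with a propagated binomial confidence interval.
* **Label-inheritance simulation** (`trypocycle.simulate`). An agent-based
  model of an RNAi knock-down of an eYFP-tagged axonemal protein: flagella
  built before induction stay fully labelled, those under construction end
  up partially labelled, later ones unlabelled. Tracking the fully-labelled
  share of 1K1N cells gives a readout that plateaus at exactly 50% when both
  daughter classes cycle at the same rate, and shifts off 50% when they do
  not — a population-level assay for G1-duration differences.
* **Cohort morphometrics** (`trypocycle.cohorts`). Classification of 1F1K1N
  cells into NFD / OFD / no-remnant cohorts and Welch (or Student) t-test
  comparison of flagellum, cell body, FAZ, kinetoplast spacing and
  anterior-angle measurements.
* **Mesh calibers** (`trypocycle.meshes`). The anterior-taper readout from
  volume-EM surface meshes: walk 2 µm from the anterior tip along an
  on-surface contour, then measure the cross-cell caliber by sphere
  expansion.
* **Synthetic data** (`trypocycle.synth`). Generators for population
  snapshots with the ergodic age structure, subsampled labelling time
  courses, and analytic tapered-tube meshes, so the full pipeline runs and
  is testable without any imaging data.

## Worked example

Convert snapshot counts into marker-persistence windows — 22 of 515 counted
cells carried the new-flagellum tip remnant:

```pycon
>>> from trypocycle import MarkerWindowModel
>>> res = MarkerWindowModel.from_counts("mAb62", 22, 515).fit()
>>> print(res.summary())
Ergodic marker-persistence windows
  unit cycle: 8.9 h; 1F1K1N span: 0.596 u

marker        marked   total   F_eff    w (u)   w (min)  ~min      95% CI (min)
mAb62             22     515  0.0854   0.0630     33.63    34      (22.2, 50.8)
```

The tip remnant is visible for ~34 minutes after cytokinesis (the same
computation with 7 marked cells gives ~11 minutes for the mid-flagellum
remnant): newly born NFDs and OFDs can only be identified within the first
few percent of the cell cycle.

Simulate the RNAi labelling assay and read the plateau:

```sh
$ trypocycle simulate-labelling --scenario equal --n-cells 10000 --seed 1 --out report.csv
plateau (post-induction 0.85-1.00 u): 49.9% fully labelled / 50.1% partially-or-unlabelled of 1K1N cells
```

Equal cycle rates for the two daughter classes put the plateau at 50%; with
`--scenario nfd-slow` (new-flagellum daughters progressing 10% slower) the
plateau splits roughly 48% fully labelled / 52% affected, and
`--scenario ofd-slow` reverses the split — so a measured plateau at 50%
indicates equal G1 durations.

The other subcommands follow the same pattern: `trypocycle cohort-stats`,
`trypocycle measure-caliber`, and the `trypocycle synth ...` generators.
Every run writes a JSON sidecar with its resolved configuration and seed.

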