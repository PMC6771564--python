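"""Synthetic data with the statistical structure the analyses assume.

Every downstream module can be exercised without microscopy data:

* population *snapshots* — cell records with the ergodic age structure of an
  exponentially growing binary-fission culture, short-lived daughter markers
  on exactly one daughter per division, and cohort-specific morphometric
  distributions;
* labelling *time courses* — simulator output subsampled to a fixed number
  of cells per timepoint, emulating observer counting noise;
* analytic *tapered tubes* — watertight surfaces of revolution with a known
  radius profile, standing in for segmented cell-surface meshes.

Cohort measurement means follow the study values where these exist in text
(anterior angle 29.5 +/- 9.3 deg for new-flagellum daughters vs 12.3 +/- 3.0
for old-flagellum daughters; FAZ 13.2 vs 17.2 um; flagellum 20.1 vs 22.8 um);
the remaining means and all standard deviations are fixture choices that
reproduce the qualitative cohort ordering, not measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ergodic import (
    CellCycleMap,
    MarkerCountTable,
    age_cdf,
    marker_window,
    sample_progress,
)
from .meshes import AnteriorPath
from .simulate import STAGES, SimScenario, SimulationReport, run as run_simulation

__all__ = [
    "COHORT_MEASUREMENT_PARAMS",
    "SnapshotSpec",
    "generate_snapshot",
    "recover_windows",
    "generate_timecourse",
    "TaperedTube",
    "generate_tapered_tube",
    "linear_profile_through",
    "nfd_like_tube",
    "ofd_like_tube",
]

#: (mean, sd) per measurement column per cohort.  Angle / FAZ / flagellum
#: means are study text values; everything else is a fixture choice.
COHORT_MEASUREMENT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "flagellum_um": {"NFD": (20.1, 1.5), "OFD": (22.8, 1.5), "NO_FCR": (22.9, 1.5)},
    "cell_body_um": {"NFD": (15.5, 1.5), "OFD": (20.3, 1.5), "NO_FCR": (20.5, 1.5)},
    "faz_um": {"NFD": (13.2, 1.5), "OFD": (17.2, 1.5), "NO_FCR": (17.3, 1.5)},
    "kn_dist_um": {"NFD": (4.0, 0.8), "OFD": (5.2, 0.8), "NO_FCR": (5.3, 0.8)},
    "kpost_dist_um": {"NFD": (3.0, 0.8), "OFD": (3.1, 0.8), "NO_FCR": (4.6, 0.8)},
    "free_flagellum_um": {"NFD": (6.9, 1.0), "OFD": (5.6, 1.0), "NO_FCR": (5.6, 1.0)},
    "anterior_angle_deg": {"NFD": (29.5, 9.3), "OFD": (12.3, 3.0), "NO_FCR": (12.5, 3.0)},
}

_STAGE_COUNTS = {
    "1F1K1N": (1, 1, 1),
    "2F1K1N": (2, 1, 1),
    "2F2K1N": (2, 2, 1),
    "2F2K2N": (2, 2, 2),
}


@dataclass(frozen=True)
class SnapshotSpec:
    """Parameters of one synthetic population snapshot.

    ``w_tip_u`` / ``w_mid_u`` are the persistence windows (in cycle units) of
    the tip marker on new-flagellum newborns and the mid-flagellum marker on
    old-flagellum newborns; each newborn is one or the other with equal
    probability, so the expected marked fraction of the whole population is
    ``Phi(w) / 2`` per marker.  The defaults (0.063 and 0.020 u at the 8.9 h
    unit cycle, i.e. ~34 and ~11 min) give expected counts matching a
    515-cell sample with 22 tip-marked and 7 mid-marked cells.
    """

    n_cells: int = 515
    cycle_map: CellCycleMap = field(default_factory=CellCycleMap)
    w_tip_u: float = 0.063
    w_mid_u: float = 0.020
    measurement_params: dict = field(
        default_factory=lambda: COHORT_MEASUREMENT_PARAMS
    )
    missing_rate: float = 0.0
    faz_flagellum_corr: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("w_tip_u", "w_mid_u"):
            w = getattr(self, name)
            if not (0.0 <= w < self.cycle_map.b_2f):
                raise ValueError(f"{name} must lie in [0, b_2f)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (-1.0 < self.faz_flagellum_corr < 1.0):
            raise ValueError("faz_flagellum_corr must lie in (-1, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _truncated_normal(mean, sd, size, rng):
    # Truncated at zero; with the default parameters the truncation is nominal.
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_snapshot(spec: SnapshotSpec) -> pd.DataFrame:
    """Generate a cell-record table for one asynchronous-culture snapshot.

    Ages are drawn by inverse-CDF sampling of the ergodic age distribution;
    the F/K/N configuration follows the stage boundaries; each cell is a
    new- or old-flagellum daughter of its last division with probability 1/2
    and carries the corresponding marker while younger than its window.
    Measurements are drawn from cohort-appropriate truncated-at-zero
    Gaussians, with the free flagellum clipped to the flagellum length.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    cm = spec.cycle_map

    age = sample_progress(n, rng)
    stage = cm.stage_of(age)
    counts = np.array([_STAGE_COUNTS[s] for s in np.atleast_1d(stage)])
    is_nfd_side = rng.random(n) < 0.5
    tip = is_nfd_side & (age < spec.w_tip_u)
    mid = ~is_nfd_side & (age < spec.w_mid_u)

    cohort = np.where(tip, "NFD", np.where(mid, "OFD", "NO_FCR"))
    df = pd.DataFrame(
        dict(
            cell_id=[f"cell{i:06d}" for i in range(n)],
            n_flagella=counts[:, 0],
            n_kinetoplasts=counts[:, 1],
            n_nuclei=counts[:, 2],
            tip_marker=tip.astype(int),
            mid_marker=mid.astype(int),
        )
    )

    measurements = {}
    if spec.faz_flagellum_corr != 0.0:
        rho = spec.faz_flagellum_corr
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        z_flag, z_faz = z[:, 0], z[:, 1]
    for col, per_cohort in spec.measurement_params.items():
        vals = np.empty(n)
        for cname in ("NFD", "OFD", "NO_FCR"):
            mask = cohort == cname
            if not mask.any():
                continue
            mean, sd = per_cohort[cname]
            if spec.faz_flagellum_corr != 0.0 and col in ("flagellum_um", "faz_um"):
                zz = z_flag if col == "flagellum_um" else z_faz
                vals[mask] = np.clip(mean + sd * zz[mask], 1e-6, None)
            else:
                vals[mask] = _truncated_normal(mean, sd, int(mask.sum()), rng)
        measurements[col] = vals
    measurements["free_flagellum_um"] = np.minimum(
        measurements["free_flagellum_um"], measurements["flagellum_um"]
    )
    for col, vals in measurements.items():
        df[col] = vals

    if spec.missing_rate > 0:
        for col in measurements:
            df.loc[rng.random(n) < spec.missing_rate, col] = np.nan

    df["cohort"] = np.where(
        np.array([s != "1F1K1N" for s in np.atleast_1d(stage)]),
        "NOT_1F1K1N",
        cohort,
    )
    df["age_u"] = age  # generator-side truth, handy for validation
    return df


def recover_windows(
    table: pd.DataFrame, cycle_map: CellCycleMap | None = None
) -> tuple[float, float]:
    """Re-estimate (w_tip, w_mid) in cycle units from a snapshot table.

    Wires the snapshot counts back through the ergodic marker-window
    estimator (one marked daughter per division).  Returns 0 with a warning
    for a marker with no positive cells.
    """
    cycle_map = cycle_map or CellCycleMap()
    n_total = len(table)
    out = []
    for col, name in (("tip_marker", "tip"), ("mid_marker", "mid")):
        n_marked = int(table[col].astype(bool).sum())
        if n_marked == 0:
            warnings.warn(f"no {name}-marked cells: window estimate is 0",
                          UserWarning, stacklevel=2)
            out.append(0.0)
            continue
        w_min = marker_window(
            MarkerCountTable(name, n_marked, n_total, daughters_marked=1), cycle_map
        )
        out.append(w_min / (cycle_map.t_unit_hours * 60.0))
    return tuple(out)


def generate_timecourse(
    scenario: SimScenario,
    cycle_map: CellCycleMap | None = None,
    sample_size: int = 500,
    timepoints: list[float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a labelling time course and count a fixed subsample per timepoint.

    Emulates the experimental readout in which a fixed number of cells
    (500 by default) is categorised at each timepoint: the simulator's
    stage x label-class counts are subsampled without replacement
    (multivariate hypergeometric draw).  ``sample_size`` equal to the
    population size returns the exact simulator tallies.
    """
    cycle_map = cycle_map or CellCycleMap()
    rng = np.random.default_rng(seed)
    report = run_simulation(scenario, cycle_map, seed=seed)
    counts = report.counts
    times = counts["time_u"].unique() if timepoints is None else timepoints
    rows = []
    for t in times:
        at_t = counts[np.isclose(counts["time_u"], t)]
        if at_t.empty:
            raise ValueError(f"timepoint {t} not covered by the simulation")
        vec = at_t["count"].to_numpy()
        pop = int(vec.sum())
        if sample_size > pop:
            raise ValueError(
                f"sample_size {sample_size} exceeds population {pop} at t={t}"
            )
        sampled = (
            vec if sample_size == pop
            else rng.multivariate_hypergeometric(vec, sample_size)
        )
        for (_, r), c in zip(at_t.iterrows(), sampled):
            rows.append(
                dict(time_u=t, stage=r["stage"],
                     old_label_class=r["old_label_class"], count=int(c))
            )
    return pd.DataFrame(rows, columns=["time_u", "stage", "old_label_class", "count"])


# --------------------------------------------------------------------------
# Analytic tapered-tube meshes
# --------------------------------------------------------------------------


@dataclass
class TaperedTube:
    """Surface-of-revolution mesh with a known radius profile.

    ``mesh`` is watertight with outward normals; ``path`` runs from the
    anterior tip along the theta = 0 meridian.  ``expected_caliber_at(s)``
    returns the analytic local diameter ``2 r(z(s))`` for comparison with
    the mesh-based measurement.
    """

    mesh: "trimesh.Trimesh"
    path: AnteriorPath
    profile: callable
    _path_z: np.ndarray

    def expected_caliber_at(self, s: float) -> float:
        cum = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(self.path.points, axis=0), axis=1))]
        )
        z = float(np.interp(s, cum, self._path_z))
        return 2.0 * float(self.profile(z))


def generate_tapered_tube(
    radius_profile,
    length: float = 8000.0,
    n_z: int = 160,
    n_theta: int = 64,
) -> TaperedTube:
    """Build a watertight tapered tube (nm) plus its anterior path.

    ``radius_profile(z)`` must be positive on (0, length]; the anterior end
    (z = 0) is closed with a flat cap (or an apex vertex if the profile
    starts at zero radius), and the path walks from the tip across the cap
    and down the meridian.
    """
    import trimesh

    zs = np.linspace(0.0, length, n_z + 1)
    rs = np.asarray([float(radius_profile(z)) for z in zs])
    if np.any(rs[1:] <= 0):
        raise ValueError("radius profile must be positive on (0, length]")
    if rs[0] < 0:
        raise ValueError("radius at the tip must be >= 0")

    pointed = rs[0] < 1e-9
    ring_start = 1 if pointed else 0
    rings = []
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    verts = [np.array([0.0, 0.0, 0.0])] if pointed else [np.array([0.0, 0.0, 0.0])]
    # vertex 0 is the anterior apex/cap centre in both cases
    ring_index = {}
    for i in range(ring_start, n_z + 1):
        ring_index[i] = len(verts)
        for th in theta:
            verts.append(np.array([rs[i] * np.cos(th), rs[i] * np.sin(th), zs[i]]))
    posterior_centre = len(verts)
    verts.append(np.array([0.0, 0.0, length]))

    faces = []
    first = ring_index[ring_start]
    for k in range(n_theta):
        kn = (k + 1) % n_theta
        faces.append([0, first + kn, first + k])  # anterior cap / apex fan
    for i in range(ring_start, n_z):
        a, b = ring_index[i], ring_index[i + 1]
        for k in range(n_theta):
            kn = (k + 1) % n_theta
            faces.append([a + k, a + kn, b + k])
            faces.append([a + kn, b + kn, b + k])
    last = ring_index[n_z]
    for k in range(n_theta):
        kn = (k + 1) % n_theta
        faces.append([posterior_centre, last + k, last + kn])

    mesh = trimesh.Trimesh(
        vertices=np.asarray(verts), faces=np.asarray(faces), process=False
    )
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:  # pragma: no cover - construction guarantee
        raise RuntimeError("generated tube mesh is unexpectedly not watertight")

    if pointed:
        path_pts = [np.array([0.0, 0.0, 0.0])]
        path_z = [0.0]
    else:
        path_pts = [np.array([0.0, 0.0, 0.0]), np.array([rs[0], 0.0, 0.0])]
        path_z = [0.0, 0.0]
    for i in range(1, n_z + 1):
        path_pts.append(np.array([rs[i], 0.0, zs[i]]))
        path_z.append(zs[i])
    path = AnteriorPath(np.asarray(path_pts))
    return TaperedTube(mesh, path, radius_profile, np.asarray(path_z))


def linear_profile_through(
    r_tip: float, r_at: float, s_at: float = 2000.0
) -> callable:
    """Linear radius profile hitting ``r_at`` at path arclength ``s_at``.

    Accounts for the cap (arclength ``r_tip``) and the meridian slope when
    converting arclength to axial position.
    """
    slope = (r_at - r_tip) / max(s_at - r_tip, 1e-9)
    for _ in range(8):  # fixed point: z(s_at) depends weakly on the slope
        z_at = (s_at - r_tip) / np.sqrt(1.0 + slope**2)
        slope = (r_at - r_tip) / z_at
    return lambda z: r_tip + slope * z


def nfd_like_tube(**kw) -> TaperedTube:
    """Blunt (non-tapered) anterior end; caliber ~908 nm at 2 um arclength.

    Synthetic fixture emulating the wide anterior of a new-flagellum
    daughter.
    """
    return generate_tapered_tube(linear_profile_through(400.0, 454.0), **kw)


def ofd_like_tube(**kw) -> TaperedTube:
    """Tapered anterior end; caliber ~403 nm at 2 um arclength.

    Synthetic fixture emulating the narrow anterior of an old-flagellum
    daughter.
    """
    return generate_tapered_tube(linear_profile_through(120.0, 201.5), **kw)
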