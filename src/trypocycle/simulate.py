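"""Agent-based simulation of flagellum-label inheritance under RNAi.

Models an RNAi knock-down of an eYFP-tagged axonemal protein in a growing
trypanosome culture.  Each agent carries four properties: progress through
the unit cell cycle, the label state of its (old) flagellum, the label state
of any new flagellum under construction, and which flagellum it inherited in
its previous division.  Flagella built before the RNAi takes effect are fully
labelled; flagella under construction when it takes effect end up partially
labelled; flagella started afterwards are unlabelled.  On division the
original agent keeps the old flagellum and a new agent inherits the new one,
so the label records each cell's inheritance history.

Counting, at intervals, how many cells in each cell-cycle stage still carry a
fully labelled old flagellum yields the population readout used to compare
the cycle durations of the two daughter classes: if both classes progress at
the same rate, the fully-labelled share of the 1K1N pool settles at exactly
50% once every lineage has divided exactly once post-induction (each such
division produces one fully-labelled and one affected 1K1N cell in lockstep);
a rate difference between the classes shifts that plateau.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ergodic import STAGES, CellCycleMap, sample_progress

__all__ = [
    "Label",
    "Inheritance",
    "CellAgent",
    "SimScenario",
    "Population",
    "SimulationReport",
    "LabellingSimulation",
    "classify_stage",
    "init_population",
    "step",
    "divide",
    "run",
    "plateau_fraction",
]


class Label(IntEnum):
    """Flagellum label state. NONE means no new flagellum has formed yet."""

    NONE = 0
    UNLABELLED = 1
    PARTIAL = 2
    FULL = 3


class Inheritance(IntEnum):
    """Which flagellum the cell inherited in its previous division."""

    OFD = 0  # old-flagellum daughter
    NFD = 1  # new-flagellum daughter


#: Report classes for the old flagellum: unaffected vs affected by RNAi.
LABEL_CLASSES = ("full", "affected")


@dataclass
class CellAgent:
    """One simulated cell (scalar view of the vectorised population)."""

    progress: float
    old_label: Label = Label.FULL
    new_label: Label = Label.NONE
    inheritance: Inheritance = Inheritance.OFD

    def __post_init__(self) -> None:
        if not (np.isfinite(self.progress) and self.progress >= 0.0):
            raise ValueError("progress must be a finite non-negative number")


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one labelling-inheritance simulation run.

    Defaults follow the study conditions: 10,000 agents, step 0.01 u,
    effective RNAi induction at 0.3 u, equal per-step increments of 0.01 u,
    reports every 0.05 u.  A "10% slower" daughter class uses an increment of
    0.009 u per step (implemented literally as the stated increment).
    """

    n_agents: int = 10_000
    dt: float = 0.01
    induction_time: float = 0.3
    increment_ofd: float = 0.01
    increment_nfd: float = 0.01
    report_interval: float = 0.05
    duration: float = 1.8
    init_flags: str = "random"  # initial inheritance flags: random | alternating
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("increment_ofd", "increment_nfd"):
            inc = getattr(self, name)
            if not (0 < inc <= self.dt):
                raise ValueError(f"{name} must lie in (0, dt]")
        if self.report_interval <= 0 or self.report_interval % self.dt > 1e-9:
            raise ValueError("report_interval must be a positive multiple of dt")
        if self.duration < self.induction_time + 1.46:
            raise ValueError(
                "duration must cover the post-induction plateau "
                "(>= induction_time + 1.46 u)"
            )
        if self.init_flags not in ("random", "alternating"):
            raise ValueError("init_flags must be 'random' or 'alternating'")

    # Named scenarios used throughout the study.
    @classmethod
    def equal_rates(cls, **kw) -> "SimScenario":
        return cls(increment_ofd=0.01, increment_nfd=0.01, **kw)

    @classmethod
    def nfd_slow(cls, **kw) -> "SimScenario":
        """New-flagellum daughters progress 10% slower (0.009 u per step)."""
        return cls(increment_ofd=0.01, increment_nfd=0.009, **kw)

    @classmethod
    def ofd_slow(cls, **kw) -> "SimScenario":
        """Old-flagellum daughters progress 10% slower (0.009 u per step)."""
        return cls(increment_ofd=0.009, increment_nfd=0.01, **kw)


@dataclass
class Population:
    """Struct-of-arrays container for the simulated agents."""

    progress: np.ndarray
    old_label: np.ndarray
    new_label: np.ndarray
    inheritance: np.ndarray

    @property
    def size(self) -> int:
        return self.progress.size

    def agent(self, i: int) -> CellAgent:
        return CellAgent(
            float(self.progress[i]),
            Label(int(self.old_label[i])),
            Label(int(self.new_label[i])),
            Inheritance(int(self.inheritance[i])),
        )

    def copy(self) -> "Population":
        return Population(
            self.progress.copy(),
            self.old_label.copy(),
            self.new_label.copy(),
            self.inheritance.copy(),
        )


def classify_stage(progress, cycle_map: CellCycleMap):
    """Stage label(s) for progress in [0, 1); strict '<' at each boundary."""
    return cycle_map.stage_of(progress)


def init_population(
    scenario: SimScenario,
    cycle_map: CellCycleMap,
    rng: np.random.Generator | None = None,
) -> Population:
    """Seed a population at t = 0 with the ergodic age structure.

    Progress is drawn by inverse-CDF sampling of the binary-fission age
    distribution; all flagella are fully labelled (a new flagellum exists
    only above ``b_2f``); inheritance flags are assigned 50/50 at random (or
    strictly alternating), the steady state of a process creating one OFD
    and one NFD per division.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    n = scenario.n_agents
    progress = sample_progress(n, rng)
    old_label = np.full(n, int(Label.FULL), dtype=np.int8)
    new_label = np.where(
        progress >= cycle_map.b_2f, int(Label.FULL), int(Label.NONE)
    ).astype(np.int8)
    if scenario.init_flags == "random":
        inheritance = rng.integers(0, 2, n).astype(np.int8)
    else:
        inheritance = (np.arange(n) % 2).astype(np.int8)
    return Population(progress, old_label, new_label, inheritance)


def divide(agent: CellAgent) -> tuple[CellAgent, CellAgent]:
    """Divide one agent into its old- and new-flagellum daughters.

    The OFD keeps the parent's old flagellum with progress reset to 0 and no
    new flagellum; the NFD inherits the parent's new flagellum (with its
    label pattern) as its old flagellum.
    """
    if agent.progress < 1.0:
        raise ValueError("cannot divide an agent with progress < 1")
    if agent.new_label == Label.NONE:
        raise ValueError("cannot divide an agent that never formed a new flagellum")
    ofd = CellAgent(0.0, agent.old_label, Label.NONE, Inheritance.OFD)
    nfd = CellAgent(0.0, agent.new_label, Label.NONE, Inheritance.NFD)
    return ofd, nfd


def step(
    population: Population,
    scenario: SimScenario,
    cycle_map: CellCycleMap,
    t_now: float,
) -> Population:
    """Advance the population by one step starting at time ``t_now``.

    Each agent advances by the increment of its inheritance class.  An agent
    crossing ``b_2f`` starts a new flagellum: fully labelled before
    induction, unlabelled afterwards.  At the single step containing the
    induction time, the new flagellum of every cell beyond ``b_2f`` is
    flagged partially labelled.  Agents reaching progress >= 1 divide.
    """
    eps = 1e-9
    t_end = t_now + scenario.dt
    induced_before = t_now >= scenario.induction_time - eps
    induction_step = (not induced_before) and t_end >= scenario.induction_time - eps

    pop = population
    incr = np.where(
        pop.inheritance == int(Inheritance.OFD),
        scenario.increment_ofd,
        scenario.increment_nfd,
    )
    new_progress = pop.progress + incr
    crossed = (pop.progress < cycle_map.b_2f) & (new_progress >= cycle_map.b_2f)
    crossing_label = int(Label.FULL) if not induced_before else int(Label.UNLABELLED)
    new_label = np.where(crossed, crossing_label, pop.new_label).astype(np.int8)
    progress = new_progress

    if induction_step:
        new_label = np.where(
            progress > cycle_map.b_2f, int(Label.PARTIAL), new_label
        ).astype(np.int8)

    dividing = progress >= 1.0
    if dividing.any():
        if np.any(new_label[dividing] == int(Label.NONE)):  # impossible if b_2f < 1
            raise RuntimeError("agent reached division without a new flagellum")
        nfd_old = new_label[dividing].copy()
        n_div = int(dividing.sum())
        # OFD: the original slot, progress reset, new flagellum cleared.
        progress = progress.copy()
        progress[dividing] = 0.0
        new_label[dividing] = int(Label.NONE)
        inheritance = pop.inheritance.copy()
        inheritance[dividing] = int(Inheritance.OFD)
        # NFD: appended, inheriting the parent's new flagellum label.
        progress = np.concatenate([progress, np.zeros(n_div)])
        old_label = np.concatenate([pop.old_label, nfd_old])
        new_label = np.concatenate([new_label, np.full(n_div, int(Label.NONE), np.int8)])
        inheritance = np.concatenate(
            [inheritance, np.full(n_div, int(Inheritance.NFD), np.int8)]
        )
        return Population(progress, old_label, new_label, inheritance)

    return Population(progress, pop.old_label, new_label, pop.inheritance)


def _tally(population: Population, cycle_map: CellCycleMap, t: float) -> list[dict]:
    stage_idx = np.searchsorted(
        np.array(cycle_map.boundaries), population.progress, side="right"
    )
    full = population.old_label == int(Label.FULL)
    rows = []
    for s, stage in enumerate(STAGES):
        in_stage = stage_idx == s
        rows.append(
            dict(time_u=t, stage=stage, old_label_class="full",
                 count=int((in_stage & full).sum()))
        )
        rows.append(
            dict(time_u=t, stage=stage, old_label_class="affected",
                 count=int((in_stage & ~full).sum()))
        )
    return rows


class SimulationReport:
    """Time course of stage x old-flagellum-class counts from one run.

    ``counts`` is a tidy frame with columns ``time_u``, ``stage``,
    ``old_label_class`` ("full" = unaffected by RNAi, "affected" = partially
    labelled or unlabelled) and ``count``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        scenario: SimScenario,
        cycle_map: CellCycleMap,
        seed: int | None,
    ):
        self.counts = counts
        self.scenario = scenario
        self.cycle_map = cycle_map
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()

    @property
    def times(self) -> np.ndarray:
        return self.counts["time_u"].unique()

    def population_size(self) -> pd.Series:
        """Total population size at each report time."""
        return self.counts.groupby("time_u", sort=True)["count"].sum()

    def full_fraction_1k1n(self) -> pd.Series:
        """Fully-labelled fraction of the 1K1N pool at each report time.

        Experimentally cells are categorised by kinetoplast/nucleus counts
        only, so 1K1N pools the 1F1K1N and 2F1K1N simulation categories.
        """
        k1n1 = self.counts[self.counts["stage"].isin(["1F1K1N", "2F1K1N"])]
        pivot = (
            k1n1.groupby(["time_u", "old_label_class"], sort=True)["count"]
            .sum()
            .unstack("old_label_class")
        )
        return pivot["full"] / (pivot["full"] + pivot["affected"])

    def plateau(self, window: tuple[float, float] | None = None, width: float = 0.15):
        """Plateau of the fully-labelled 1K1N fraction; see :func:`plateau_fraction`."""
        return plateau_fraction(self, window=window, width=width)

    def config(self) -> dict:
        cfg = asdict(self.scenario)
        cfg.update(
            seed=self.seed,
            cycle_map=dict(
                b_2f=self.cycle_map.b_2f,
                b_2k=self.cycle_map.b_2k,
                b_2n=self.cycle_map.b_2n,
                t_unit_hours=self.cycle_map.t_unit_hours,
            ),
        )
        return cfg

    def plot(self, path=None):  # pragma: no cover - exercised manually
        """Quick-look plot of per-class 1K1N proportions over time."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frac = self.full_fraction_1k1n()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(frac.index, 100 * frac.values, label="fully labelled")
        ax.plot(frac.index, 100 * (1 - frac.values), label="partially/unlabelled")
        ax.axvline(self.scenario.induction_time, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("time (cell cycle units)")
        ax.set_ylabel("% of 1K1N cells")
        ax.set_ylim(0, 100)
        ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def run(
    scenario: SimScenario,
    cycle_map: CellCycleMap | None = None,
    seed: int | None = None,
) -> SimulationReport:
    """Run a full simulation and report counts every ``report_interval``.

    The population is reported at t = 0 and every report interval thereafter;
    under equal rates it doubles per unit cycle.  With the same seed the
    report is bit-identical across runs.
    """
    cycle_map = cycle_map or CellCycleMap()
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    pop = init_population(scenario, cycle_map, rng)

    n_steps = int(round(scenario.duration / scenario.dt))
    rep_every = int(round(scenario.report_interval / scenario.dt))
    rows = _tally(pop, cycle_map, 0.0)
    for k in range(n_steps):
        t_now = k * scenario.dt
        pop = step(pop, scenario, cycle_map, t_now)
        if (k + 1) % rep_every == 0:
            rows.extend(_tally(pop, cycle_map, round((k + 1) * scenario.dt, 10)))
    counts = pd.DataFrame(rows, columns=["time_u", "stage", "old_label_class", "count"])
    return SimulationReport(counts, scenario, cycle_map, seed)


class LabellingSimulation:
    """Model-object facade over :func:`run`.

    >>> sim = LabellingSimulation(SimScenario.equal_rates(n_agents=2000))
    >>> report = sim.run(seed=0)
    >>> est = report.plateau()
    >>> abs(est.fraction - 0.5) < 0.02
    True
    """

    def __init__(self, scenario: SimScenario, cycle_map: CellCycleMap | None = None):
        self.scenario = scenario
        self.cycle_map = cycle_map or CellCycleMap()

    def run(self, seed: int | None = None) -> SimulationReport:
        return run(self.scenario, self.cycle_map, seed=seed)


@dataclass(frozen=True)
class PlateauEstimate:
    """Plateau readout: mean fully-labelled 1K1N fraction over a time window."""

    fraction: float
    window_post_induction: tuple[float, float]
    values: tuple[float, ...]

    @property
    def percent_full(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_affected(self) -> float:
        return 100.0 * (1.0 - self.fraction)


def plateau_fraction(
    report: SimulationReport,
    window: tuple[float, float] | None = None,
    width: float = 0.15,
    min_post: float = 0.8,
) -> PlateauEstimate:
    """Plateau of the fully-labelled fraction within the 1K1N pool.

    With an explicit ``window`` (start, end), averages the fraction over all
    report times whose *post-induction* time falls in the closed window.

    With ``window=None`` the plateau is detected: among all stretches of
    consecutive reports spanning ``width`` cycle units that start at least
    ``min_post`` units after induction (the first post-induction division
    wave cannot complete earlier than ``b_2k`` units after induction), the
    flattest stretch (smallest max-min) is chosen and its mean returned.
    The detected plateau is where the equal-rates readout sits at exactly
    50% and rate-difference scenarios show their characteristic split.
    """
    frac = report.full_fraction_1k1n()
    post = frac.index.to_numpy() - report.scenario.induction_time
    values = frac.to_numpy()

    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError("window end must exceed window start")
        sel = (post >= lo - 1e-9) & (post <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"no report times fall in post-induction window {window}")
        chosen = values[sel]
        return PlateauEstimate(float(chosen.mean()), (lo, hi), tuple(chosen))

    n_win = int(round(width / report.scenario.report_interval)) + 1
    eligible = np.flatnonzero(post >= min_post - 1e-9)
    if eligible.size < n_win:
        raise ValueError(
            "report does not extend far enough past induction to detect a plateau"
        )
    best = None
    for i0 in eligible:
        i1 = i0 + n_win
        if i1 > values.size:
            break
        seg = values[i0:i1]
        spread = float(seg.max() - seg.min())
        if best is None or spread < best[0] - 1e-12:
            best = (spread, i0)
    _, i0 = best
    seg = values[i0 : i0 + n_win]
    return PlateauEstimate(
        float(seg.mean()),
        (float(post[i0]), float(post[i0 + n_win - 1])),
        tuple(float(v) for v in seg),
    )
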