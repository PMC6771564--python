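"""Daughter-cell cohort classification and morphometric comparison.

The two flagella-connector-remnant markers split the G1 (1F1K1N) cells of a
single culture into three cohorts: new-flagellum daughters (NFD, tip marker),
old-flagellum daughters (OFD, mid-flagellum marker) and cells born earlier
that have already shed both remnants (no-FCR).  This module classifies cell
records into those cohorts and compares morphometric parameters (flagellum,
cell body, FAZ, kinetoplast-nucleus distance, ...) between cohorts with
two-sample t tests.

The default test is Welch's unequal-variance t (the printed angle summaries
have clearly unequal spreads); Student's pooled test is available via
``kind="student"``.  No multiple-testing correction is applied: each
parameter is reported at its own P < 0.05, matching the study convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORTS",
    "MEASUREMENT_COLUMNS",
    "CellRecord",
    "classify_cohort",
    "classify_cohorts",
    "tally_fraction",
    "summarize",
    "two_sample_test",
    "histogram",
    "CohortComparison",
    "CohortComparisonResults",
    "TestResult",
]

#: Cohort labels for 1F1K1N cells (plus the catch-all for later stages).
NFD, OFD, NO_FCR, NOT_1F1K1N = "NFD", "OFD", "NO_FCR", "NOT_1F1K1N"
COHORTS = (NFD, OFD, NO_FCR)

#: Morphometric columns of the cell-record table (lengths in micrometres).
MEASUREMENT_COLUMNS = (
    "flagellum_um",
    "cell_body_um",
    "faz_um",
    "kn_dist_um",
    "kpost_dist_um",
    "free_flagellum_um",
    "anterior_angle_deg",
)


@dataclass
class CellRecord:
    """One measured cell: F/K/N configuration, marker signals, morphometrics."""

    cell_id: str
    n_flagella: int = 1
    n_kinetoplasts: int = 1
    n_nuclei: int = 1
    tip_marker: bool = False  # new-flagellum tip remnant (marks NFDs)
    mid_marker: bool = False  # mid-flagellum remnant (marks OFDs)
    flagellum_um: float = np.nan
    cell_body_um: float = np.nan
    faz_um: float = np.nan
    kn_dist_um: float = np.nan
    kpost_dist_um: float = np.nan
    free_flagellum_um: float = np.nan
    anterior_angle_deg: float = np.nan

    def __post_init__(self) -> None:
        for name in ("n_flagella", "n_kinetoplasts", "n_nuclei"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in MEASUREMENT_COLUMNS:
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (
            not np.isnan(self.free_flagellum_um)
            and not np.isnan(self.flagellum_um)
            and self.free_flagellum_um > self.flagellum_um + 1e-9
        ):
            raise ValueError("free_flagellum_um cannot exceed flagellum_um")


def classify_cohort(record: CellRecord | pd.Series) -> str:
    """Assign one record to NFD / OFD / NO_FCR / NOT_1F1K1N.

    Only cells with exactly one flagellum, kinetoplast and nucleus are
    cohort-classified; among those, the tip marker identifies NFDs and the
    mid-flagellum marker OFDs.  A 1F1K1N record carrying both markers is a
    data error (the remnants segregate to different daughters).
    """
    counts = (
        int(record["n_flagella"] if isinstance(record, pd.Series) else record.n_flagella),
        int(record["n_kinetoplasts"] if isinstance(record, pd.Series) else record.n_kinetoplasts),
        int(record["n_nuclei"] if isinstance(record, pd.Series) else record.n_nuclei),
    )
    tip = bool(record["tip_marker"] if isinstance(record, pd.Series) else record.tip_marker)
    mid = bool(record["mid_marker"] if isinstance(record, pd.Series) else record.mid_marker)
    if counts != (1, 1, 1):
        return NOT_1F1K1N
    if tip and mid:
        raise ValueError("a 1F1K1N cell cannot carry both FCR markers")
    if tip:
        return NFD
    if mid:
        return OFD
    return NO_FCR


def classify_cohorts(records: pd.DataFrame) -> pd.Series:
    """Vectorised cohort assignment; raises on any double-marked 1F1K1N row."""
    is_g1 = (
        (records["n_flagella"] == 1)
        & (records["n_kinetoplasts"] == 1)
        & (records["n_nuclei"] == 1)
    )
    tip = records["tip_marker"].astype(bool)
    mid = records["mid_marker"].astype(bool)
    both = is_g1 & tip & mid
    if both.any():
        bad = records.index[both].tolist()
        raise ValueError(f"1F1K1N rows with both FCR markers set: {bad}")
    out = pd.Series(NO_FCR, index=records.index, dtype=object)
    out[tip] = NFD
    out[mid] = OFD
    out[~is_g1] = NOT_1F1K1N
    return out


def tally_fraction(n_pos: int, n_total: int) -> float:
    """Percentage ``100 * n_pos / n_total`` rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("need 0 <= n_pos <= n_total")
    pct = Decimal(100 * n_pos) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(
    records: pd.DataFrame,
    cohort: str,
    parameter: str,
    cohort_column: str = "cohort",
) -> tuple[float, float, int]:
    """(mean, sample s.d., n) of one parameter within one cohort.

    Missing values are excluded; at least two non-missing values are
    required.  The s.d. uses the n-1 denominator.
    """
    if parameter not in records.columns:
        raise KeyError(f"unknown parameter column {parameter!r}")
    col = records.loc[records[cohort_column] == cohort, parameter].dropna()
    if len(col) < 2:
        raise ValueError(
            f"need >= 2 non-missing values for {parameter!r} in cohort {cohort!r}, "
            f"got {len(col)}"
        )
    return float(col.mean()), float(col.std(ddof=1)), int(len(col))


class TestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float
    significant: bool  # at P < 0.05


def _welch_df(sd1, n1, sd2, n2) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def two_sample_test(a, b, kind: str = "welch") -> TestResult:
    """Two-sided two-sample t test between groups ``a`` and ``b``.

    Each group is either a vector of values or a ``(mean, sd, n)`` summary
    triple.  ``kind`` selects Welch's unequal-variance test (default, with
    Welch-Satterthwaite degrees of freedom) or Student's pooled test.
    """
    if kind not in ("welch", "student"):
        raise ValueError("kind must be 'welch' or 'student'")

    def as_stats(g):
        if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
            return float(g[0]), float(g[1]), int(g[2])
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError("each group needs at least two non-missing values")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = as_stats(a)
    m2, s2, n2 = as_stats(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")

    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=(kind == "student")
    )
    df = (n1 + n2 - 2) if kind == "student" else _welch_df(s1, n1, s2, n2)
    t, p = float(res.statistic), float(res.pvalue)
    return TestResult(t, float(df), p, p < 0.05)


def histogram(
    values: Sequence[float] | pd.Series,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed right-open histogram with bins anchored at 0.

    Returns ``(edges, counts)`` where ``edges`` has ``len(counts) + 1``
    entries ``0, w, 2w, ...``.  Counts sum to the number of non-missing
    values; an empty selection yields empty arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    if np.any(arr < 0):
        raise ValueError("histogram expects non-negative values")
    n_bins = int(np.floor(arr.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.floor(arr / bin_width).astype(int)  # left-closed, right-open
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def cohort_histogram(
    records: pd.DataFrame,
    cohort: str,
    parameter: str,
    bin_width: float,
    cohort_column: str = "cohort",
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one parameter within one cohort (see :func:`histogram`)."""
    sel = records.loc[records[cohort_column] == cohort, parameter]
    return histogram(sel, bin_width)


class CohortComparison:
    """Morphometric comparison of the three 1F1K1N cohorts.

    Construct from a cell-record table (one row per cell, measurement columns
    in micrometres), call :meth:`fit` for per-cohort summaries and pairwise
    tests.

    Parameters
    ----------
    records : DataFrame
        Cell-record table; a ``cohort`` column is computed from counts and
        markers if not already present.
    """

    def __init__(self, records: pd.DataFrame):
        records = records.copy()
        if "cohort" not in records.columns:
            records["cohort"] = classify_cohorts(records)
        self.records = records

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame) -> "CohortComparison":
        return cls(records)

    def fit(
        self,
        kind: str = "welch",
        parameters: Sequence[str] | None = None,
        cohorts: Sequence[str] = COHORTS,
    ) -> "CohortComparisonResults":
        """Summarise every cohort and test every cohort pair per parameter.

        Parameters with fewer than two non-missing values in a cohort are
        skipped for that cohort (and for pairs involving it).
        """
        if parameters is None:
            parameters = [
                c for c in MEASUREMENT_COLUMNS if c in self.records.columns
            ]
        summaries = []
        stats_lookup: dict[tuple[str, str], tuple[float, float, int]] = {}
        for cohort in cohorts:
            for param in parameters:
                try:
                    m, s, n = summarize(self.records, cohort, param)
                except ValueError:
                    continue
                summaries.append(
                    dict(cohort=cohort, parameter=param, mean=m, sd=s, n=n)
                )
                stats_lookup[(cohort, param)] = (m, s, n)
        pairwise = []
        for param in parameters:
            for i, ca in enumerate(cohorts):
                for cb in cohorts[i + 1 :]:
                    if (ca, param) not in stats_lookup or (cb, param) not in stats_lookup:
                        continue
                    res = two_sample_test(
                        stats_lookup[(ca, param)], stats_lookup[(cb, param)], kind=kind
                    )
                    pairwise.append(
                        dict(
                            parameter=param,
                            cohort_a=ca,
                            cohort_b=cb,
                            statistic=res.statistic,
                            df=res.df,
                            pvalue=res.pvalue,
                            significant=res.significant,
                        )
                    )
        return CohortComparisonResults(
            self,
            pd.DataFrame(summaries, columns=["cohort", "parameter", "mean", "sd", "n"]),
            pd.DataFrame(
                pairwise,
                columns=[
                    "parameter", "cohort_a", "cohort_b",
                    "statistic", "df", "pvalue", "significant",
                ],
            ),
            kind,
        )


class CohortComparisonResults:
    """Per-cohort summary statistics and pairwise test results."""

    def __init__(
        self,
        model: CohortComparison,
        summaries: pd.DataFrame,
        pairwise: pd.DataFrame,
        kind: str,
    ):
        self.model = model
        self.summaries = summaries
        self.pairwise = pairwise
        self.kind = kind

    def summary(self) -> str:
        lines = [f"Cohort morphometrics ({self.kind} t test, two-sided)"]
        lines.append("")
        for param, grp in self.summaries.groupby("parameter", sort=False):
            lines.append(param)
            for _, r in grp.iterrows():
                lines.append(
                    f"  {r['cohort']:<8} {r['mean']:8.2f} +/- {r['sd']:5.2f}"
                    f"  (n={int(r['n'])})"
                )
            tests = self.pairwise[self.pairwise["parameter"] == param]
            for _, r in tests.iterrows():
                star = " *" if r["significant"] else ""
                lines.append(
                    f"    {r['cohort_a']} vs {r['cohort_b']}: "
                    f"t={r['statistic']:.2f}, df={r['df']:.1f}, "
                    f"P={r['pvalue']:.3g}{star}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CohortComparisonResults: {self.summaries['parameter'].nunique()} "
            f"parameters, {len(self.pairwise)} pairwise tests>"
        )
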