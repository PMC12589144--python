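"""Replication statistics: uncorrected chi-squared on 2x2 tables,
Mann-Whitney U with the normal approximation, and the population-SD z
confidence interval for a mean — the exact procedures behind the study's
group-comparison table, plus the machinery to rebuild that table from a
cohort.

These deliberately reproduce the conventions of simple online calculators:
Pearson chi-squared WITHOUT Yates continuity correction (and without a
minimum-expected-count refusal — a warning is logged instead), and a mean
CI built from the population (divide-by-n) standard deviation with the
standard-normal quantile. Both choices are what make the published numbers
reproduce exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .cohort import Cohort
from .hscore import HScorePolicy, hscore
from .screening import percent_display

__all__ = [
    "TwoByTwo",
    "GroupComparison",
    "chi_squared_2x2",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "population_z_ci",
    "population_z_ci_display",
    "build_table3",
    "percent_difference",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b) = group 1 with/without the feature, (c, d) = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


class SmallExpectedCountWarning(UserWarning):
    """An expected cell count is below 5; the chi-squared approximation is
    rough there (the statistic is still computed)."""


def chi_squared_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 table, no
    continuity correction.

    Returns ``(statistic, p)`` with p from the chi-squared distribution
    with 1 df. Degenerate tables (a zero row or column margin) raise.
    """
    obs = t.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: zero marginal total")
    expected = np.outer(row, col) / t.total
    if (expected < 5).any():
        warnings.warn(
            f"expected cell count below 5 (min {expected.min():.2f}); "
            "chi-squared approximation may be poor",
            SmallExpectedCountWarning,
            stacklevel=2,
        )
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(_sps.chi2.sf(statistic, df=1))
    return statistic, p


def fisher_exact_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Fisher's exact test (odds ratio, two-sided p) — offered for small
    tables; note the replication path uses chi-squared regardless."""
    odds, p = _sps.fisher_exact([[t.a, t.b], [t.c, t.d]])
    return float(odds), float(p)


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with midranks and the tie-corrected normal
    approximation.

    Returns ``(u, z, p)`` where ``u`` is the U statistic of the first
    sample, ``z`` the standardised statistic — negative when the first
    group's values are stochastically smaller — and ``p`` the two-tailed
    normal-approximation p-value. When every pooled value is identical the
    variance vanishes: ``z`` and ``p`` come back NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # midranks for ties
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        warnings.warn(
            "all pooled values identical: Mann-Whitney z undefined", UserWarning, stacklevel=2
        )
        return float(u), float("nan"), float("nan")
    z = (u - mean_u) / math.sqrt(var_u)
    p = 2.0 * float(_sps.norm.sf(abs(z)))
    return float(u), float(z), min(p, 1.0)


def population_z_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean with a z confidence interval using the population
    (divide-by-n) standard deviation.

    Returns ``(mean, lower, upper)`` = mean +/- z * sigma/sqrt(n) with
    sigma = population SD and z the standard-normal quantile (1.959964 at
    95%). Rounding for display is the caller's business.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("population_z_ci requires n >= 2")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    mean = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    z = float(_sps.norm.ppf(0.5 + confidence / 2.0))
    half = z * sigma / math.sqrt(vals.size)
    return mean, mean - half, mean + half


def population_z_ci_display(values, confidence: float = 0.95) -> tuple[int, int, int]:
    """The CI as whole numbers the way simple reporting tools print it:
    the mean and the margin of error are each rounded to the nearest
    integer FIRST, and the interval endpoints are formed from the rounded
    pair. (Rounding the raw endpoints directly can differ by 1 in the last
    digit; this convention is the one the replicated report used.)"""
    mean, lower, _ = population_z_ci(values, confidence)
    margin = mean - lower
    m, h = round(mean), round(margin)
    return m, m - h, m + h


def percent_difference(high: float, low: float) -> float:
    """How much greater ``high`` is than ``low``, in percent of ``low``."""
    if low == 0:
        raise ValueError("baseline value is zero")
    return (high - low) / low * 100.0


# ---------------------------------------------------------------------------
# Group-comparison table


@dataclass
class GroupComparison:
    """One comparison row: a feature tallied (or averaged) per group with
    its test statistic and p-value."""

    label: str
    group1_summary: str
    group2_summary: str
    statistic: float
    p_value: float
    test_name: str  # "chi-squared" | "mann-whitney"
    group1_count: int | None = None
    group2_count: int | None = None


def _count_row(label, flags_low, flags_high) -> GroupComparison:
    a = sum(flags_low)
    c = sum(flags_high)
    n1, n2 = len(flags_low), len(flags_high)
    stat, p = chi_squared_2x2(TwoByTwo(a, n1 - a, c, n2 - c))
    return GroupComparison(
        label=label,
        group1_summary=f"{a} ({percent_display(a / n1)}%)",
        group2_summary=f"{c} ({percent_display(c / n2)}%)",
        statistic=stat,
        p_value=p,
        test_name="chi-squared",
        group1_count=a,
        group2_count=c,
    )


# Binary feature definitions matching the published comparison table's row
# wording (strict inequalities, transaminase AST>30 or ALT>100).
_TABLE3_FEATURES = [
    ("Patients with haemoglobin < 90 g/L", lambda p: p.haemoglobin_gL is not None and p.haemoglobin_gL < 90),
    ("Patients with platelets < 100e9/L", lambda p: p.platelets_1e9L is not None and p.platelets_1e9L < 100),
    ("Patients with neutrophils < 1e9/L", lambda p: p.neutrophils_1e9L is not None and p.neutrophils_1e9L < 1),
    ("Patients with a fever", lambda p: bool(p.has_fever())),
    ("Patients with hepatomegaly", lambda p: bool(p.hepatomegaly)),
    ("Patients with splenomegaly", lambda p: bool(p.splenomegaly)),
    ("Patients with triglycerides > 1.5 mmol/L", lambda p: p.triglycerides_mmolL is not None and p.triglycerides_mmolL > 1.5),
    ("Patients with fibrinogen < 2.5 g/L", lambda p: p.fibrinogen_gL is not None and p.fibrinogen_gL < 2.5),
    ("Patients with haemophagocytosis recorded", lambda p: bool(p.haemophagocytosis)),
    ("Patients with immunosuppression", lambda p: bool(p.immunosuppressed)),
    (
        "Patients with transaminase derangement (AST > 30/ALT > 100)",
        lambda p: (p.ast_UL is not None and p.ast_UL > 30) or (p.alt_UL is not None and p.alt_UL > 100),
    ),
]


def build_table3(
    cohort: Cohort,
    hscore_policy: HScorePolicy | None = None,
    censoring_policy: str = "ceiling",
) -> list[GroupComparison]:
    """Rebuild the group-comparison table: patients split at the HScore
    cutoff, mean peak ferritin compared by Mann-Whitney U, then eleven
    binary features by uncorrected chi-squared.

    Group 1 is the below-cutoff group (so the Mann-Whitney z is negative
    when the below-cutoff group's ferritins are smaller, matching the
    published sign convention).
    """
    from .cohort import numeric_ferritin

    policy = hscore_policy or HScorePolicy()
    low, high = [], []
    for p in cohort:
        (high if hscore(p, policy).positive else low).append(p)
    if not low or not high:
        raise ValueError("both HScore groups must be non-empty to build the table")

    rows: list[GroupComparison] = []
    ferr_low = [v for v in (numeric_ferritin(p.ferritin_ugL, censoring_policy) for p in low) if v is not None]
    ferr_high = [v for v in (numeric_ferritin(p.ferritin_ugL, censoring_policy) for p in high) if v is not None]
    _, z, p_mw = mann_whitney_u(ferr_low, ferr_high)
    rows.append(
        GroupComparison(
            label="Mean peak serum ferritin level (ug/L)",
            group1_summary=f"{np.mean(ferr_low):,.0f}",
            group2_summary=f"{np.mean(ferr_high):,.0f}",
            statistic=z,
            p_value=p_mw,
            test_name="mann-whitney",
        )
    )
    for label, predicate in _TABLE3_FEATURES:
        rows.append(_count_row(label, [predicate(p) for p in low], [predicate(p) for p in high]))
    return rows


def table3_to_dataframe(rows: list[GroupComparison], n_low: int, n_high: int):
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            f"HScore < 169 (n={n_low})": [r.group1_summary for r in rows],
            f"HScore >= 169 (n={n_high})": [r.group2_summary for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test_name for r in rows],
        }
    )
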