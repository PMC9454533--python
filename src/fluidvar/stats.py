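"""Cohort statistics: Spearman rank correlation, Wilcoxon signed-rank,
chi-square independence, medians and ranges.

Conventions (fixed and reported in each result's method descriptor):
Spearman rho is the Pearson correlation of mid-ranks with the
t-distribution p-value; the Wilcoxon signed-rank test drops zero
differences, mid-ranks tied absolute differences, uses the exact null
distribution when n <= 25 without ties and otherwise a normal
approximation with tie and continuity correction, two-sided; the
chi-square test of independence uses the Pearson statistic without
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "chi_square_independence",
    "median_range",
    "format_percent",
    "venn_totals",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t-distribution approximation with n - 2 degrees of
    freedom.  A constant vector has no rank ordering and raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman mid-ranks, t approximation")


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention).  With n <= 25
    remaining pairs and untied absolute differences the exact null
    distribution is used; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate input: all paired differences are zero")
    if len(d) < 3:
        raise ValueError("need at least 3 nonzero differences")
    abs_d = np.abs(d)
    has_ties = len(np.unique(abs_d)) < len(abs_d)
    if len(d) <= 25 and not has_ties:
        method = "exact"
        res = sps.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        method = "normal approximation, tie + continuity correction"
        res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    return TestResult(
        float(res.statistic), float(res.pvalue), f"wilcoxon signed-rank, zeros dropped, {method}"
    )


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the margins; df = (r-1)(c-1); no continuity
    correction.  A zero row or column margin leaves expected counts
    undefined and raises ValueError.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("table must be a 2-D array of counts")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), f"pearson chi-square, df={dof}, no correction")


def median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """Return (median, min, max); even counts average the central pair."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    return float(np.median(vals)), float(vals.min()), float(vals.max())


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A reporting-layer percentage, rounded to the printed precision."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals if decimals > 0 else None)


def venn_totals(exclusive_a: int, exclusive_b: int, shared: int) -> dict[str, int]:
    """Fluid totals and grand total from Venn components (conservation law)."""
    if min(exclusive_a, exclusive_b, shared) < 0:
        raise ValueError("counts must be non-negative")
    total_a = exclusive_a + shared
    total_b = exclusive_b + shared
    return {
        "total_a": total_a,
        "total_b": total_b,
        "grand_total": total_a + total_b,
    }
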