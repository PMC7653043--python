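"""Registry-style statistical machinery: type-6 quantiles, Mann-Whitney U,
chi-square / Fisher contingency tests, and simple linear regression.

Conventions match common clinical-statistics software defaults:

* Quantiles use the type-6 rule (h = (n+1)p with linear interpolation
  between order statistics, clamped to the data range) — the percentile
  definition behind the study tables' medians and interquartile ranges.
* Mann-Whitney p-values come from exact enumeration when the sample sizes
  are small (n1*n2 <= 400) and there are no ties, otherwise from the
  normal approximation with tie-corrected variance and no continuity
  correction.
* Contingency tables use the Pearson chi-square statistic, falling back to
  Fisher's exact test for 2x2 tables with any expected cell below 5.

All tests are two-sided.  scipy provides the distributional machinery;
this module fixes the conventions and returns small result records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegeneratePredictorError, DegenerateTableError, EmptyInputError

EXACT_MWU_MAX_PRODUCT = 400


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float

    def format(self, ndigits: int | None = 0) -> str:
        """`median (q1, q3)` string for report tables."""
        if ndigits is None:
            return f"{self.median:g} ({self.q1:g}, {self.q3:g})"
        fmt = f"{{:.{ndigits}f}}"
        return (
            f"{fmt.format(self.median)} ({fmt.format(self.q1)}, {fmt.format(self.q3)})"
        )


@dataclass(frozen=True)
class MWUResult:
    u_statistic: float  # U for the first sample
    z_value: float
    p_two_sided: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p_value: float
    method_used: str  # "chi_square" | "fisher_exact"
    dof: int | None = None


def quantile_type6(values: Sequence[float], p: float) -> float:
    """Type-6 quantile: h = (n+1)p, linear interpolation, clamped to range."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("quantile of an empty sample")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(np.quantile(arr, p, method="weibull"))


def group_summary(values: Sequence[float]) -> GroupSummary:
    """n, median and type-6 quartiles of a sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("summary of an empty sample")
    return GroupSummary(
        n=int(arr.size),
        median=quantile_type6(arr, 0.5),
        q1=quantile_type6(arr, 0.25),
        q3=quantile_type6(arr, 0.75),
    )


def _tie_corrected_z(a: np.ndarray, b: np.ndarray, u1: float) -> float:
    n1, n2 = len(a), len(b)
    n = n1 + n2
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return 0.0
    return (u1 - mu) / np.sqrt(var)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration for small tie-free samples (n1*n2 <= 400);
    otherwise the normal approximation with mid-ranks for ties,
    tie-corrected variance and no continuity correction.  The reported U
    and z refer to the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("Mann-Whitney requires two non-empty samples")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    use_exact = (a.size * b.size <= EXACT_MWU_MAX_PRODUCT) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=False,
    )
    u1 = float(res.statistic)
    return MWUResult(
        u_statistic=u1,
        z_value=float(_tie_corrected_z(a, b, u1)),
        p_two_sided=min(1.0, float(res.pvalue)),
        method="exact" if use_exact else "asymptotic",
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on a single predictor x.

    Returns slope, intercept, R^2 (squared Pearson correlation) and the
    two-sided t-test p-value for the slope.  A constant y gives a flat fit
    with R^2 = 0 and p = 1; a constant x is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise EmptyInputError("regression requires at least 3 points")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor x is constant")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_slope=1.0, n=int(x.size))
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_slope=float(fit.pvalue),
        n=int(x.size),
    )


def contingency_test(table) -> ContingencyResult:
    """Pearson chi-square on a 2xk count table, Fisher fallback for sparse 2x2.

    The fallback (Fisher's exact test, two-sided) triggers when the table
    is 2x2 and any expected cell count is below 5; ``method_used`` records
    which test produced the p-value.  For the chi-square branch the
    statistic is Pearson's X^2 without continuity correction; for Fisher
    it is the sample odds ratio.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateTableError("table has an all-zero margin")
    expected = sps.contingency.expected_freq(obs)
    if obs.shape == (2, 2) and expected.min() < 5:
        odds, p = sps.fisher_exact(obs.astype(int), alternative="two-sided")
        return ContingencyResult(statistic=float(odds), p_value=float(p), method_used="fisher_exact")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        statistic=float(chi2), p_value=float(p), method_used="chi_square", dof=int(dof)
    )
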