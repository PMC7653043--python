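"""Independent brute-force oracles used to validate the statistics module.

Everything here is deliberately naive — exhaustive enumeration and textbook
sum formulas — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom, t as t_dist


def mwu_exact_p_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties.  Counts the assignments whose U is at least as extreme
    (in |U - n1*n2/2|) as the observed one.
    """
    a, b = list(a), list(b)
    n1 = len(a)
    combined = sorted(a + b)
    assert len(set(combined)) == len(combined), "oracle assumes no ties"

    def u_stat(group_a):
        group_b = [v for v in combined if v not in group_a]
        return sum(1 for x in group_a for y in group_b if x > y)

    mu = n1 * len(b) / 2.0
    u_obs = u_stat(set(a))
    extreme = 0
    total = 0
    for comb in itertools.combinations(combined, n1):
        total += 1
        if abs(u_stat(set(comb)) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def fisher_exact_p_two_sided(table) -> float:
    """Two-sided Fisher p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(1.0, p)


def ols_closed_form(x, y):
    """Simple-regression slope/intercept/R^2/p from the textbook sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 0.0
    resid = y - (intercept + slope * x)
    se = math.sqrt(np.sum(resid**2) / (n - 2) / sxx) if n > 2 else float("nan")
    if se == 0:
        p = 0.0
    else:
        p = 2 * t_dist.sf(abs(slope / se), df=n - 2)
    return slope, intercept, r2, p


def chi_square_direct(table):
    """Pearson X^2 = sum (O - E)^2 / E with margin-product expected counts."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())
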