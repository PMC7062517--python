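"""Nonparametric tests: Mann-Whitney U (exact by enumeration at small n)
and Spearman's rank correlation (exact permutation p at small n).

Conventions
-----------
U counts (x_i, y_j) pairs with x_i < y_j, plus half of exact ties (midrank
convention), so large U means x tends to be smaller than y. The mirrored
statistic satisfies U(x, y) + U(y, x) = m * n and both orderings give the
same two-sided p. All reported tests are two-sided with significance at
P < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata, t as t_dist

#: Exact enumeration is used when m + n <= this cap (C(12,6) = 924 splits).
EXACT_CAP_MW = 12
#: Exact permutation p for Spearman when n <= this cap (8! = 40,320 perms).
EXACT_CAP_SPEARMAN = 8

_EPS = 1e-9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # exact | normal_approximation | t_approximation | undefined
    n1: int
    n2: int


def _u_from_ranks(rank_sum_y: float, n_y: int) -> float:
    return rank_sum_y - n_y * (n_y + 1) / 2.0


def mann_whitney_u(
    x, y, alternative: str = "two_sided", exact_cap: int = EXACT_CAP_MW
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    With m + n <= ``exact_cap`` the p-value is exact, from complete
    enumeration of all C(m+n, m) assignments of the pooled observations to
    groups (conditioning on the observed values, so ties are handled
    exactly). Otherwise a normal approximation with tie-corrected variance
    and continuity correction is used. ``alternative='less'`` tests x
    stochastically smaller than y; two-sided p is min(1, 2 x smaller
    one-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = _u_from_ranks(ranks[m:].sum(), n)

    if m + n <= exact_cap:
        total = ranks.sum()
        combos = np.array(list(itertools.combinations(range(m + n), m)))
        u_all = _u_from_ranks(total - ranks[combos].sum(axis=1), n)
        p_ge = float(np.mean(u_all >= u_obs - _EPS))
        p_le = float(np.mean(u_all <= u_obs + _EPS))
        method = "exact"
    else:
        mean = m * n / 2.0
        big_n = m + n
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
        var = m * n / 12.0 * (big_n + 1 - tie_term)
        if var <= 0:
            p_ge = p_le = 1.0
        else:
            sd = math.sqrt(var)
            p_ge = float(norm.sf((u_obs - mean - 0.5) / sd))
            p_le = float(norm.cdf((u_obs - mean + 0.5) / sd))
        method = "normal_approximation"

    if alternative == "less":
        p = p_ge
    elif alternative == "greater":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(statistic=float(u_obs), p_value=p, method=method, n1=m, n2=n)


def spearman_rho(x, y, exact_cap: int = EXACT_CAP_SPEARMAN) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    Exact permutation p (two-sided, |rho| >= |rho_obs|) for n <= exact_cap;
    t-approximation with n - 2 degrees of freedom otherwise. Constant input
    leaves rho undefined (NaN, method='undefined').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("sequences must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(float("nan"), float("nan"), "undefined", n, n)
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)

    if n <= exact_cap:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - _EPS))
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * t_dist.sf(abs(t), n - 2))
        method = "t_approximation"
    return TestResult(statistic=rho, p_value=p, method=method, n1=n, n2=n)
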