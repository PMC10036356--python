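"""Concentration-viscosity power-law fitting and nonparametric group tests.

The scaling fit is ordinary least squares of ln eta on ln c, so the
slope is the power-law exponent gamma in eta ~ c^gamma.  Group
comparisons use the Wilcoxon rank-sum test (exact by full enumeration
for small samples without ties, normal approximation with tie and
continuity corrections otherwise) and the Kruskal–Wallis H test with tie
correction against a chi-square reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from mucorheo.errors import InvalidInputError

__all__ = [
    "ScalingFit",
    "RankSumResult",
    "KruskalResult",
    "fit_power_law",
    "rank_sum_test",
    "kruskal_wallis",
]

#: largest pooled sample for which the rank-sum null is fully enumerated
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class ScalingFit:
    """Power-law exponent with its 95% CI from a log-log OLS fit."""

    gamma: float
    log_prefactor: float
    ci95: tuple[float, float]
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    p_two_sided: float
    method: str  # "exact" or "normal-approx"


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    df: int


def fit_power_law(points: Sequence[tuple[float, float]]) -> ScalingFit:
    """OLS fit of ln eta on ln c; gamma is the slope.

    The 95% CI uses the t distribution on the residual variance; with
    exactly two points the CI degenerates to the point estimate.
    """
    pts = [(float(c), float(e)) for c, e in points]
    if any(c <= 0 or e <= 0 for c, e in pts):
        raise InvalidInputError("concentrations and viscosities must be > 0")
    cs = np.array([c for c, _ in pts])
    if len(set(cs.tolist())) < 2:
        raise InvalidInputError("need >= 2 distinct concentrations")
    x = np.log(cs)
    y = np.log(np.array([e for _, e in pts]))
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n > 2:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        tcrit = float(sps.t.ppf(0.975, n - 2))
        ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        ci = (slope, slope)
    return ScalingFit(
        gamma=slope, log_prefactor=intercept, ci95=ci, r_squared=r2, n_points=n
    )


def _rank(data: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(data, kind="stable")
    ranks = np.empty(len(data))
    sorted_vals = data[order]
    i = 0
    while i < len(data):
        j = i
        while j + 1 < len(data) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    continuity: bool = True,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    With ``method='auto'``: exact by full enumeration of rank
    assignments when n_x + n_y <= EXACT_ENUMERATION_LIMIT and the pooled
    data has no ties; otherwise a normal approximation with tie
    correction and (by default) continuity correction.  ``'exact'`` /
    ``'normal'`` force a path (exact refuses ties).  The exact
    two-sided p doubles the smaller tail (capped at 1).  Without the
    continuity correction the two-group approximation coincides with
    the Kruskal-Wallis chi-square p.
    """
    if method not in ("auto", "exact", "normal"):
        raise InvalidInputError(f"unknown method {method!r}")
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    ranks = _rank(pooled)
    w = float(ranks[:nx].sum())
    no_ties = len(set(pooled.tolist())) == n
    if method == "exact" and not no_ties:
        raise InvalidInputError("exact enumeration requires tie-free data")

    use_exact = (
        method == "exact"
        or (method == "auto" and n <= EXACT_ENUMERATION_LIMIT and no_ties)
    )
    if use_exact:
        all_ranks = range(1, n + 1)
        sums = [sum(c) for c in combinations(all_ranks, nx)]
        total = len(sums)
        lo = sum(1 for s in sums if s <= w)
        hi = sum(1 for s in sums if s >= w)
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return RankSumResult(statistic=w, p_two_sided=p, method="exact")

    mu = nx * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    ny = n - nx
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(statistic=w, p_two_sided=1.0, method="normal-approx")
    z = (abs(w - mu) - (0.5 if continuity else 0.0)) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * sps.norm.sf(z))
    return RankSumResult(statistic=w, p_two_sided=min(p, 1.0), method="normal-approx")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal–Wallis H with tie correction; p from chi-square (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidInputError("need >= 2 non-empty groups")
    arrays = [np.asarray(list(g), float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _rank(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # every value identical
        return KruskalResult(h=0.0, p=1.0, df=len(groups) - 1)
    h /= denom
    df = len(groups) - 1
    return KruskalResult(h=float(h), p=float(sps.chi2.sf(h, df)), df=df)
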