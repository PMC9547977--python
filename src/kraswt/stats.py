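"""From-scratch statistical kernel used by every pipeline stage.

Each routine is implemented directly (log-gamma hypergeometric mass, step-up
BH, normal-approximation rank tests with tie and continuity corrections)
and is validated in the test suite against brute-force enumeration or
permutation oracles.  Distribution tail functions (normal, t, F) come from
scipy.special / scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as _scipy_stats

# relative tolerance used when comparing point probabilities in the
# two-sided Fisher rule, matching common statistical software
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _log_hypergeom_pmf(a: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = a) for X ~ Hypergeom with fixed 2x2 margins (r1, c1, total n)."""
    a = np.asarray(a, dtype=float)
    return (
        _log_binom(r1, a) + _log_binom(n - r1, c1 - a) - _log_binom(n, c1)
    )


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed that of the
    observed table (point-probability rule).  The statistic is the sample
    odds ratio a*d / (b*c), with the 0 -> inf convention on zero cells.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if n == 0 or lo == hi:
        p = 1.0
    else:
        support = np.arange(lo, hi + 1)
        logpmf = _log_hypergeom_pmf(support, r1, c1, n)
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        p_obs = pmf[a - lo]
        p = float(pmf[pmf <= p_obs * (1 + _FISHER_REL_TOL)].sum())
        p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
        if a * d == 0 and b * c == 0:
            odds = np.nan
    else:
        odds = a * d / (b * c)
    return TestResult(statistic=float(odds), p_value=p, method="fisher2x2")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N population, K successes,
    n draws)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"impossible configuration k={k}, K={K}, n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(K, n)
    support = np.arange(lo, hi + 1)
    logpmf = _log_binom(K, support) + _log_binom(N - K, n - support) - _log_binom(N, n)
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    return float(min(1.0, pmf[support >= k].sum()))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                     alternative: str = "two-sided") -> TestResult:
    """Wilcoxon/Mann-Whitney rank-sum test, normal approximation with tie
    correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = x.size, y.size
    allv = np.concatenate([x, y])
    ranks = _rankdata(allv)
    w = ranks[:n1].sum()  # rank sum of x
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie correction to the variance
    _, counts = np.unique(allv, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var == 0:
        return TestResult(statistic=float(w), p_value=1.0, method="wilcoxon_ranksum")
    diff = w - mu
    if alternative == "two-sided":
        z = (abs(diff) - 0.5) / np.sqrt(var)
        p = 2.0 * special.ndtr(-max(z, 0.0))
    elif alternative == "greater":
        z = (diff - 0.5) / np.sqrt(var)
        p = float(special.ndtr(-z))
    elif alternative == "less":
        z = (diff + 0.5) / np.sqrt(var)
        p = float(special.ndtr(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(w), p_value=float(min(1.0, p)),
                      method="wilcoxon_ranksum")


def wilcoxon_signedrank(d: Sequence[float],
                        alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test of symmetry about zero (zeros dropped),
    normal approximation with tie and continuity corrections."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size < 1:
        raise ValueError("no nonzero differences")
    absr = _rankdata(np.abs(d))
    w_plus = absr[d > 0].sum()
    n = d.size
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    if var == 0:
        return TestResult(statistic=float(w_plus), p_value=1.0,
                          method="wilcoxon_signedrank")
    diff = w_plus - mu
    if alternative == "two-sided":
        z = (abs(diff) - 0.5) / np.sqrt(var)
        p = 2.0 * special.ndtr(-max(z, 0.0))
    elif alternative == "greater":
        z = (diff - 0.5) / np.sqrt(var)
        p = float(special.ndtr(-z))
    elif alternative == "less":
        z = (diff + 0.5) / np.sqrt(var)
        p = float(special.ndtr(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(w_plus), p_value=float(min(1.0, p)),
                      method="wilcoxon_signedrank")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    rx, ry = _rankdata(x), _rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho = float((rx * ry).sum() / denom)
    n = x.size
    rho_c = min(1.0 - 1e-15, max(-1.0 + 1e-15, rho))
    t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
    p = float(2.0 * _scipy_stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has < 2 observations")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b = len(arrays) - 1
    df_w = allv.size - len(arrays)
    if ss_within == 0:
        p = 1.0 if ss_between == 0 else 0.0
        return TestResult(statistic=np.inf if ss_between else 0.0,
                          p_value=p, method="anova")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_scipy_stats.f.sf(f, df_b, df_w))
    return TestResult(statistic=float(f), p_value=min(1.0, p), method="anova")
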