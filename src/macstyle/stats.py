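"""Exact nonparametric tests and the Friedman post-hoc procedure.

All tests are two-tailed. Exact p-values use full enumeration (or an
equivalent exact distribution) wherever feasible, with midrank handling of
ties, falling back to the normal approximation above documented size
thresholds (flagged via ``exact=False``). The two-tailed exact p is the
doubled one-tail probability capped at 1, matching the convention of the
exact rank-test implementations common in this literature. Zero differences
in the one-sample signed-rank test are dropped (Wilcoxon convention).

The Friedman post-hoc comparison follows Siegel & Castellan: two conditions
differ when the absolute difference of their rank sums exceeds the critical
difference z(1 - alpha/(k(k-1))) * sqrt(N k (k+1) / 6).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: above this total permutation count, tied-sample tests fall back to the
#: normal approximation
MAX_ENUM = 200_000
#: largest n for the exact signed-rank distribution
WILCOXON_EXACT_N = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    exact: bool


@dataclass
class PostHocResult:
    rank_sums: np.ndarray
    pairwise: dict[tuple[int, int], float]  # (u, v) -> |rank-sum_u - rank-sum_v|
    critical_difference: float
    alpha: float

    @property
    def critical_difference_rounded(self) -> int:
        return int(round(self.critical_difference))


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------


def friedman(blocks, tie_correction: bool = True) -> TestResult:
    """Friedman rank test over an N x k table (blocks = subjects, columns = conditions).

    Within-block midranks; the chi-square statistic optionally carries the
    standard tie correction and is referred to chi-square with k-1 df.
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("blocks must be an N x k table with N >= 2, k >= 2")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
    if tie_correction:
        ties = 0.0
        for row in x:
            _, counts = np.unique(row, return_counts=True)
            ties += float((counts**3 - counts).sum())
        c = 1.0 - ties / (n * k * (k**2 - 1))
        if c <= 0:  # all rows constant
            return TestResult(statistic=0.0, p_value=1.0, n=(n, k), exact=False)
        stat /= c
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(statistic=float(stat), p_value=p, n=(n, k), exact=False)


def friedman_posthoc(blocks, alpha: float = 0.05) -> PostHocResult:
    """Siegel–Castellan multiple comparisons after a significant Friedman test."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(blocks, dtype=float)
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rj = ranks.sum(axis=0)
    pairwise = {
        (u, v): float(abs(rj[u] - rj[v])) for u in range(k) for v in range(u + 1, k)
    }
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    crit = float(z * math.sqrt(n * k * (k + 1) / 6.0))
    return PostHocResult(rank_sums=rj, pairwise=pairwise, critical_difference=crit, alpha=alpha)


def critical_difference(n: int, k: int, alpha: float = 0.05) -> float:
    """Siegel–Castellan critical rank-sum difference for N blocks, k conditions."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    return float(z * math.sqrt(n * k * (k + 1) / 6.0))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample, from midranks of the pooled data."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sample Mann-Whitney U with an exact two-tailed p when feasible.

    Without ties the exact null distribution of U is used directly; with
    ties the permutation distribution is fully enumerated when the number of
    group labelings is at most MAX_ENUM, otherwise the tie-corrected normal
    approximation is used (``exact=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(statistic=u, p_value=float(res.pvalue), n=(n1, n2), exact=True)

    if math.comb(n1 + n2, n1) <= MAX_ENUM:
        ranks = sps.rankdata(pooled)
        const = n1 * (n1 + 1) / 2.0
        us = np.array(
            [ranks[list(c)].sum() - const for c in itertools.combinations(range(n1 + n2), n1)]
        )
        lo = float(np.mean(us <= u + 1e-12))
        hi = float(np.mean(us >= u - 1e-12))
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(statistic=u, p_value=p, n=(n1, n2), exact=True)

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=u, p_value=float(res.pvalue), n=(n1, n2), exact=False)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (one sample)
# ---------------------------------------------------------------------------


def wilcoxon_signed_exact(x, mu0: float = 0.0) -> TestResult:
    """One-sample Wilcoxon signed-rank test of location against ``mu0``.

    Values equal to mu0 are dropped. The statistic is W+ (sum of ranks of
    positive differences, midranks for tied magnitudes). For n <= 25 the
    exact distribution over all 2^n sign patterns is computed (via a
    convolution over doubled ranks so midranks stay integral); larger
    samples use the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("sample must be nonempty")
    d = x - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=(0,), exact=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_N:
        ranks2 = np.round(ranks * 2).astype(int)  # midranks doubled -> integers
        total = int(ranks2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        dist /= dist.sum()
        w2 = int(round(w_plus * 2))
        lo = float(dist[: w2 + 1].sum())
        hi = float(dist[w2:].sum())
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(statistic=w_plus, p_value=p, n=(n,), exact=True)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_variance_reduction(d)
    z = (w_plus - mean) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p_value=min(1.0, p), n=(n,), exact=False)


def _tie_variance_reduction(d: np.ndarray) -> float:
    """Variance reduction for tied |d| groups: sum(t^3 - t) / 48."""
    _, counts = np.unique(np.abs(d), return_counts=True)
    return float((counts**3 - counts).sum()) / 48.0
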