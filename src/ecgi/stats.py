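"""Rank tests and Fisher's exact test shared across the pipeline stages.

Small samples get exact permutation null distributions computed by full
enumeration (with midranks, so ties are handled exactly); larger samples use
the tie-corrected normal approximation with continuity correction. The
Fisher test delegates to :func:`scipy.stats.fisher_exact` (two-sided p is
the sum of hypergeometric point probabilities not exceeding the observed
table's) but reports the sample odds ratio (a*d)/(b*c).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_greater: float
    p_less: float
    p_two_sided: float
    method: str
    degenerate: bool = False


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_test(a, b, exact_max: int = 10) -> RankTestResult:
    """Two-sample rank-sum (Mann-Whitney) test on unpaired samples.

    Exact enumeration of all C(n+m, n) rank assignments when both samples
    have at most ``exact_max`` observations; tie-corrected normal
    approximation otherwise. One-sided p_greater tests A > B.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = float(np.sum(ranks[:n]))

    if n <= exact_max and m <= exact_max:
        # integer arithmetic on doubled midranks avoids float-sum ties
        r2 = np.rint(2 * ranks).astype(np.int64)
        w2_obs = int(round(2 * w_obs))
        total = math.comb(n + m, n)
        n_ge = n_le = 0
        for combo in itertools.combinations(r2.tolist(), n):
            s = sum(combo)
            if s >= w2_obs:
                n_ge += 1
            if s <= w2_obs:
                n_le += 1
        p_greater = n_ge / total
        p_less = n_le / total
        p_two = min(1.0, 2 * min(p_greater, p_less))
        return RankTestResult(w_obs, p_greater, p_less, p_two, "exact")

    mu = n * (m + n + 1) / 2.0
    big_n = n + m
    var = (
        n * m / 12.0 * (big_n + 1 - _tie_term(ranks) / (big_n * (big_n - 1)))
    )
    if var <= 0:
        return RankTestResult(w_obs, 1.0, 1.0, 1.0, "normal", degenerate=True)
    sd = math.sqrt(var)
    p_greater = float(sps.norm.sf((w_obs - mu - 0.5) / sd))
    p_less = float(sps.norm.cdf((w_obs - mu + 0.5) / sd))
    p_two = min(1.0, 2 * min(p_greater, p_less))
    return RankTestResult(w_obs, p_greater, p_less, p_two, "normal")


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int  # non-zero differences
    p_greater: float
    p_less: float
    p_two_sided: float
    method: str
    degenerate: bool = False


def signed_rank_test(deltas, exact_max: int = 25) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. For n <= ``exact_max`` the null
    distribution of W+ over all 2^n sign assignments is computed exactly by
    a generating-function convolution on doubled midranks; beyond that the
    tie-corrected normal approximation is used. All differences zero is a
    degenerate input reported with p = 1.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        return SignedRankResult(0.0, 0, 1.0, 1.0, 1.0, "degenerate", degenerate=True)
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))

    if n <= exact_max:
        r2 = np.rint(2 * ranks).astype(np.int64)
        w2_obs = int(round(2 * w_plus))
        coeff = np.zeros(int(r2.sum()) + 1, dtype=np.int64)
        coeff[0] = 1
        top = 0
        for r in r2:
            coeff[r : top + r + 1] += coeff[: top + 1]
            top += int(r)
        total = float(2**n)
        p_greater = float(coeff[w2_obs:].sum()) / total
        p_less = float(coeff[: w2_obs + 1].sum()) / total
        p_two = min(1.0, 2 * min(p_greater, p_less))
        return SignedRankResult(w_plus, n, p_greater, p_less, p_two, "exact")

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(ranks) / 48.0
    if var <= 0:
        return SignedRankResult(w_plus, n, 1.0, 1.0, 1.0, "normal", degenerate=True)
    sd = math.sqrt(var)
    p_greater = float(sps.norm.sf((w_plus - mu - 0.5) / sd))
    p_less = float(sps.norm.cdf((w_plus - mu + 0.5) / sd))
    p_two = min(1.0, 2 * min(p_greater, p_less))
    return SignedRankResult(w_plus, n, p_greater, p_less, p_two, "normal")


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test with the sample odds ratio.

    The odds ratio is (a*d)/(b*c); 0/0 gives NaN and x/0 gives inf.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    num, den = a * d, b * c
    if den == 0:
        odds = math.nan if num == 0 else math.inf
    else:
        odds = num / den
    return FisherResult(((a, b), (c, d)), odds, float(p))
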