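"""Self-contained exact statistics: Fisher's exact test on 2x2 tables and
the Wilcoxon/Mann-Whitney rank-sum test.

Both tests are implemented here rather than delegated, because their exact
behaviour (two-sided minimum-likelihood Fisher p; exact rank-sum enumeration
for small samples) is part of the package's contract.  scipy is used only
for special functions and the normal distribution.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, rankdata

logger = logging.getLogger("occupeak")

_REL_TOL = 1e-7  # relative slack when comparing hypergeometric masses


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    Returns (odds ratio, p).  The odds ratio is the sample OR
    (a*d)/(b*c): infinite when b*c = 0 and a*d > 0, NaN for 0/0.  The
    two-sided p is the minimum-likelihood sum: all tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table (within relative tolerance 1e-7), evaluated in log space
    with no normal approximation.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"contingency cells must be non-negative integers, got {x}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    n = a + b + c + d
    if n == 0:
        return odds, 1.0
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = _log_binom(r1, k) + _log_binom(c + d, c1 - k) - _log_binom(n, c1)
    log_obs = logp[a - lo]
    keep = logp <= log_obs + math.log1p(_REL_TOL)
    p = float(np.exp(logp[keep]).sum())
    return odds, min(p, 1.0)


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U statistic with a two-sided p-value.

    ``method`` records the evaluation path ("exact", "normal-approx",
    "degenerate"); ``direction`` is median(x) - median(y), the sign of the
    shift the test detected.
    """

    u: float
    p: float
    method: str
    direction: float
    n_x: int
    n_y: int


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets of size n1 of ranks 1..n1+n2 by rank sum, returned
    as the distribution of U = ranksum - n1(n1+1)/2 over 0..n1*n2."""
    n = n1 + n2
    max_u = n1 * n2
    # dp[j][u]: number of ways to pick j ranks so far with U-sum u
    dp = np.zeros((n1 + 1, max_u + 1))
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n1), 0, -1):
            # adding `rank` as the j-th smallest chosen rank contributes
            # (rank - j) to U
            contrib = rank - j
            if contrib > max_u:
                continue
            dp[j, contrib:] += dp[j - 1, : max_u + 1 - contrib]
    return dp[n1]


def rank_sum_test(x, y, exact_max_n: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    U is computed from midranks.  The exact null distribution (full
    enumeration over the C(n1+n2, n1) labelings, evaluated by dynamic
    programming) is used whenever both samples have <= ``exact_max_n``
    observations and there are no ties; otherwise a normal approximation
    with tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("rank_sum_test: both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    direction = float(np.median(x) - np.median(y))
    if np.all(pooled == pooled[0]):
        logger.warning("rank_sum_test: zero variance in pooled sample; p = 1.0")
        return RankSumResult(u=n1 * n2 / 2, p=1.0, method="degenerate",
                             direction=0.0, n_x=n1, n_y=n2)
    ranks = rankdata(pooled)  # average ranks for ties
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 <= exact_max_n and n2 <= exact_max_n:
        dist = _exact_u_distribution(n1, n2)
        total = dist.sum()
        ui = int(round(u))
        cdf = dist[: ui + 1].sum() / total
        sf = dist[ui:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return RankSumResult(u=u, p=p, method="exact", direction=direction,
                             n_x=n1, n_y=n2)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return RankSumResult(u=u, p=1.0, method="degenerate", direction=direction,
                             n_x=n1, n_y=n2)
    # continuity correction: shrink |U - mean| by 0.5
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / math.sqrt(var_u)
    p = float(2.0 * norm.sf(abs(z)))
    return RankSumResult(u=u, p=min(p, 1.0), method="normal-approx",
                         direction=direction, n_x=n1, n_y=n2)
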