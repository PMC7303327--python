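"""Mann-Whitney U comparison of two independent groups.

Conventions are stated explicitly because different packages differ: ties
get midranks, U is the smaller of the two one-sided statistics, the normal
approximation uses the tie-corrected variance and a 0.5 continuity
correction, and for small problems (n1*n2 <= 400) the two-sided p-value is
exact — computed from the full permutation distribution of the rank sum via
a subset-sum dynamic program over the (doubled, hence integer) midranks,
with p = 2 * min(P(U <= u), P(U >= u)) capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["GroupSummary", "GroupComparison", "mann_whitney", "compare_groups"]

EXACT_MAX_N1N2 = 400


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass
class GroupComparison:
    metric: str
    group_a: GroupSummary
    group_b: GroupSummary
    u: float
    z: float
    p: float
    method: str  # "exact" | "normal"


def _summary(values: np.ndarray) -> GroupSummary:
    q25, q75 = np.percentile(values, [25.0, 75.0])  # linear interpolation
    return GroupSummary(
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        median=float(np.median(values)),
        iqr_low=float(q25),
        iqr_high=float(q75),
    )


def _exact_rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Counts of n1-subsets of the pooled ranks by doubled rank sum.

    Midranks are half-integers, so doubling makes every rank an integer and
    the distribution a plain subset-sum count.  Entry ``s`` of the returned
    vector is the number of ways to pick ``n1`` pooled observations whose
    doubled ranks sum to ``s``.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(min(n1, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n1]


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, str]:
    """U (the smaller one-sided statistic), Z, two-sided p and the method used."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all pooled values identical: no ordering information at all
        return u, 0.0, 1.0, "degenerate"
    cc = 0.5 if u < mu else (-0.5 if u > mu else 0.0)
    z = (u - mu + cc) / np.sqrt(var)

    if n1 * n2 <= EXACT_MAX_N1N2:
        doubled = np.rint(2.0 * ranks).astype(int)
        dist = _exact_rank_sum_distribution(doubled, n1)
        total = dist.sum()
        # doubled rank-sum value equivalent to the observed U1
        s_obs = int(round(2.0 * r1))
        sums = np.arange(dist.size)
        p_low = dist[sums <= s_obs].sum() / total
        p_high = dist[sums >= s_obs].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return u, float(z), float(p), "exact"

    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return u, float(z), p, "normal"


def compare_groups(a, b, metric: str = "") -> GroupComparison:
    """Full two-group comparison: summaries plus the Mann-Whitney test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    u, z, p, method = mann_whitney(a, b)
    return GroupComparison(
        metric=metric,
        group_a=_summary(a),
        group_b=_summary(b),
        u=float(u),
        z=float(z),
        p=float(p),
        method=method,
    )
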