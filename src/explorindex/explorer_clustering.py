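"""Exact one-dimensional k-means over Exploration Indexes.

On scalar data the k-means objective is minimized by a partition that is
contiguous in sorted order, so the global optimum can be found by dynamic
programming over cut positions — no random initialization, no seeds, and
the optimal 2-cluster partition is always a threshold rule.  A direct
consequence: the Mann-Whitney U between the two clusters of an optimal
2-partition always equals n1*n2 in the upper orientation (every high-group
value exceeds every low-group value) and 0 in the lower orientation.

The number of clusters is chosen by the elbow method, formalized as the k
maximizing the discrete second difference of the within-cluster sum of
squares curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exploration_metrics import MetricProfile
from .inferential_models import RankTestResult, mann_whitney_u

__all__ = [
    "ClusterResult",
    "kmeans_1d",
    "select_k_elbow",
    "cluster_index_values",
    "partition_explorers",
]


@dataclass
class ClusterResult:
    """Explorer-class partition with the evidence used to select it."""

    k_selected: int
    assignments: dict[str, str]  # individual_id -> "high"/"low" (k=2) or "c1".."ck"
    wcss_by_k: dict[int, float]
    cluster_means: dict[str, float]
    cluster_sds: dict[str, float]
    cluster_ranges: dict[str, tuple[float, float]]
    cluster_sizes: dict[str, int]
    u_statistic: Optional[float] = None  # high-group orientation, k=2 only
    u_min: Optional[float] = None
    p_value: Optional[float] = None
    note: str = ""


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-SS of sorted[i:j] via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return max(0.0, s2 - s * s / n)


def kmeans_1d(values: Sequence[float], k: int) -> tuple[np.ndarray, float]:
    """Globally optimal 1-D k-means by dynamic programming.

    Returns integer labels (0..k-1, ordered by cluster mean ascending) in the
    original order of ``values``, and the total within-cluster sum of
    squares.  Requires k <= number of distinct values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a nonempty 1-D vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct values ({n_distinct})")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    prefix = np.concatenate([[0.0], np.cumsum(xs)])
    prefix2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    # dp[m][j] = best cost of partitioning xs[:j] into m clusters
    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = np.inf, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + _segment_cost(prefix, prefix2, i, j)
                if c < best:
                    best, arg = c, i
            dp[m, j] = best
            back[m, j] = arg
    # recover cut positions
    cuts = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        cuts.append((i, j))
        j = i
    cuts.reverse()
    labels_sorted = np.empty(n, dtype=int)
    for lab, (i, j) in enumerate(cuts):
        labels_sorted[i:j] = lab  # ascending in value => ascending mean
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(dp[k, n])


def select_k_elbow(values: Sequence[float], k_max: int = 6) -> tuple[int, dict[int, float]]:
    """Choose k by the elbow of the WCSS curve.

    Computes WCSS for k = 1..k_max and selects the k in 2..k_max-1 that
    maximizes the discrete second difference
    wcss(k-1) - 2*wcss(k) + wcss(k+1); ties break toward smaller k.
    Constant input returns k = 1.
    """
    x = np.asarray(values, dtype=float)
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    if x.size < k_max:
        raise ValueError(f"need at least k_max={k_max} values, got {x.size}")
    n_distinct = np.unique(x).size
    if n_distinct == 1:
        return 1, {1: 0.0}
    k_hi = min(k_max, n_distinct)
    wcss = {k: kmeans_1d(x, k)[1] for k in range(1, k_hi + 1)}
    if k_hi < 3:
        return k_hi, wcss
    best_k, best_curv = None, -np.inf
    for k in range(2, k_hi):
        curv = wcss[k - 1] - 2 * wcss[k] + wcss[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return int(best_k), wcss


def cluster_index_values(
    values: Sequence[float],
    ids: Optional[Sequence[str]] = None,
    k_max: int = 6,
) -> ClusterResult:
    """Elbow-selected exact k-means on scalar index values.

    When k = 2 is selected, clusters are labeled ``high``/``low`` by mean
    and compared with a Mann-Whitney U test; the reported ``u_statistic``
    is for the high group (its complement ``u_min`` is the other
    orientation of the same perfectly separated comparison).
    """
    x = np.asarray(values, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(x.size)]
    if len(ids) != x.size:
        raise ValueError("ids must match values in length")
    k, wcss_by_k = select_k_elbow(x, k_max=max(3, min(k_max, x.size)))
    labels, _ = kmeans_1d(x, k)

    if k == 2:
        names = {0: "low", 1: "high"}
    else:
        names = {j: f"c{j + 1}" for j in range(k)}
    assignments = {iid: names[lab] for iid, lab in zip(ids, labels)}
    means, sds, ranges, sizes = {}, {}, {}, {}
    for j in range(k):
        vals = x[labels == j]
        nm = names[j]
        means[nm] = float(vals.mean())
        sds[nm] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        ranges[nm] = (float(vals.min()), float(vals.max()))
        sizes[nm] = int(vals.size)
    result = ClusterResult(
        k_selected=k,
        assignments=assignments,
        wcss_by_k=wcss_by_k,
        cluster_means=means,
        cluster_sds=sds,
        cluster_ranges=ranges,
        cluster_sizes=sizes,
        note="" if k != 1 else "constant or unimodal input; no elbow at k >= 2",
    )
    if k == 2:
        rt: RankTestResult = mann_whitney_u(x[labels == 1], x[labels == 0])
        # orient U toward the high group: with contiguous optimal clusters the
        # high group wins every pairwise comparison, so U_high = n1*n2
        n1, n2 = sizes["high"], sizes["low"]
        from scipy.stats import rankdata

        r_high = float(rankdata(x)[labels == 1].sum())
        u_high = r_high - n1 * (n1 + 1) / 2
        result.u_statistic = u_high
        result.u_min = n1 * n2 - u_high
        result.p_value = rt.p_value
    return result


def partition_explorers(profiles: list[MetricProfile], k_max: int = 6) -> ClusterResult:
    """Cluster individuals into explorer classes by their Exploration Index."""
    if len(profiles) < 4:
        raise ValueError("need >= 4 profiles to partition explorer classes")
    if any(p.exploration_index is None for p in profiles):
        raise ValueError("profiles lack exploration_index; run exploration_index() first")
    values = [p.exploration_index for p in profiles]
    ids = [p.individual_id for p in profiles]
    return cluster_index_values(values, ids, k_max=min(k_max, len(profiles)))
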