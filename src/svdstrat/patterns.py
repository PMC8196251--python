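"""Hierarchical clustering of statistic-map spatial patterns.

Unthresholded statistic maps are vectorized over the analysis mask,
compared by Pearson correlation, converted to 1 - r distances, merged by
unweighted average linkage, and the cluster count is chosen by the
Calinski-Harabasz criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PatternVector",
    "ClusterSolution",
    "vectorize_statmaps",
    "pattern_distance",
    "average_linkage",
    "cut_linkage",
    "calinski_harabasz",
    "select_k_calinski",
]

_DEGENERATE_DISTANCE = 1e-8


@dataclass(frozen=True)
class PatternVector:
    """Ordered in-mask statistic values for one subtype's alteration map."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 3:
            raise ValueError("pattern vector needs >= 3 voxels")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"pattern {self.label!r} has non-finite values")
        if np.ptp(values) == 0:
            raise ValueError(f"pattern {self.label!r} has zero variance")


@dataclass(frozen=True)
class ClusterSolution:
    """Outcome of the pattern-clustering procedure.

    ``selected_k`` is None on the degenerate path (all patterns
    indistinguishable), with ``degenerate=True``.
    """

    labels: tuple[str, ...]
    distances: np.ndarray
    linkage: np.ndarray
    ch_by_k: dict[int, float]
    selected_k: int | None
    membership: dict[str, int] | None
    degenerate: bool = False


def vectorize_statmaps(
    statmaps: Sequence[tuple[str, np.ndarray]] | dict[str, np.ndarray],
    mask: np.ndarray,
) -> list[PatternVector]:
    """Extract in-mask values from each labelled 3D map, in a shared,
    fixed voxel order (C-order scan of the mask)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    items = statmaps.items() if isinstance(statmaps, dict) else statmaps
    vectors = []
    for label, arr in items:
        arr = np.asarray(arr, float)
        if arr.shape != mask.shape:
            raise ValueError(
                f"map {label!r} grid {arr.shape} does not match mask {mask.shape}"
            )
        vectors.append(PatternVector(label=label, values=arr[mask]))
    return vectors


def pattern_distance(vectors: Sequence[PatternVector]) -> np.ndarray:
    """Pairwise 1 - Pearson r distance matrix (symmetric, zero diagonal,
    entries in [0, 2])."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 pattern vectors")
    lengths = {v.values.size for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"pattern vectors differ in length: {sorted(lengths)}")
    data = np.stack([v.values for v in vectors])
    corr = np.corrcoef(data)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def average_linkage(distances: np.ndarray) -> np.ndarray:
    """Agglomerative merges by unweighted average inter-cluster distance.

    Returns a linkage matrix in the standard (n-1) x 4 layout: the two
    merged cluster ids (originals 0..n-1, then n, n+1, ... for merged
    clusters), the merge height, and the new cluster's size. Ties are
    broken by the lowest pair of cluster ids.
    """
    D = np.asarray(distances, float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    # active clusters: id -> member indices
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                members_a, members_b = active[a], active[b]
                d = D[np.ix_(members_a, members_b)].mean()
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        Z[step] = (a, b, d, len(active[a]) + len(active[b]))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return Z


def cut_linkage(linkage: np.ndarray, n_items: int, k: int) -> np.ndarray:
    """Flat cluster membership (0..k-1, relabelled by first occurrence)
    after undoing the last k-1 merges."""
    if not 1 <= k <= n_items:
        raise ValueError(f"k={k} out of range for {n_items} items")
    parent = list(range(n_items + len(linkage)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n_items - k):
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        new = n_items + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n_items)]
    relabel: dict[int, int] = {}
    out = np.empty(n_items, int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    return out


def calinski_harabasz(data: np.ndarray, membership: np.ndarray) -> float:
    """Between/within dispersion ratio, each normalized by its degrees of
    freedom; dispersion is the sum of squared Euclidean distances to the
    relevant centroid."""
    data = np.asarray(data, float)
    membership = np.asarray(membership, int)
    n = data.shape[0]
    ks = np.unique(membership)
    k = ks.size
    if not 1 < k < n:
        raise ValueError(f"k must lie in (1, n); got k={k}, n={n}")
    grand = data.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in ks:
        sub = data[membership == g]
        centroid = sub.mean(axis=0)
        between += sub.shape[0] * float(np.sum((centroid - grand) ** 2))
        within += float(np.sum((sub - centroid) ** 2))
    if within == 0.0:
        return np.inf if between > 0 else np.nan
    return (between / (k - 1)) / (within / (n - k))


def select_k_calinski(
    vectors: Sequence[PatternVector],
    candidate_ks: Sequence[int] | None = None,
) -> ClusterSolution:
    """Full procedure: 1-r distances, average-linkage tree, CH values per
    candidate k, argmax selection (ties to the smallest k).

    With n=4 subtype patterns the valid candidates are {2, 3}. When all
    patterns are indistinguishable (every distance below 1e-8) the
    degenerate path is reported and no k is selected.
    """
    n = len(vectors)
    if n < 3:
        raise ValueError("need >= 3 patterns to select a cluster count")
    if candidate_ks is None:
        candidate_ks = range(2, n)
    candidate_ks = sorted(set(int(k) for k in candidate_ks))
    if any(k < 2 or k > n - 1 for k in candidate_ks):
        raise ValueError(f"candidate ks must lie in [2, {n - 1}]")

    labels = tuple(v.label for v in vectors)
    D = pattern_distance(vectors)
    Z = average_linkage(D)
    data = np.stack([v.values for v in vectors])

    off_diag = D[~np.eye(n, dtype=bool)]
    if np.all(off_diag < _DEGENERATE_DISTANCE):
        return ClusterSolution(
            labels=labels, distances=D, linkage=Z,
            ch_by_k={}, selected_k=None, membership=None, degenerate=True,
        )

    ch_by_k: dict[int, float] = {}
    memberships: dict[int, np.ndarray] = {}
    for k in candidate_ks:
        member = cut_linkage(Z, n, k)
        memberships[k] = member
        ch_by_k[k] = calinski_harabasz(data, member)

    finite = {k: v for k, v in ch_by_k.items() if np.isfinite(v) or v == np.inf}
    if not finite or all(np.isnan(v) for v in ch_by_k.values()):
        return ClusterSolution(
            labels=labels, distances=D, linkage=Z,
            ch_by_k=ch_by_k, selected_k=None, membership=None, degenerate=True,
        )
    best_ch = max(finite.values())
    selected_k = min(k for k, v in finite.items() if v == best_ch)
    membership = {
        label: int(c) for label, c in zip(labels, memberships[selected_k])
    }
    return ClusterSolution(
        labels=labels, distances=D, linkage=Z,
        ch_by_k=ch_by_k, selected_k=selected_k, membership=membership,
    )
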