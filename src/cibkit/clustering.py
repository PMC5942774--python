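"""Hierarchical clustering of strains by category-wise mean-CIB profiles.

Distances are Pearson correlation distances (1 - r) with pairwise deletion
of missing categories; merging uses unweighted average linkage on the
distance matrix, with a deterministic lexicographic tie-break so reruns
and input reorderings give isomorphic trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedDistanceError(ValueError):
    """Correlation distance undefined (constant vector or too few pairs)."""


@dataclass
class Dendrogram:
    """Agglomerative merge history over named leaves.

    ``merges`` lists ``(cluster_a, cluster_b, height, size)`` in merge
    order, where cluster names are leaf labels or previously created
    internal names; heights are non-decreasing under average linkage on a
    proper distance matrix.
    """

    merges: list[tuple[str, str, float, int]]
    leaves: list[str]

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (height / 2)."""
        node_repr: dict[str, str] = {leaf: leaf for leaf in self.leaves}
        node_height: dict[str, float] = {leaf: 0.0 for leaf in self.leaves}
        name = ""
        for i, (a, b, height, _size) in enumerate(self.merges):
            name = f"n{i}"
            bl_a = (height - node_height[a]) / 2.0
            bl_b = (height - node_height[b]) / 2.0
            node_repr[name] = f"({node_repr[a]}:{bl_a:.6g},{node_repr[b]}:{bl_b:.6g})"
            node_height[name] = height
        root = node_repr[name] if self.merges else self.leaves[0]
        return f"{root};"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["cluster_a", "cluster_b", "height", "size"])

    def leaf_partitions(self) -> list[frozenset[str]]:
        """Leaf set of each internal node, in merge order."""
        members: dict[str, frozenset[str]] = {l: frozenset([l]) for l in self.leaves}
        out = []
        for i, (a, b, _h, _s) in enumerate(self.merges):
            merged = members[a] | members[b]
            members[f"n{i}"] = merged
            out.append(merged)
        return out


def correlation_distance(u, v) -> float:
    """Pearson correlation distance 1 - r in [0, 2].

    Positions with a missing value (NaN) in either vector are dropped
    before computing; at least 3 complete pairs are required and both
    vectors must be non-constant on them.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(u) | np.isnan(v))
    u, v = u[keep], v[keep]
    if u.size < 3:
        raise UndefinedDistanceError(
            f"only {u.size} complete pairs; need at least 3"
        )
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedDistanceError("zero-variance vector")
    r = stats.pearsonr(u, v).statistic
    return float(1.0 - r)


def _pairwise_distances(profiles: pd.DataFrame) -> np.ndarray:
    labels = list(profiles.index)
    n = len(labels)
    d = np.zeros((n, n))
    values = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = correlation_distance(values[i], values[j])
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"distance undefined for strains {labels[i]!r} and "
                    f"{labels[j]!r}: {exc}"
                ) from None
    return d


def average_linkage_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Cluster strains (rows) by correlation distance, average linkage.

    ``profiles`` is a strain x category matrix of mean CIB; NaN cells are
    handled by pairwise deletion inside each distance. Unweighted average
    linkage: the distance between clusters is the mean over all inter-
    cluster leaf pairs. Ties are broken toward the lexicographically
    smallest (sorted) pair of cluster names, so the result is independent
    of input row order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 strains to cluster")
    labels = [str(l) for l in profiles.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strain labels")
    d = _pairwise_distances(profiles)

    clusters: dict[str, list[int]] = {lab: [i] for i, lab in enumerate(labels)}
    merges: list[tuple[str, str, float, int]] = []
    counter = 0
    while len(clusters) > 1:
        best = None
        names = sorted(clusters)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ia, ib = clusters[a], clusters[b]
                dist = d[np.ix_(ia, ib)].mean()
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        name = f"n{counter}"
        counter += 1
        clusters[name] = merged
        merges.append((a, b, float(dist), len(merged)))
    return Dendrogram(merges=merges, leaves=labels)
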