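"""Cross-dataset agreement: distance matrix + hierarchical clustering.

Each predictor dataset (glycoprotein, MRM, RPPA, mRNA, ...) yields a vector
of per-drug cross-validation correlations.  Datasets are compared by the
Euclidean distance between those vectors over the drugs each pair shares
(pairwise-complete), and the distance matrix is clustered agglomeratively
into a dendrogram, serialized as newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ComparisonError(ValueError):
    pass


def build_distance_matrix(perf: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Euclidean distances between dataset rows.

    ``perf`` is datasets x drugs with NaN where a drug is absent; every pair
    of datasets must share at least 2 drugs.
    """
    if perf.shape[0] < 2:
        raise ComparisonError("need at least 2 datasets")
    present = perf.notna().to_numpy()
    values = perf.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.max() > 1 + 1e-9 or finite.min() < -1 - 1e-9):
        raise ComparisonError("correlations must lie in [-1, 1]")
    m = perf.shape[0]
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            shared = present[i] & present[j]
            if shared.sum() < 2:
                raise ComparisonError(
                    f"datasets {perf.index[i]!r} and {perf.index[j]!r} share fewer than 2 drugs"
                )
            diff = values[i, shared] - values[j, shared]
            dist[i, j] = dist[j, i] = float(np.sqrt(np.sum(diff**2)))
    return pd.DataFrame(dist, index=perf.index, columns=perf.index)


@dataclass
class _Cluster:
    members: tuple[str, ...]   # sorted leaf labels
    height: float
    newick: str


@dataclass
class DendrogramTree:
    """Agglomerative merge tree with newick serialization."""

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    newick: str


_LINKAGES = {
    "complete": max,
    "single": min,
    "average": None,
}


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "complete") -> DendrogramTree:
    """Agglomerative clustering of a distance matrix.

    At each step the pair of clusters with minimal linkage distance merges;
    exact ties break toward the lexicographically smallest (sorted) label
    pair.  Branch lengths in the newick output place each leaf at depth
    height/2 of its subtree root (ultrametric convention).
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    values = dist.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ComparisonError("distance matrix must be square")
    if not np.allclose(values, values.T):
        raise ComparisonError("distance matrix must be symmetric")
    if np.any(values < 0) or not np.allclose(np.diag(values), 0):
        raise ComparisonError("distances must be non-negative with zero diagonal")

    labels = [str(x) for x in dist.index]
    clusters: dict[tuple[str, ...], _Cluster] = {
        (lab,): _Cluster((lab,), 0.0, lab) for lab in labels
    }
    leaf_pos = {lab: i for i, lab in enumerate(labels)}

    def cluster_distance(a: _Cluster, b: _Cluster) -> float:
        pair_d = [
            values[leaf_pos[x], leaf_pos[y]] for x in a.members for y in b.members
        ]
        if linkage == "complete":
            return float(max(pair_d))
        if linkage == "single":
            return float(min(pair_d))
        return float(np.mean(pair_d))

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = clusters[keys[i]], clusters[keys[j]]
                d = cluster_distance(a, b)
                tie_key = tuple(sorted((keys[i], keys[j])))
                if best is None or d < best[0] - 1e-12:
                    best = (d, tie_key, keys[i], keys[j])
                elif abs(d - best[0]) <= 1e-12 and tie_key < best[1]:
                    best = (d, tie_key, keys[i], keys[j])
        d, _, ka, kb = best
        a, b = clusters.pop(ka), clusters.pop(kb)
        merged_members = tuple(sorted(a.members + b.members))
        bl_a = d / 2.0 - a.height / 2.0
        bl_b = d / 2.0 - b.height / 2.0
        newick = f"({a.newick}:{bl_a:.6g},{b.newick}:{bl_b:.6g})"
        clusters[merged_members] = _Cluster(merged_members, d, newick)
        merges.append((a.members, b.members, float(d)))

    root = next(iter(clusters.values()))
    return DendrogramTree(leaves=labels, merges=merges, newick=root.newick + ";")


def are_siblings(tree: DendrogramTree, a: str, b: str) -> bool:
    """True if leaves a and b merge with each other before anything else."""
    for left, right, _ in tree.merges:
        involved = a in left + right or b in left + right
        if involved:
            return (left, right) in (((a,), (b,)), ((b,), (a,)))
    return False
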