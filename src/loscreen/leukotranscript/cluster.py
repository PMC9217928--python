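"""Average-linkage (UPGMA) hierarchical clustering of samples.

Samples are clustered on euclidean distances between their normalized count
profiles.  At each step the pair of clusters with the smallest average
inter-cluster distance is merged and the merge height recorded; average
linkage is reducible, so heights are non-decreasing.  Ties are broken by the
lexicographically smallest pair of cluster representatives (each cluster
represented by its smallest original leaf index), which makes the merge
sequence — and the exported Newick string — fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import Dendrogram


def hierarchical_cluster(
    matrix: np.ndarray, sample_ids: list[str] | None = None
) -> Dendrogram:
    """UPGMA dendrogram of the columns (samples) of ``matrix``.

    ``matrix`` is genes x samples (as produced by :func:`normalize`); the
    euclidean distance is taken between sample columns over all genes.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite entries in the clustering input")
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(n)]

    dist = squareform(pdist(matrix.T, metric="euclidean"))
    # active cluster state: id -> (representative leaf, size)
    rep = {i: i for i in range(n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    # Lance-Williams update of average distances
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]

    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (min(rep[i], rep[j]), max(rep[i], rep[j]))
                cand = (d[(i, j)], key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        height, _, ci, cj = best
        merges.append((ci, cj, float(height), size[ci] + size[cj]))

        for k in active:
            if k in (ci, cj):
                continue
            dik = d[(min(ci, k), max(ci, k))]
            djk = d[(min(cj, k), max(cj, k))]
            dnew = (size[ci] * dik + size[cj] * djk) / (size[ci] + size[cj])
            d[(min(k, next_id), max(k, next_id))] = dnew
        rep[next_id] = min(rep[ci], rep[cj])
        size[next_id] = size[ci] + size[cj]
        active.discard(ci)
        active.discard(cj)
        active.add(next_id)
        next_id += 1

    return Dendrogram(leaf_labels=list(sample_ids), merges=merges)


def to_newick(dendrogram: Dendrogram, decimals: int = 6) -> str:
    """Newick string with branch lengths = height differences between nodes."""
    n = len(dendrogram.leaf_labels)
    height = {i: 0.0 for i in range(n)}
    subtree = {i: dendrogram.leaf_labels[i] for i in range(n)}
    node = n
    for left, right, h, _ in dendrogram.merges:
        bl_l = h - height[left]
        bl_r = h - height[right]
        subtree[node] = (
            f"({subtree[left]}:{bl_l:.{decimals}f},{subtree[right]}:{bl_r:.{decimals}f})"
        )
        height[node] = h
        node += 1
    return subtree[node - 1] + ";"
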