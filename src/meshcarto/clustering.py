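"""Grouping a region's images into individual crystals.

Hierarchical agglomerative clustering with a modified average linkage: the
inter-cluster distance is the weighted mean of cross-pair distance scores,
where pairs of images taken at goniometer angles differing by more than an
omega gate (default 0.5 degrees) receive zero weight — such pairs see
genuinely different slices of reciprocal space, so their D carries no
information about whether the images share a lattice.  When no cross pair
is comparable the distance falls back to the ray gate (0.1 degrees,
maximally dissimilar), so incomparable clusters are never merged below the
cutoff.  Flat crystals are read off the dendrogram at a fixed linkage
cutoff (default 0.093 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import Region

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "weighted_average_linkage",
    "cut_dendrogram",
    "assign_crystal_ids",
]


@dataclass
class Dendrogram:
    """Merge history in scipy linkage-matrix layout.

    ``merges`` has one row per merge: (cluster_i, cluster_j, linkage
    distance in degrees, new cluster size); original observations are
    clusters 0..n-1 and the merge at row m creates cluster n+m.
    """

    n_leaves: int
    merges: np.ndarray  # (n_leaves - 1, 4)

    def linkage_matrix(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)


@dataclass
class ClusterAssignment:
    """Per-node crystal label (1..k) within one region."""

    labels: np.ndarray  # (n_leaves,) int, contiguous from 1

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def _square(condensed: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = condensed
    return out + out.T


def weighted_average_linkage(
    condensed: np.ndarray,
    omegas: np.ndarray,
    omega_gate: float = 0.5,
    fallback: float = 0.1,
) -> Dendrogram:
    """Agglomerative clustering with omega-gated weighted average linkage.

    The distance between clusters A and B is
    sum(w_ij * D_ij) / sum(w_ij) over cross pairs, with w_ij = 1 when
    |omega_i - omega_j| <= omega_gate and 0 otherwise; if every cross pair
    is gated out the distance is ``fallback``.  With all weights 1 this
    reduces exactly to textbook (unweighted) average linkage.  Ties are
    broken by the smallest (i, j) cluster-index pair, making the merge
    order deterministic.
    """
    omegas = np.asarray(omegas, dtype=float)
    n = len(omegas)
    if n == 0:
        raise ValueError("empty region")
    if n == 1:
        return Dendrogram(n_leaves=1, merges=np.empty((0, 4)))
    condensed = np.asarray(condensed, dtype=float)
    if len(condensed) != n * (n - 1) // 2:
        raise ValueError("condensed matrix length does not match omegas")

    d = _square(condensed, n)
    w = (np.abs(omegas[:, None] - omegas[None, :]) <= omega_gate).astype(float)
    np.fill_diagonal(w, 0.0)
    # running sums over cross pairs between current clusters
    wd = w * d
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))  # positions into wd/w rows
    cluster_id = list(range(n))  # scipy-style id of each active cluster
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        act = np.asarray(active)
        wa = w[np.ix_(act, act)]
        da = np.where(wa > 0, wd[np.ix_(act, act)] / np.where(wa > 0, wa, 1.0),
                      fallback)
        iu = np.triu_indices(len(act), k=1)
        dists = da[iu]
        dist = dists.min()
        # deterministic tie-break: smallest (cluster_id_i, cluster_id_j)
        tied = np.flatnonzero(dists == dist)
        ids = np.asarray(cluster_id)
        keys = sorted(
            (min(ids[iu[0][t]], ids[iu[1][t]]),
             max(ids[iu[0][t]], ids[iu[1][t]]), t)
            for t in tied
        )
        t = keys[0][2]
        ai, aj = int(iu[0][t]), int(iu[1][t])
        i, j = active[ai], active[aj]
        new_size = sizes[i] + sizes[j]
        merges[step] = (cluster_id[ai], cluster_id[aj], dist, new_size)
        # fold cluster j's sums into i, retire j
        wd[i, :] += wd[j, :]
        wd[:, i] = wd[i, :]
        w[i, :] += w[j, :]
        w[:, i] = w[i, :]
        sizes[i] = new_size
        cluster_id[ai] = n + step
        del active[aj], cluster_id[aj]
    return Dendrogram(n_leaves=n, merges=merges)


def cut_dendrogram(dendrogram: Dendrogram, d_cutoff: float) -> ClusterAssignment:
    """Flat clusters: maximal merges with linkage distance < d_cutoff.

    Labels are contiguous 1..k, numbered by each cluster's smallest leaf.
    """
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1 if n > 1 else 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (ci, cj, dist, _) in enumerate(dendrogram.merges):
        if dist < d_cutoff:
            new = n + step
            parent[find(int(ci))] = new
            parent[find(int(cj))] = new

    roots: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots) + 1
        labels[leaf] = roots[root]
    return ClusterAssignment(labels=labels)


def assign_crystal_ids(
    region_assignments: list[tuple[Region, ClusterAssignment]],
) -> dict[int, list[tuple[int, int]]]:
    """Combine per-region clusters into globally numbered crystals.

    Returns {crystal_id: [(row, col), ...]} with ids 1..K assigned in
    region order then cluster-label order; singleton clusters are kept.
    """
    crystals: dict[int, list[tuple[int, int]]] = {}
    next_id = 1
    for region, assignment in region_assignments:
        for label in range(1, assignment.n_clusters + 1):
            members = [
                node
                for node, lab in zip(region.nodes, assignment.labels)
                if lab == label
            ]
            crystals[next_id] = members
            next_id += 1
    return crystals
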