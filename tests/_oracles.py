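"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: exhaustive enumeration
for the rank-sum null, naive agglomeration for average linkage, a per-voxel
membership scan for cube/mask assignment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, with U the
    Mann-Whitney statistic of the first group, enumerated over all
    C(n+m, n) equally likely assignments of the pooled values.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = _u_stat(x, y)
    us = []
    idx = np.arange(len(pooled))
    for sel in combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(sel)] = True
        us.append(_u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _u_stat(x, y) -> float:
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return u


def permutation_p_exhaustive(x, y) -> float:
    """Two-sided mean-difference permutation p over all label splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = abs(x.mean() - y.mean())
    hits = total = 0
    for sel in combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(sel)] = True
        d = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if d >= obs - 1e-12 * (1.0 + obs):
            hits += 1
    return hits / total


def average_linkage_clusters(dist: np.ndarray, t: int) -> list[frozenset]:
    """Naive O(n^3) average-linkage agglomeration down to ``t`` clusters.

    ``dist`` is a square distance matrix. Cluster-pair distance is the mean
    of all member-pair distances (UPGMA). Returns the partition as a list
    of frozensets of row indices.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > t:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [dist[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return [frozenset(c) for c in clusters]


def cube_overlap_scan(
    centroid_um, label_volume, voxel_size_um, z_offset_um=5.0
) -> dict[int, int]:
    """Per-region cube overlap by scanning every voxel of the volume.

    The cube membership test is geometric: a voxel (i, j, k) belongs to the
    neuron's cube when it lies within +-2 (x, y) / +-1 (z) voxels of the
    voxel containing the offset centroid.
    """
    pos = np.asarray(centroid_um, float).copy()
    pos[2] += z_offset_um
    cv = np.floor(pos / np.asarray(voxel_size_um)).astype(int)
    counts: dict[int, int] = {}
    nx, ny, nz = label_volume.shape
    if np.any(cv < 0) or np.any(cv >= (nx, ny, nz)):
        return counts
    for i in range(nx):
        if abs(i - cv[0]) > 2:
            continue
        for j in range(ny):
            if abs(j - cv[1]) > 2:
                continue
            for k in range(nz):
                if abs(k - cv[2]) > 1:
                    continue
                lab = int(label_volume[i, j, k])
                if lab:
                    counts[lab] = counts.get(lab, 0) + 1
    return counts
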