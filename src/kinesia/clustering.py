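"""Motor-associated clustering and region-pair connectivity.

Neuronal 1-Hz activity traces are clustered together with the tail-angle
trace using hierarchical average-linkage clustering on Spearman distance
(1 - rank correlation). The cluster containing the tail row is the
motor-associated cluster; its size is tracked while the requested cluster
count grows from t = 3, and iteration stops the first time the cluster
would lose more than 20% of its neurons, keeping the previous assignment.
Connectivity between two regions is the percentage of cross-region neuron
pairs whose Spearman correlation exceeds 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata


@dataclass
class ClusterPartition:
    motor: np.ndarray  # bool per neuron (tail row excluded)
    t_final: int
    iteration_trace: list[tuple[int, int]]  # (t, motor-cluster size)
    tail_corr: np.ndarray  # Spearman rho of each neuron with the tail


@dataclass
class ConnectivityEntry:
    region_a: str
    region_b: str
    n_pairs_total: int
    n_pairs_above: int
    connectivity_pct: float


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    """Z-score each row over time, then rescale it to [0, 1]."""
    m = np.asarray(mat, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    lo = z.min(axis=1, keepdims=True)
    rng = np.ptp(z, axis=1, keepdims=True)
    return np.where(rng > 0, (z - lo) / np.where(rng > 0, rng, 1.0), 0.0)


def spearman_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Condensed pairwise distance 1 - Spearman rho (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 1, np.asarray(rows, float))
    return pdist(ranks, metric="correlation")


def motor_partition(
    activity: np.ndarray,
    tail_trace_1hz: np.ndarray,
    t0: int = 3,
    stability: float = 0.2,
    max_t: int | None = None,
    crop: tuple[int, int] | None = None,
) -> ClusterPartition:
    """Split neurons into motor-associated and non-motor sets.

    ``activity`` is (n_neurons, T) at 1 Hz; ``tail_trace_1hz`` is the
    max-resampled tail angle over the same frames. Rows are z-scored then
    scaled to [0, 1], the tail row (|angle|, normalized) is appended last,
    and one average-linkage tree is built on Spearman distance. The tree is
    cut at t = t0, t0+1, ... clusters; the size of the tail-containing
    cluster at each t is recorded, and the first cut where it would drop by
    more than ``stability`` (fraction) of the previous size stops the
    iteration, returning the previous cut's assignment.

    ``crop`` optionally restricts both matrices to a [start, stop) frame
    window (the portion of the tail movie during which the scan ran).
    """
    act = np.asarray(activity, dtype=float)
    tail = np.abs(np.asarray(tail_trace_1hz, dtype=float))
    if crop is not None:
        act = act[:, crop[0] : crop[1]]
        tail = tail[crop[0] : crop[1]]
    if act.shape[1] != tail.size:
        raise ValueError("activity and tail trace lengths differ")
    if np.ptp(tail) == 0:
        raise ValueError("tail trace is constant: Spearman ranks undefined")
    n = act.shape[0]
    mat = np.vstack([_normalize_rows(act), (tail - tail.min()) / np.ptp(tail)])
    ranks = np.apply_along_axis(rankdata, 1, mat)
    dist = pdist(ranks, metric="correlation")
    tree = linkage(dist, method="average")
    tail_row = n  # last row index
    rank_tail = ranks[tail_row]
    denom = np.linalg.norm(ranks - ranks.mean(axis=1, keepdims=True), axis=1)
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tail_corr = (centred[:n] @ centred[tail_row]) / (
            denom[:n] * denom[tail_row]
        )
    tail_corr = np.nan_to_num(tail_corr)

    if max_t is None:
        max_t = n + 1
    prev_members: np.ndarray | None = None
    prev_size = None
    trace: list[tuple[int, int]] = []
    t = t0
    while t <= max_t:
        labels = fcluster(tree, t=t, criterion="maxclust")
        members = labels == labels[tail_row]
        size = int(members[:n].sum())
        trace.append((t, size))
        if prev_size is not None and size < (1.0 - stability) * prev_size:
            return ClusterPartition(
                motor=prev_members[:n],
                t_final=t - 1,
                iteration_trace=trace,
                tail_corr=tail_corr,
            )
        prev_members, prev_size = members, size
        if size == 0:
            break
        t += 1
    return ClusterPartition(
        motor=prev_members[:n],
        t_final=t - 1 if t > t0 else t0,
        iteration_trace=trace,
        tail_corr=tail_corr,
    )


def per_region_motor_stats(
    partition: ClusterPartition,
    region_assignments: list[list[str]],
    cum_dff_z: np.ndarray,
    region_names: list[str],
) -> pd.DataFrame:
    """Motor / non-motor activity split per anatomical region.

    For every region: summed cumulative dF/F of motor and non-motor
    neurons, the motor-neuron count and fraction, and the mean tail
    correlation of the motor neurons. The two dF/F columns always add up
    to the region's total (partition additivity).
    """
    motor = partition.motor
    dff = np.asarray(cum_dff_z, dtype=float)
    rows = []
    for name in region_names:
        idx = np.array(
            [i for i, regs in enumerate(region_assignments) if name in regs],
            dtype=int,
        )
        m = idx[motor[idx]] if idx.size else idx
        nm = idx[~motor[idx]] if idx.size else idx
        n_tot = idx.size
        rows.append(
            {
                "region": name,
                "motor_cum_dff_z": float(dff[m].sum()) if m.size else 0.0,
                "nonmotor_cum_dff_z": float(dff[nm].sum()) if nm.size else 0.0,
                "n_motor": int(m.size),
                "n_total": n_tot,
                "motor_fraction": m.size / n_tot if n_tot else 0.0,
                "motor_tail_corr_mean": (
                    float(partition.tail_corr[m].mean()) if m.size else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def connectivity(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    threshold: float = 0.8,
    region_a: str = "A",
    region_b: str = "B",
) -> ConnectivityEntry:
    """Fraction of cross-region neuron pairs with Spearman rho > threshold.

    Defined on unordered cross pairs only (|A| x |B|); within-region pairs
    are never counted, and connectivity(A, B) == connectivity(B, A).
    """
    a = np.atleast_2d(np.asarray(traces_a, dtype=float))
    b = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("each region needs at least one neuron")
    ra = np.apply_along_axis(rankdata, 1, a)
    rb = np.apply_along_axis(rankdata, 1, b)

    def _centred_unit(r: np.ndarray) -> np.ndarray:
        c = r - r.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(c, axis=1, keepdims=True)
        return np.where(nrm > 0, c / np.where(nrm > 0, nrm, 1.0), 0.0)

    rho = _centred_unit(ra) @ _centred_unit(rb).T
    n_total = rho.size
    n_above = int(np.count_nonzero(rho > threshold))
    return ConnectivityEntry(
        region_a=region_a,
        region_b=region_b,
        n_pairs_total=n_total,
        n_pairs_above=n_above,
        connectivity_pct=100.0 * n_above / n_total,
    )
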