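"""Two-group comparison of brain-wide activity maps and region tables.

Per-neuron metrics (active count, z-scored cumulative dF/F, firing rate)
are accumulated into 12 x 12 x 12-um voxel heatmaps, one layer per larva.
Each voxel is compared between groups with a two-sided Wilcoxon rank-sum
test at p < 0.05 (no multiple-testing correction, by design); the
group-mean difference masked to significant voxels is then mapped onto
anatomical masks to give, per mask, the percentage of altered voxels and
the summed difference per metric and direction. The Relevance score of a
mask is the sum of the absolute values of its six summed differences
(hyper and hypo for each of the three metrics) and ranks the regions most
affected by the ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ReferenceGrid, RegionMaskSet

METRICS = ("active_count", "cum_dff_z", "firing_rate")


@dataclass
class VoxelHeatmaps:
    """Per-larva metric volumes on the downsampled grid."""

    voxel_um: float
    shape: tuple[int, int, int]
    count: np.ndarray  # (n_larvae, *shape)
    cum_dff: np.ndarray
    rate: np.ndarray  # nan where a larva has no neurons in the voxel

    def layer(self, metric: str) -> np.ndarray:
        return {"active_count": self.count, "cum_dff_z": self.cum_dff,
                "firing_rate": self.rate}[metric]


def heatmap_shape(grid: ReferenceGrid, voxel_um: float = 12.0) -> tuple[int, int, int]:
    """Downsampled grid shape: ceil(physical extent / voxel size) per axis."""
    return tuple(int(np.ceil(e / voxel_um)) for e in grid.extent_um)


def build_heatmaps(
    larvae_neurons: list[list],
    grid: ReferenceGrid,
    voxel_um: float = 12.0,
    z_offset_um: float = 5.0,
) -> VoxelHeatmaps:
    """Accumulate per-neuron metrics into one 12-um layer per larva.

    Each neuron falls into the voxel floor(position_um / voxel_um) (after
    the same +5-um z offset used for mask assignment): counts add 1,
    cumulative dF/F adds the neuron's z-score, and the rate voxel is the
    mean rate of its neurons -- nan where a larva has none, so empty voxels
    are missing rather than zero-rate.
    """
    shape = heatmap_shape(grid, voxel_um)
    L = len(larvae_neurons)
    count = np.zeros((L,) + shape)
    dff = np.zeros((L,) + shape)
    rate_sum = np.zeros((L,) + shape)
    for li, neurons in enumerate(larvae_neurons):
        for n in neurons:
            pos = np.asarray(n.centroid_um, dtype=float).copy()
            pos[2] += z_offset_um
            v = np.floor(pos / voxel_um).astype(int)
            if np.any(v < 0) or np.any(v >= shape):
                continue
            count[li][tuple(v)] += 1
            dff[li][tuple(v)] += 0.0 if n.cum_dff_z is None else n.cum_dff_z
            rate_sum[li][tuple(v)] += (
                0.0 if n.firing_rate_hz is None else n.firing_rate_hz
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(count > 0, rate_sum / np.maximum(count, 1), np.nan)
    return VoxelHeatmaps(
        voxel_um=voxel_um, shape=shape, count=count, cum_dff=dff, rate=rate
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value.

    Uses the exact null distribution when both samples have <= 10
    observations and no ties, the tie-corrected normal approximation
    otherwise. Two identical constant samples give p = 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for the difference of group means.

    All label permutations are enumerated when there are at most 20000 of
    them (the 3-vs-3 case has 20, fully exhaustive); otherwise ``n_perm``
    random permutations are drawn from ``seed`` and the p-value includes
    the observed labelling, so p >= 1/(n_perm + 1).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    total = comb(len(pooled), nx)
    eps = 1e-12 * (1.0 + obs)
    if total <= 20000:
        hits = 0
        idx = np.arange(len(pooled))
        for sel in combinations(idx, nx):
            sel = np.asarray(sel)
            mask = np.zeros(len(pooled), dtype=bool)
            mask[sel] = True
            d = abs(pooled[mask].mean() - pooled[~mask].mean())
            if d >= obs - eps:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:nx].mean() - perm[nx:].mean())
        if d >= obs - eps:
            hits += 1
    return (1 + hits) / (n_perm + 1)


@dataclass
class TwoGroupTest:
    statistic: float
    p_wilcoxon: float
    p_permutation: float | None
    p_reported: float  # max of the computed p-values


def two_group_test(
    x: np.ndarray,
    y: np.ndarray,
    with_permutation: bool = False,
    n_perm: int = 10000,
    seed: int | None = None,
) -> TwoGroupTest:
    """Rank-sum test, optionally paired with a permutation test.

    When both are computed the reported p is the larger of the two (the
    conservative choice used throughout the group comparisons).
    """
    stat, p_w = wilcoxon_rank_sum(x, y)
    p_p = permutation_test(x, y, n_perm, seed) if with_permutation else None
    p_rep = max(p_w, p_p) if p_p is not None else p_w
    return TwoGroupTest(stat, p_w, p_p, p_rep)


# ---------------------------------------------------------------------------
# voxelwise comparison
# ---------------------------------------------------------------------------


def voxelwise_test(
    heat_control: VoxelHeatmaps,
    heat_deficient: VoxelHeatmaps,
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-voxel rank-sum comparison of each metric between groups.

    Returns, per metric, a boolean significance volume and a signed
    mean-difference volume (deficient minus control) masked to significant
    voxels. Count and dF/F layers treat absent neurons as zero; rate layers
    treat them as missing, and a rate voxel is tested only when at least
    ``min_per_group`` larvae per group have a value there.
    """
    out = {}
    for metric in METRICS:
        a = heat_control.layer(metric).reshape(heat_control.count.shape[0], -1)
        b = heat_deficient.layer(metric).reshape(
            heat_deficient.count.shape[0], -1
        )
        nvox = a.shape[1]
        pvals = np.ones(nvox)
        diff = np.zeros(nvox)
        if metric == "firing_rate":
            ok = (np.sum(~np.isnan(a), axis=0) >= min_per_group) & (
                np.sum(~np.isnan(b), axis=0) >= min_per_group
            )
        else:
            ok = ~(np.all(a == 0, axis=0) & np.all(b == 0, axis=0))
        for j in np.flatnonzero(ok):
            xa = a[:, j][~np.isnan(a[:, j])]
            xb = b[:, j][~np.isnan(b[:, j])]
            _, p = wilcoxon_rank_sum(xa, xb)
            pvals[j] = p
            diff[j] = np.mean(xb) - np.mean(xa)
        sig = pvals < alpha
        diff = np.where(sig, diff, 0.0)
        out[metric] = {
            "significant": sig.reshape(heat_control.shape),
            "difference": diff.reshape(heat_control.shape),
            "p": pvals.reshape(heat_control.shape),
        }
    return out


def downsample_mask(mask: np.ndarray, grid: ReferenceGrid, voxel_um: float = 12.0) -> np.ndarray:
    """12-um occupancy of a fine-grid mask: any covered source voxel counts."""
    shape = heatmap_shape(grid, voxel_um)
    out = np.zeros(shape, dtype=bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return out
    pos = idx * np.asarray(grid.voxel_size_um)
    v = np.floor(pos / voxel_um).astype(int)
    v = v[np.all((v >= 0) & (v < shape), axis=1)]
    out[v[:, 0], v[:, 1], v[:, 2]] = True
    return out


def map_to_masks(
    voxel_results: dict[str, dict[str, np.ndarray]],
    masks: RegionMaskSet,
    voxel_um: float = 12.0,
) -> pd.DataFrame:
    """Relevance table: per-mask altered-voxel percentages and summed diffs.

    For every mask and metric: the percentage of the mask's 12-um voxels
    significantly increased / decreased, and the summed difference over
    those voxels in each direction. relevance = sum of |summed difference|
    over all six metric x direction components; rows are sorted by it.
    """
    rows = []
    for name, mask in masks.masks.items():
        dm = downsample_mask(mask, masks.grid, voxel_um)
        n_mask = int(dm.sum())
        row: dict = {"region": name, "n_voxels": n_mask}
        relevance = 0.0
        for metric in METRICS:
            sig = voxel_results[metric]["significant"] & dm
            diff = voxel_results[metric]["difference"]
            up = sig & (diff > 0)
            dn = sig & (diff < 0)
            sum_up = float(diff[up].sum())
            sum_dn = float(diff[dn].sum())
            row[f"{metric}_pct_increased"] = (
                100.0 * up.sum() / n_mask if n_mask else 0.0
            )
            row[f"{metric}_pct_decreased"] = (
                100.0 * dn.sum() / n_mask if n_mask else 0.0
            )
            row[f"{metric}_sum_increased"] = sum_up
            row[f"{metric}_sum_decreased"] = sum_dn
            relevance += abs(sum_up) + abs(sum_dn)
        row["relevance"] = relevance
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    return df.sort_values("relevance", ascending=False)


def region_test(
    tables_control: list[pd.DataFrame],
    tables_deficient: list[pd.DataFrame],
    metric: str = "n_active",
    alpha: float = 0.05,
    with_permutation: bool = False,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-region two-group test on per-larva region statistics.

    ``tables_*`` are region_table outputs (one per larva, same region
    index). Effect size is the percent change of the deficient group mean
    relative to the control mean.
    """
    regions = tables_control[0].index
    xmat = np.vstack([t.loc[regions, metric].to_numpy() for t in tables_control])
    ymat = np.vstack(
        [t.loc[regions, metric].to_numpy() for t in tables_deficient]
    )
    rows = []
    for j, region in enumerate(regions):
        x, y = xmat[:, j], ymat[:, j]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size == 0 or y.size == 0:
            rows.append(
                {"region": region, "p": np.nan, "p_wilcoxon": np.nan,
                 "p_permutation": np.nan, "pct_change": np.nan,
                 "significant": False}
            )
            continue
        res = two_group_test(x, y, with_permutation, n_perm, seed)
        mx = x.mean()
        pct = 100.0 * (y.mean() - mx) / mx if mx != 0 else np.nan
        rows.append(
            {
                "region": region,
                "p": res.p_reported,
                "p_wilcoxon": res.p_wilcoxon,
                "p_permutation": res.p_permutation,
                "pct_change": pct,
                "significant": bool(res.p_reported < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("region")
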