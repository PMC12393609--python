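"""Atlas-region assignment and ablation quantification.

Neurons live in a common reference space sampled on a 1 x 1 x 2 um voxel
grid (the full brain is a 500 x 1000 x 200-voxel stack spanning
500 x 1000 x 400 um). Each neuron is represented by an axis-aligned
5 x 5 x 6-um cube -- 5 x 5 x 3 = 75 grid voxels -- centred on its centroid
after a +5-um z offset (half the volumetric z step, compensating the
continuously moving objective). A neuron belongs to every anatomical mask
that overlaps its cube by at least 10 voxels; masks may overlap, so the
assignment is many-to-many.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIVISIONS = ("forebrain", "midbrain", "hindbrain")

#: Source composition of the full-scale anatomical mask collection: Z-brain
#: anatomical regions, mapZebrain anatomical regions, and HCR/transgenic
#: marker expression masks, each further split by neurotransmitter class
#: downstream. The toy atlas stands in for these in tests.
ATLAS_SOURCES = {
    "zbrain_regions": 294,
    "mapzebrain_regions": 114,
    "hcr_transgenic_markers": 296,
}


def total_mask_sources(sources: dict[str, int] | None = None) -> int:
    """Total number of region/marker mask sources before class splitting."""
    return sum((sources or ATLAS_SOURCES).values())


@dataclass(frozen=True)
class ReferenceGrid:
    """Reference-space sampling grid."""

    shape_voxels: tuple[int, int, int] = (500, 1000, 200)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            s * v for s, v in zip(self.shape_voxels, self.voxel_size_um)
        )


@dataclass
class RegionMaskSet:
    """Named binary masks on one grid, with parent/class/division metadata."""

    grid: ReferenceGrid
    masks: dict[str, np.ndarray]  # name -> bool volume, shape = grid shape
    manifest: pd.DataFrame  # columns: name, parent, cls, division

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            if tuple(m.shape) != tuple(self.grid.shape_voxels):
                raise ValueError(f"mask {name!r} not on the reference grid")

    def names(self) -> list[str]:
        return list(self.masks)


# ---------------------------------------------------------------------------
# cube construction and assignment
# ---------------------------------------------------------------------------

_CUBE_HALF = (2, 2, 1)  # +-2 voxels in x, y and +-1 in z -> 5 x 5 x 3 = 75


def neuron_cube(
    centroid_um: tuple[float, float, float] | np.ndarray,
    grid: ReferenceGrid,
    z_offset_um: float = 5.0,
) -> np.ndarray:
    """Voxel set of the 75-voxel cube representing one neuron.

    The centroid (plus the z offset) maps to the voxel containing it
    (floor), and the cube spans that voxel +-2 in x and y and +-1 in z.
    Voxels falling outside the volume are clipped away, so a centroid on a
    face yields a half cube; a centroid outside the grid yields an empty
    set with a warning.
    """
    pos = np.asarray(centroid_um, dtype=float).copy()
    pos[2] += z_offset_um
    vox = np.floor(pos / np.asarray(grid.voxel_size_um)).astype(int)
    shape = np.asarray(grid.shape_voxels)
    if np.any(vox < 0) or np.any(vox >= shape):
        warnings.warn(f"centroid {tuple(pos)} um outside the reference grid")
        return np.empty((0, 3), dtype=int)
    off = np.stack(
        np.meshgrid(*[np.arange(-h, h + 1) for h in _CUBE_HALF], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    cube = vox[None, :] + off
    ok = np.all((cube >= 0) & (cube < shape[None, :]), axis=1)
    return cube[ok]


def assign_regions(
    cube_voxels: np.ndarray,
    masks: RegionMaskSet,
    min_overlap: int = 10,
) -> list[str]:
    """All mask names overlapping the cube by at least ``min_overlap`` voxels."""
    if cube_voxels.shape[0] == 0:
        return []
    x, y, z = cube_voxels.T
    out = []
    for name, m in masks.masks.items():
        if int(np.count_nonzero(m[x, y, z])) >= min_overlap:
            out.append(name)
    return out


def assign_all(
    centroids_um: np.ndarray,
    masks: RegionMaskSet,
    min_overlap: int = 10,
    z_offset_um: float = 5.0,
) -> list[list[str]]:
    """Vectorized region assignment for many neurons at once.

    Equivalent to ``assign_regions(neuron_cube(c), ...)`` per centroid but
    evaluates all cubes against each mask in one indexing pass.
    """
    grid = masks.grid
    pts = np.asarray(centroids_um, dtype=float).copy()
    if pts.size == 0:
        return []
    pts[:, 2] += z_offset_um
    vox = np.floor(pts / np.asarray(grid.voxel_size_um)).astype(int)
    shape = np.asarray(grid.shape_voxels)
    inside = np.all((vox >= 0) & (vox < shape[None, :]), axis=1)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} centroid(s) outside the reference grid"
        )
    off = np.stack(
        np.meshgrid(*[np.arange(-h, h + 1) for h in _CUBE_HALF], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    cubes = vox[:, None, :] + off[None, :, :]  # (n, 75, 3)
    ok = np.all((cubes >= 0) & (cubes < shape[None, None, :]), axis=2)
    ok &= inside[:, None]
    cc = np.clip(cubes, 0, shape - 1)
    x, y, z = cc[..., 0], cc[..., 1], cc[..., 2]
    result: list[list[str]] = [[] for _ in range(pts.shape[0])]
    for name, m in masks.masks.items():
        hits = m[x, y, z] & ok
        counts = hits.sum(axis=1)
        for i in np.flatnonzero(counts >= min_overlap):
            result[i].append(name)
    return result


# ---------------------------------------------------------------------------
# per-region activity tables
# ---------------------------------------------------------------------------


def mask_division(
    mask: np.ndarray, division_masks: dict[str, np.ndarray]
) -> str | None:
    """Division (fore/mid/hindbrain) holding more than half the mask volume."""
    total = int(np.count_nonzero(mask))
    if total == 0:
        return None
    for div, dm in division_masks.items():
        if int(np.count_nonzero(mask & dm)) > total / 2:
            return div
    return None


def region_table(
    neurons: list,
    masks: RegionMaskSet,
    min_overlap: int = 10,
    z_offset_um: float = 5.0,
    division_masks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-region activity statistics for one larva.

    For every mask: the number of assigned (active) neurons, the sum of
    their z-scored cumulative dF/F, and their mean firing rate (nan and
    flagged when the region is empty). Neurons may contribute to several
    overlapping masks. ``neurons`` are records with ``centroid_um``,
    ``cum_dff_z`` and ``firing_rate_hz`` attributes.
    """
    cents = np.array([n.centroid_um for n in neurons], dtype=float).reshape(
        -1, 3
    )
    assigned = assign_all(cents, masks, min_overlap, z_offset_um)
    dff = np.array(
        [0.0 if n.cum_dff_z is None else n.cum_dff_z for n in neurons]
    )
    rate = np.array(
        [
            np.nan if n.firing_rate_hz is None else n.firing_rate_hz
            for n in neurons
        ]
    )
    per_mask: dict[str, list[int]] = {name: [] for name in masks.names()}
    for i, names in enumerate(assigned):
        for name in names:
            per_mask[name].append(i)
    rows = []
    for name, idx in per_mask.items():
        idx = np.asarray(idx, dtype=int)
        division = None
        if division_masks is not None:
            division = mask_division(masks.masks[name], division_masks)
        rows.append(
            {
                "region": name,
                "n_active": idx.size,
                "cum_dff_z_sum": float(dff[idx].sum()) if idx.size else 0.0,
                "firing_rate_mean_hz": (
                    float(np.nanmean(rate[idx])) if idx.size else np.nan
                ),
                "empty": idx.size == 0,
                "division": division,
            }
        )
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# ablation quantification
# ---------------------------------------------------------------------------


@dataclass
class AblationQuant:
    mask: str
    a: float  # mean suprathreshold voxel count, control
    b: float  # mean suprathreshold voxel count, treated
    threshold: float
    percent_loss: float
    n_outliers: int


def _normalize01(vol: np.ndarray) -> np.ndarray:
    v = np.asarray(vol, dtype=float)
    rng = np.ptp(v)
    return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)


def _mad_outlier_count(values: np.ndarray, k: float = 3.0) -> int:
    med = np.median(values)
    mad = 1.4826 * np.median(np.abs(values - med))
    if mad == 0:
        return 0
    return int(np.count_nonzero(np.abs(values - med) > k * mad))


def quantify_ablation(
    control_volumes: list[np.ndarray],
    treated_volumes: list[np.ndarray],
    composite_masks: dict[str, np.ndarray],
    t0: float = 0.2,
    step: float = 0.05,
    bounds: tuple[float, float] = (0.1, 0.5),
    outlier_k: float = 3.0,
) -> list[AblationQuant]:
    """Percent marker-signal loss per composite mask between two groups.

    Each stack is 0-1 normalized; voxels above an intensity threshold and
    inside the mask are counted per larva. The threshold starts at ``t0``
    and is adjusted over a +-``step`` grid within ``bounds``, choosing the
    value that minimizes the number of per-larva scaled-MAD outliers across
    both groups (ties resolve toward ``t0``). Loss = 100 * (a - b) / a with
    a, b the mean control / treated counts.
    """
    ctrl = [_normalize01(v) for v in control_volumes]
    trt = [_normalize01(v) for v in treated_volumes]
    lo, hi = bounds
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)

    def counts_at(thr: float, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ca = np.array([np.count_nonzero((v > thr) & mask) for v in ctrl])
        cb = np.array([np.count_nonzero((v > thr) & mask) for v in trt])
        return ca, cb

    out = []
    for name, mask in composite_masks.items():
        mask = mask.astype(bool)
        best = None
        for thr in grid:
            ca, cb = counts_at(thr, mask)
            n_out = _mad_outlier_count(ca, outlier_k) + _mad_outlier_count(
                cb, outlier_k
            )
            key = (n_out, abs(thr - t0), thr)
            if best is None or key < best[0]:
                best = (key, thr, ca, cb)
        _, thr, ca, cb = best
        a, b = float(ca.mean()), float(cb.mean())
        loss = 100.0 * (a - b) / a if a > 0 else np.nan
        out.append(
            AblationQuant(
                mask=name,
                a=a,
                b=b,
                threshold=float(thr),
                percent_loss=float(loss),
                n_outliers=int(best[0][0]),
            )
        )
    return out
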