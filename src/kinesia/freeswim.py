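"""Open-field larval tracking and locomotor metrics.

A multi-well plate is imaged from above against white light; transparent
(nacre) larvae are visible only by their dark eye cluster. Well boundaries
are detected on the background image (maximum projection of the first and
last minute of video) with a smoothed Otsu threshold; within each well the
darkest qualifying blob is tracked per frame. Eight locomotor metrics are
computed per larva over the 15-minute recording, and a larva is classified
as impaired when it explores less than 35% of its arena -- the most
CA-loss-sensitive metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu


class ArenaDetectionError(RuntimeError):
    pass


@dataclass
class ArenaLayout:
    """Detected wells (px bounding boxes) and the physical scale."""

    wells: list[tuple[int, int, int, int]]  # (min_row, min_col, max_row, max_col)
    mm_per_px: float
    body_length_mm: float = 4.5
    boundary_factor: float = 1.5

    @property
    def wall_margin_mm(self) -> float:
        """Thigmotaxis boundary distance: 1.5 body lengths = 6.75 mm."""
        return self.body_length_mm * self.boundary_factor

    def well_size_mm(self, i: int) -> tuple[float, float]:
        r0, c0, r1, c1 = self.wells[i]
        return ((r1 - r0) * self.mm_per_px, (c1 - c0) * self.mm_per_px)


@dataclass
class Trajectory:
    """Gap-filled larva positions for one well."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    area_px: np.ndarray
    missing: np.ndarray  # True where no blob was found before filling
    frame_rate_hz: float
    low_snr: bool = False
    low_quality: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.t_s.size),
                "t_s": self.t_s,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "area_px": self.area_px,
                "missing": self.missing,
            }
        )


@dataclass
class LocomotorMetrics:
    total_distance_mm: float
    rms_speed_mm_s: float
    arena_explored_pct: float
    bout_rate_hz: float
    inter_bout_interval_s: float
    bout_amplitude_mm: float
    active_duration_pct: float
    thigmotaxis_pct: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def make_background(frames: np.ndarray, block_s: float = 60.0, frame_rate_hz: float = 40.0) -> np.ndarray:
    """Maximum projection of the first and last ``block_s`` of video."""
    n = max(1, min(int(block_s * frame_rate_hz), frames.shape[0]))
    stack = np.concatenate([frames[:n], frames[-n:]], axis=0)
    return stack.max(axis=0)


def detect_arenas(
    background: np.ndarray,
    expected_wells: int = 24,
    mm_per_px: float = 0.14,
    otsu_multiplier: float = 1.2,
    sigma: float = 2.0,
    min_area_px: int = 100,
) -> ArenaLayout:
    """Locate the bright wells between black-painted walls.

    The background is Gaussian-smoothed and thresholded at Otsu's value
    times ``otsu_multiplier``; connected bright components of sufficient
    area are the wells, ordered row-major. A count other than
    ``expected_wells`` raises :class:`ArenaDetectionError` with the found
    count, as does a degenerate (uniform) image.
    """
    img = gaussian(np.asarray(background, dtype=float), sigma=sigma)
    if np.ptp(img) == 0:
        raise ArenaDetectionError("uniform background: no arena structure")
    thr = threshold_otsu(img) * otsu_multiplier
    mask = img > thr
    labels = measure.label(mask)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area_px]
    if len(props) != expected_wells:
        raise ArenaDetectionError(
            f"found {len(props)} wells, expected {expected_wells}"
        )
    props.sort(key=lambda p: (round(p.centroid[0] / 10), p.centroid[1]))
    wells = [tuple(int(v) for v in p.bbox) for p in props]
    return ArenaLayout(wells=wells, mm_per_px=mm_per_px)


def track_larva(
    frames: np.ndarray,
    well: tuple[int, int, int, int],
    layout: ArenaLayout,
    frame_rate_hz: float = 40.0,
    min_contrast: float = 10.0,
    min_area_px: int = 3,
    max_area_px: int = 100,
    wall_erode_px: int = 2,
    max_missing_frac: float = 0.2,
) -> Trajectory:
    """Track the dark eye cluster of one larva within its well.

    Per frame, pixels darker than the local background (per-frame median)
    by at least ``min_contrast`` grey levels are candidate eye pixels; a
    morphological opening and a small erosion of the well border suppress
    speckle and wall-shadow false positives. The darkest remaining blob's
    intensity-weighted centroid is the position. Frames without a
    qualifying blob are missing and filled from the nearest valid frame;
    more than ``max_missing_frac`` missing flags the trajectory as low
    quality, and a median achieved contrast below ``min_contrast`` flags
    low SNR.
    """
    r0, c0, r1, c1 = well
    n = frames.shape[0]
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    areas = np.zeros(n)
    contrasts = np.full(n, np.nan)
    interior = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    if wall_erode_px * 2 < min(interior.shape):
        interior[wall_erode_px:-wall_erode_px or None,
                 wall_erode_px:-wall_erode_px or None] = True
    else:
        interior[:] = True
    for i in range(n):
        crop = np.asarray(frames[i][r0:r1, c0:c1], dtype=float)
        bg = np.median(crop)
        mask = (bg - crop >= min_contrast) & interior
        mask = morphology.opening(mask)
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
        if not mask.any():
            continue
        lab, nlab = ndimage.label(mask)
        best, best_depth = None, -np.inf
        for k in range(1, nlab + 1):
            sel = lab == k
            a = int(sel.sum())
            if a < min_area_px or a > max_area_px:
                continue
            depth = float((bg - crop[sel]).mean())
            if depth > best_depth:
                best, best_depth = sel, depth
        if best is None:
            continue
        weights = np.clip(bg - crop, 0, None) * best
        cy, cx = ndimage.center_of_mass(weights)
        xs[i], ys[i] = cx, cy
        areas[i] = int(best.sum())
        contrasts[i] = float((bg - crop[best]).max())
    missing = np.isnan(xs)
    if missing.all():
        traj = Trajectory(
            t_s=np.arange(n) / frame_rate_hz,
            x_mm=np.zeros(n),
            y_mm=np.zeros(n),
            area_px=areas,
            missing=missing,
            frame_rate_hz=frame_rate_hz,
            low_snr=True,
            low_quality=True,
        )
        return traj
    xs = _fill_nearest(xs)
    ys = _fill_nearest(ys)
    med_contrast = float(np.nanmedian(contrasts))
    return Trajectory(
        t_s=np.arange(n) / frame_rate_hz,
        x_mm=xs * layout.mm_per_px,
        y_mm=ys * layout.mm_per_px,
        area_px=areas,
        missing=missing,
        frame_rate_hz=frame_rate_hz,
        low_snr=bool(med_contrast < min_contrast),
        low_quality=bool(missing.mean() > max_missing_frac),
    )


def _fill_nearest(x: np.ndarray) -> np.ndarray:
    """Fill nans from the temporally nearest valid sample (earlier on ties)."""
    valid = np.flatnonzero(~np.isnan(x))
    idx = np.arange(x.size)
    pos = np.searchsorted(valid, idx)
    left = valid[np.clip(pos - 1, 0, valid.size - 1)]
    right = valid[np.clip(pos, 0, valid.size - 1)]
    nearest = np.where((idx - left) <= (right - idx), left, right)
    out = x[nearest]
    out[valid] = x[valid]
    return out


@dataclass
class BoutParams:
    """Beat-and-glide bout convention (the metric definitions expose it).

    A bout is a contiguous interval with inter-frame speed above
    ``speed_mm_s`` for at least ``min_frames`` analysis frames, separated
    from the next bout by at least ``min_gap_s`` below threshold.
    """

    speed_mm_s: float = 2.0
    min_frames: int = 3
    min_gap_s: float = 0.1


def _find_bouts(speed: np.ndarray, fs: float, p: BoutParams) -> list[tuple[int, int]]:
    above = speed > p.speed_mm_s
    bouts = []
    i = 0
    n = above.size
    min_gap = max(1, int(round(p.min_gap_s * fs)))
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n:
            if above[j]:
                j += 1
                continue
            # below threshold: close the bout only if the gap is long enough
            k = j
            while k < n and not above[k]:
                k += 1
            if k - j >= min_gap or k == n:
                break
            j = k
        bouts.append((i, j))
        i = j + 1
    return [(a, b) for a, b in bouts if b - a >= p.min_frames]


def compute_metrics(
    traj: Trajectory,
    layout: ArenaLayout,
    well_index: int = 0,
    grid_mm: float = 1.75,
    bout: BoutParams | None = None,
) -> LocomotorMetrics:
    """The eight open-field locomotor metrics for one larva.

    Distances come from frame-to-frame displacements at the analysis rate;
    exploration is the fraction of ``grid_mm`` occupancy bins visited;
    thigmotaxis is the fraction of time spent within the wall margin
    (1.5 body lengths = 6.75 mm) of any well wall.
    """
    if traj.t_s.size < 2:
        raise ValueError("trajectory too short")
    bout = bout or BoutParams()
    fs = traj.frame_rate_hz
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    step = np.hypot(dx, dy)
    total = float(step.sum())
    speed = step * fs
    rms_speed = float(np.sqrt(np.mean(speed**2)))

    w_mm, h_mm = layout.well_size_mm(well_index)
    nbx = max(1, int(np.ceil(w_mm / grid_mm)))
    nby = max(1, int(np.ceil(h_mm / grid_mm)))
    bx = np.clip((traj.x_mm / grid_mm).astype(int), 0, nbx - 1)
    by = np.clip((traj.y_mm / grid_mm).astype(int), 0, nby - 1)
    visited = np.zeros((nby, nbx), dtype=bool)
    visited[by, bx] = True
    explored = 100.0 * visited.sum() / (nbx * nby)

    bouts = _find_bouts(speed, fs, bout)
    dur_s = traj.t_s[-1] - traj.t_s[0] + 1.0 / fs
    bout_rate = len(bouts) / dur_s
    if len(bouts) >= 2:
        ibi = float(
            np.mean(
                [(bouts[k + 1][0] - bouts[k][1]) / fs for k in range(len(bouts) - 1)]
            )
        )
    else:
        ibi = np.nan
    if bouts:
        amps = [
            float(
                np.hypot(
                    traj.x_mm[min(b, traj.x_mm.size - 1)] - traj.x_mm[a],
                    traj.y_mm[min(b, traj.y_mm.size - 1)] - traj.y_mm[a],
                )
            )
            for a, b in bouts
        ]
        bout_amp = float(np.mean(amps))
        active = sum(b - a for a, b in bouts) / speed.size * 100.0
    else:
        bout_amp = 0.0
        active = 0.0

    margin = layout.wall_margin_mm
    near_wall = (
        (traj.x_mm < margin)
        | (traj.x_mm > w_mm - margin)
        | (traj.y_mm < margin)
        | (traj.y_mm > h_mm - margin)
    )
    thigmo = 100.0 * float(near_wall.mean())

    return LocomotorMetrics(
        total_distance_mm=total,
        rms_speed_mm_s=rms_speed,
        arena_explored_pct=float(explored),
        bout_rate_hz=float(bout_rate),
        inter_bout_interval_s=ibi,
        bout_amplitude_mm=bout_amp,
        active_duration_pct=float(active),
        thigmotaxis_pct=thigmo,
    )


def dwell_time_map(
    traj: Trajectory,
    layout: ArenaLayout,
    well_index: int = 0,
    grid_mm: float = 1.75,
) -> np.ndarray:
    """Seconds spent per occupancy bin; the positional-dwell heatmap."""
    w_mm, h_mm = layout.well_size_mm(well_index)
    nbx = max(1, int(np.ceil(w_mm / grid_mm)))
    nby = max(1, int(np.ceil(h_mm / grid_mm)))
    bx = np.clip((traj.x_mm / grid_mm).astype(int), 0, nbx - 1)
    by = np.clip((traj.y_mm / grid_mm).astype(int), 0, nby - 1)
    out = np.zeros((nby, nbx))
    np.add.at(out, (by, bx), 1.0 / traj.frame_rate_hz)
    return out


def classify_impairment(
    metrics: LocomotorMetrics | float, cutoff_pct: float = 35.0
) -> str:
    """"impaired" iff arena exploration is strictly below the cut-off."""
    pct = (
        metrics.arena_explored_pct
        if isinstance(metrics, LocomotorMetrics)
        else float(metrics)
    )
    return "impaired" if pct < cutoff_pct else "unimpaired"


def exclude_outliers(
    values: np.ndarray | list, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop values beyond ``k`` scaled median absolute deviations.

    The MAD is scaled by 1.4826 (consistent-with-normal). The comparison is
    strict, so an all-equal list excludes nothing even though its MAD is
    zero, while a majority-identical list ([1,1,1,1,100]) excludes the
    discrepant value. Requires at least three values. Returns
    (retained values, excluded indices).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(v)
    mad = 1.4826 * np.median(np.abs(v - med))
    out = np.abs(v - med) > k * mad
    return v[~out], np.flatnonzero(out)
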