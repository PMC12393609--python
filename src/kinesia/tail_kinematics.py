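"""Tail kinematics: skeleton point sets to a baseline-corrected tail-angle trace.

The tail of a head-embedded larva is imaged from below at ~100-200 Hz. Each
frame is reduced to an ordered medial-axis point list (base to tip), the tail
is split into eight segments by point count, and a single summary angle per
frame is derived from the mean position of segments 4-7 relative to a fixed,
user-supplied base point. The resulting angle trace is nan-filled, corrected
for slow drift of the resting tail posture, and max-resampled to the imaging
rate (1 Hz) for correlation with neuronal activity.

Coordinate and sign convention (the raw recordings do not fix one): the head
points toward -x, y increases downward in image coordinates, and a positive
angle means the tail is deflected toward the animal's right. Angles are in
degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import morphology
from skimage.filters import threshold_otsu


@dataclass
class TailSkeleton:
    """Ordered per-frame tail point sets (px), base to tip."""

    frames: list[np.ndarray]  # each (n_i, 2) float array of (x, y), ordered
    base_point: tuple[float, float]
    frame_rate_hz: float


@dataclass
class TailTrace:
    """Signed tail angle per frame, degrees."""

    angle_deg: np.ndarray
    frame_rate_hz: float
    baseline_removed: bool = False
    nan_filled: bool = False

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.angle_deg.size) / self.frame_rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "angle_deg": self.angle_deg})


def skeletonize_frame(
    image: np.ndarray,
    roi: tuple[slice, slice] | None = None,
    polarity: str = "dark",
    min_points: int = 5,
) -> np.ndarray:
    """Extract an ordered medial-axis point list for the tail in one frame.

    Parameters
    ----------
    image : grayscale frame.
    roi : optional (row_slice, col_slice) restricting the search.
    polarity : "dark" if the tail is darker than background, "bright" otherwise.
    min_points : skeletons with fewer points are treated as absent.

    Returns (n, 2) array of (x, y) pixel coordinates ordered from the end
    closest to the image-left (head side) to the tip, or an empty (0, 2)
    array when no tail is detected. Absence is a valid outcome; the frame's
    angle becomes nan downstream.
    """
    img = np.asarray(image, dtype=float)
    r0 = c0 = 0
    if roi is not None:
        r0, c0 = roi[0].start or 0, roi[1].start or 0
        img = img[roi]
    if img.size == 0 or np.ptp(img) == 0:
        return np.empty((0, 2))
    thr = threshold_otsu(img)
    mask = img < thr if polarity == "dark" else img > thr
    mask = morphology.remove_small_objects(mask, max_size=min_points - 1)
    if not mask.any():
        return np.empty((0, 2))
    skel = morphology.skeletonize(mask)
    rr, cc = np.nonzero(skel)
    if rr.size < min_points:
        return np.empty((0, 2))
    pts = np.column_stack([cc + c0, rr + r0]).astype(float)  # (x, y)
    return _order_points(pts)


def _order_points(pts: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour ordering starting from the leftmost point.

    The head faces -x, so the skeleton end with the smallest x is the base
    side. Adequate for the thin, non-self-crossing curves a larval tail
    produces; branch points from specular noise are resolved by proximity.
    """
    n = pts.shape[0]
    start = int(np.argmin(pts[:, 0]))
    order = [start]
    remaining = set(range(n)) - {start}
    current = start
    while remaining:
        rem = np.fromiter(remaining, dtype=int)
        d2 = np.sum((pts[rem] - pts[current]) ** 2, axis=1)
        nxt = int(rem[np.argmin(d2)])
        order.append(nxt)
        remaining.discard(nxt)
        current = nxt
    return pts[order]


def partition_segments(n_points: int, n_segments: int = 8) -> list[slice]:
    """Split ``n_points`` ordered points into ``n_segments`` runs by count.

    Points are split as evenly as possible; the first ``n_points % n_segments``
    segments absorb one extra point each (17 points -> sizes 3,2,2,2,2,2,2,2).
    """
    base, extra = divmod(n_points, n_segments)
    sizes = [base + (1 if i < extra else 0) for i in range(n_segments)]
    out, pos = [], 0
    for s in sizes:
        out.append(slice(pos, pos + s))
        pos += s
    return out


def _line_angle_deg(x: np.ndarray, y: np.ndarray) -> float:
    """Angle (deg) to the x-axis of the least-squares line through (x, y)."""
    if np.ptp(x) >= np.ptp(y):
        m = np.polyfit(x, y, 1)[0]
        return float(np.degrees(np.arctan(m)))
    m = np.polyfit(y, x, 1)[0]
    ang = 90.0 - float(np.degrees(np.arctan(m)))
    return ang if ang <= 90.0 else ang - 180.0


def segment_angles(points: np.ndarray, n_segments: int = 8) -> np.ndarray:
    """Per-segment tail angles (deg) for one frame's ordered point list.

    Each segment's points are fitted with a cubic along the dominant axis,
    the cubic is evaluated at the points, and a straight line fitted to the
    evaluated curve gives the segment's angle with the x-axis. Fewer than
    2 * n_segments points yields all-nan (the partition would degenerate).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2 * n_segments:
        return np.full(n_segments, np.nan)
    out = np.empty(n_segments)
    for i, seg in enumerate(partition_segments(pts.shape[0], n_segments)):
        x, y = pts[seg, 0], pts[seg, 1]
        deg = min(3, x.size - 1)
        if np.ptp(x) >= np.ptp(y):
            coef = np.polyfit(x, y, deg)
            out[i] = _line_angle_deg(x, np.polyval(coef, x))
        else:
            coef = np.polyfit(y, x, deg)
            out[i] = _line_angle_deg(np.polyval(coef, y), y)
    return out


def summary_angle(
    skel: TailSkeleton,
    segments: tuple[int, int] = (4, 7),
    n_segments: int = 8,
) -> TailTrace:
    """One signed angle per frame from the caudal tail segments.

    The mean position of the points in segments ``segments[0]..segments[1]``
    (1-based, default 4-7) is connected to the fixed base point; the signed
    slope angle of that line (atan2(dy, dx), degrees) is the frame's tail
    angle. Frames without a usable skeleton yield nan.
    """
    lo, hi = segments
    bx, by = skel.base_point
    angles = np.full(len(skel.frames), np.nan)
    for i, pts in enumerate(skel.frames):
        if pts.shape[0] < 2 * n_segments:
            continue
        parts = partition_segments(pts.shape[0], n_segments)
        sel = np.vstack([pts[parts[j]] for j in range(lo - 1, hi)])
        mx, my = sel.mean(axis=0)
        angles[i] = np.degrees(np.arctan2(my - by, mx - bx))
    return TailTrace(angle_deg=angles, frame_rate_hz=skel.frame_rate_hz)


def fill_nans(trace: TailTrace) -> TailTrace:
    """Replace each nan sample by its temporally nearest valid sample.

    Ties between an earlier and a later neighbour go to the earlier one.
    An all-nan trace is an error: there is nothing to fill from.
    """
    x = np.asarray(trace.angle_deg, dtype=float)
    valid = np.flatnonzero(~np.isnan(x))
    if valid.size == 0:
        raise ValueError("trace contains no valid samples")
    if valid.size == x.size:
        return replace(trace, nan_filled=True)
    idx = np.arange(x.size)
    pos = np.searchsorted(valid, idx)
    left = valid[np.clip(pos - 1, 0, valid.size - 1)]
    right = valid[np.clip(pos, 0, valid.size - 1)]
    use_left = (idx - left) <= (right - idx)  # earlier wins ties
    nearest = np.where(use_left, left, right)
    filled = x[nearest]
    filled[valid] = x[valid]
    return replace(trace, angle_deg=filled, nan_filled=True)


def remove_baseline(
    trace: TailTrace,
    window_s: float = 60.0,
    baseline_max_hz: float = 20.0,
) -> TailTrace:
    """Subtract a drifting resting-posture baseline from the angle trace.

    The baseline is the median over a centred (bidirectional) window of
    ``window_s`` seconds, evaluated at every sample. The resting tail angle
    drifts slowly over tens of minutes (agarose relaxation, posture creep);
    tail events occupy a small fraction of any one-minute window, so the
    windowed median tracks the rest posture while ignoring events.

    For frame rates above ``baseline_max_hz`` the median is computed on a
    decimated copy of the trace and linearly interpolated back; the baseline
    is band-limited far below that rate, so this changes nothing but runtime.
    """
    x = np.asarray(trace.angle_deg, dtype=float)
    fs = trace.frame_rate_hz
    dec = max(1, int(round(fs / baseline_max_hz)))
    xs = x[::dec]
    w = max(3, int(round(window_s * fs / dec)) | 1)
    base_s = (
        pd.Series(xs).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    if dec > 1:
        t_full = np.arange(x.size)
        base = np.interp(t_full, t_full[::dec], base_s)
    else:
        base = base_s
    return replace(trace, angle_deg=x - base, baseline_removed=True)


def resample_to_imaging(
    trace: TailTrace,
    target_hz: float = 1.0,
    outlier_q: float = 0.90,
) -> TailTrace:
    """Max-resample the tail angle to the (slower) imaging rate.

    Plain interpolation at 1 Hz destroys tail-beat amplitude (beats last tens
    of milliseconds), so each target bin [t, t + 1/target_hz) instead reports
    the maximum |angle| after discarding within-bin outliers above the
    ``outlier_q`` quantile of |angle| (linear-interpolation quantile). The
    sign of the retained extreme sample is kept. Single-sample bins pass
    through unchanged, and a bin is never allowed to empty itself.
    """
    if trace.frame_rate_hz < target_hz:
        raise ValueError("trace frame rate below target rate")
    x = np.asarray(trace.angle_deg, dtype=float)
    fs = trace.frame_rate_hz
    per = fs / target_hz
    n_bins = int(np.ceil(x.size / per))
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = int(round(b * per)), min(int(round((b + 1) * per)), x.size)
        seg = x[lo:hi]
        a = np.abs(seg)
        q = np.quantile(a, outlier_q)
        keep = a <= q
        if not keep.any():  # degenerate guard; q >= max makes this unreachable
            keep = np.ones_like(keep)
        kept = seg[keep]
        out[b] = kept[np.argmax(np.abs(kept))]
    return TailTrace(
        angle_deg=out,
        frame_rate_hz=target_hz,
        baseline_removed=trace.baseline_removed,
        nan_filled=trace.nan_filled,
    )
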