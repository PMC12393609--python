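"""Calcium-trace curation, normalization, and AR1 spike inference.

Candidate ROIs from an upstream source extractor (footprints plus raw
fluorescence traces at 1 Hz) are curated for morphology and activity,
wrongly split somata are merged, and each kept neuron's trace is processed
into: a 0-1 normalized trace, a baseline-subtracted dF/F, a z-scored
cumulative dF/F, and a nonnegative spike train inferred under a first-order
autoregressive (AR1) calcium model with a noise-level residual constraint.
The per-neuron firing rate is the number of spike peaks divided by the
recording duration (1445 s for a standard 24-minute session).

AR1 model: c_t = gamma * c_{t-1} + s_t with s_t >= 0, observed as
y_t = c_t + noise. The constrained problem -- minimize the total spike mass
subject to ||y - c||_2 <= noise_sd * sqrt(T) -- is solved by an online
pool-adjacent-violators sweep (an active-set method) with an outer search
over the sparsity weight that enforces the residual constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import percentile_filter


@dataclass
class DeconvModel:
    """AR1 deconvolution parameters for one neuron."""

    gamma: float
    noise_sd: float = 0.0
    sparsity: float | None = None  # None -> set by the residual constraint

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")


@dataclass
class NeuronRecord:
    id: int
    centroid_um: tuple[float, float, float]
    raw_trace: np.ndarray
    footprint_px: np.ndarray | None = None  # (n, 2) pixel coords
    footprint_w: np.ndarray | None = None
    norm_trace: np.ndarray | None = None
    dff_trace: np.ndarray | None = None
    cum_dff_z: float | None = None
    spike_train: np.ndarray | None = None
    firing_rate_hz: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ROI curation
# ---------------------------------------------------------------------------


@dataclass
class RoiCandidate:
    """One candidate ROI from the upstream extractor."""

    id: int
    centroid_um: tuple[float, float, float]
    pixels: np.ndarray  # (n, 2) int pixel coordinates
    weights: np.ndarray  # (n,) nonnegative footprint weights
    trace: np.ndarray


def _activity_snr(trace: np.ndarray) -> float:
    med = np.median(trace)
    mad = 1.4826 * np.median(np.abs(trace - med))
    if mad == 0:
        return 0.0
    return float((trace.max() - med) / mad)


def _compactness(pixels: np.ndarray) -> float:
    """Area over the area of the circumscribing circle; 1 for a disk."""
    if pixels.shape[0] <= 2:
        return 1.0
    c = pixels.mean(axis=0)
    rmax = np.sqrt(np.max(np.sum((pixels - c) ** 2, axis=1))) + 0.5
    return float(pixels.shape[0] / (np.pi * rmax**2))


def _footprints_touch(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two pixel sets are 8-adjacent or overlap."""
    d = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)
    return bool((d <= 1).any())


def curate_rois(
    candidates: list[RoiCandidate],
    min_px: int = 4,
    max_px: int = 400,
    min_compactness: float = 0.15,
    min_snr: float = 5.0,
    merge_dist_um: float = 8.0,
    merge_corr: float = 0.9,
) -> tuple[list[NeuronRecord], dict]:
    """Remove false-positive ROIs and merge wrongly split somata.

    An ROI is dropped when its footprint is too small, too large, or too
    ragged (compactness below ``min_compactness``), or when its trace shows
    no activity (peak-over-MAD SNR below ``min_snr``). Surviving pairs are
    merged when their centroids are closer than one cell diameter
    (``merge_dist_um``), their traces correlate above ``merge_corr``, and
    their footprints are contiguous; merged traces are footprint-weighted
    means. Returns the kept records and a QC-count dict.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    kept, removed = [], 0
    for c in candidates:
        n = c.pixels.shape[0]
        if (
            n < min_px
            or n > max_px
            or _compactness(c.pixels) < min_compactness
            or _activity_snr(np.asarray(c.trace, float)) < min_snr
        ):
            removed += 1
            continue
        kept.append(c)
    # union-find merge over qualifying pairs
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            dist = np.linalg.norm(
                np.asarray(a.centroid_um) - np.asarray(b.centroid_um)
            )
            if dist >= merge_dist_um:
                continue
            ta, tb = np.asarray(a.trace, float), np.asarray(b.trace, float)
            if ta.std() == 0 or tb.std() == 0:
                continue
            if np.corrcoef(ta, tb)[0, 1] <= merge_corr:
                continue
            if not _footprints_touch(a.pixels, b.pixels):
                continue
            parent[find(i)] = find(j)

    groups: dict[int, list[RoiCandidate]] = {}
    for i, c in enumerate(kept):
        groups.setdefault(find(i), []).append(c)
    records, merged = [], 0
    for new_id, group in enumerate(groups.values()):
        if len(group) == 1:
            c = group[0]
            records.append(
                NeuronRecord(
                    id=new_id,
                    centroid_um=tuple(c.centroid_um),
                    raw_trace=np.asarray(c.trace, float),
                    footprint_px=c.pixels,
                    footprint_w=c.weights,
                )
            )
            continue
        merged += len(group) - 1
        wsum = np.array([c.weights.sum() for c in group])
        trace = np.average(
            np.vstack([c.trace for c in group]), axis=0, weights=wsum
        )
        centroid = np.average(
            np.vstack([c.centroid_um for c in group]), axis=0, weights=wsum
        )
        records.append(
            NeuronRecord(
                id=new_id,
                centroid_um=tuple(centroid),
                raw_trace=trace,
                footprint_px=np.vstack([c.pixels for c in group]),
                footprint_w=np.concatenate([c.weights for c in group]),
                flags=["merged"],
            )
        )
    qc = {
        "n_candidates": len(candidates),
        "n_removed": removed,
        "n_merged_away": merged,
        "n_kept": len(records),
    }
    return records, qc


# ---------------------------------------------------------------------------
# Trace normalization
# ---------------------------------------------------------------------------


def normalize_and_baseline(
    raw_trace: np.ndarray,
    frame_rate_hz: float = 1.0,
    window_s: float = 120.0,
    baseline_percentile: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize a trace to [0, 1] and subtract a running baseline.

    The baseline is a morphological-opening-style estimate over a centred
    2-minute window: a running ``baseline_percentile``-th percentile
    (erosion; sits below calcium transients) followed by a running
    ``100 - baseline_percentile``-th percentile of that series (dilation;
    cancels the half-window lag a single percentile pass leaves on a
    moving drift). It tracks bleaching and z-creep while leaving transient
    amplitudes intact. Returns (norm_trace, dff_trace).
    """
    x = np.asarray(raw_trace, dtype=float)
    rng = np.ptp(x)
    norm = (x - x.min()) / rng if rng > 0 else np.zeros_like(x)
    w = max(3, int(round(window_s * frame_rate_hz)) | 1)
    eroded = percentile_filter(norm, baseline_percentile, size=w, mode="nearest")
    base = percentile_filter(
        eroded, 100.0 - baseline_percentile, size=w, mode="nearest"
    )
    return norm, norm - base


def cumulative_dff(
    dff_traces: list[np.ndarray] | np.ndarray,
) -> np.ndarray:
    """Z-scored per-neuron cumulative dF/F within one larva.

    Each neuron's dF/F is summed over time; the sums are z-scored across the
    larva's neuron population (population-sd denominator) so cumulative
    activity is comparable across larvae. An all-equal population maps to
    all zeros.
    """
    sums = np.array([np.sum(t) for t in dff_traces], dtype=float)
    sd = sums.std()  # population (n) denominator
    if sd == 0:
        return np.zeros_like(sums)
    return (sums - sums.mean()) / sd


# ---------------------------------------------------------------------------
# AR1 constrained deconvolution
# ---------------------------------------------------------------------------


def estimate_gamma(trace: np.ndarray, clip: tuple[float, float] = (0.5, 0.99)) -> float:
    """AR1 coefficient from the trace autocovariance ratio acov(2)/acov(1).

    Under c_t = gamma c_{t-1} + s_t observed with white noise, lag-1 and
    lag-2 autocovariances are gamma*v and gamma^2*v, so their ratio is noise
    free. Clipped to ``clip`` to guard short or silent traces.
    """
    x = np.asarray(trace, float)
    x = x - x.mean()
    a1 = float(x[1:] @ x[:-1])
    a2 = float(x[2:] @ x[:-2])
    if a1 <= 0:
        return clip[0]
    return float(np.clip(a2 / a1, *clip))


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust white-noise sd from scaled first differences.

    diff(y) of a slow signal plus white noise has sd ~ noise_sd*sqrt(2);
    the median absolute deviation makes the estimate transient-proof.
    """
    d = np.diff(np.asarray(trace, float))
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _oasis_ar1(y: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    """Pool-adjacent-violators solve of the L1-penalized AR1 problem.

    minimize 0.5*||c - y||^2 + lam * sum(s)  s.t.  s = c_t - gamma*c_{t-1} >= 0,
    c >= 0. Returns the denoised calcium c; spikes are its AR1 innovations.
    """
    T = y.size
    # absorb the L1 penalty into the target (last sample carries weight 1)
    yp = y - lam * (1.0 - gamma)
    if T:
        yp[-1] = y[-1] - lam
    # pools: value v, weight w, start t, length l
    v = np.empty(T)
    w = np.empty(T)
    t0 = np.empty(T, dtype=np.int64)
    ln = np.empty(T, dtype=np.int64)
    m = 0
    g = gamma
    for t in range(T):
        v[m] = yp[t]
        w[m] = 1.0
        t0[m] = t
        ln[m] = 1
        m += 1
        while m > 1:
            i = m - 2
            gl = g ** ln[i]
            # s >= 0 at the pool boundary iff next start >= gamma^l * start
            if v[m - 1] / w[m - 1] >= gl * v[i] / w[i]:
                break
            v[i] += gl * v[m - 1]
            w[i] += gl * gl * w[m - 1]
            ln[i] += ln[m - 1]
            m -= 1
    c = np.empty(T)
    for k in range(m):
        h = max(v[k] / w[k], 0.0)
        for j in range(ln[k]):
            c[t0[k] + j] = h
            h *= g
    return c


def _spikes_from_calcium(c: np.ndarray, gamma: float) -> np.ndarray:
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    s[s < 1e-9] = 0.0
    return s


def deconvolve_ar1(
    dff_trace: np.ndarray,
    model: DeconvModel,
    max_outer: int = 60,
    tol: float = 0.02,
) -> tuple[np.ndarray, dict]:
    """Infer a nonnegative spike train under the constrained AR1 model.

    With ``model.sparsity`` set, a single penalized solve is returned. With
    the default (None), the sparsity weight is searched (doubling then
    bisection) so the residual norm matches ``noise_sd * sqrt(T)`` within
    ``tol`` relative tolerance -- the noise-constrained formulation. With
    ``noise_sd == 0`` the unpenalized solve is returned, which on a noiseless
    AR1 trace reproduces the generating spikes exactly.

    Returns (spike_train, info); ``info['converged']`` is False when the
    search cannot bracket the constraint, in which case the record should be
    flagged rather than trusted.
    """
    y = np.asarray(dff_trace, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    T = y.size
    g = model.gamma
    if model.sparsity is not None:
        c = _oasis_ar1(y, g, model.sparsity)
        s = _spikes_from_calcium(c, g)
        rss = float(np.sum((y - c) ** 2))
        return s, {"lambda": model.sparsity, "rss": rss, "converged": True}
    target = model.noise_sd**2 * T
    c0 = _oasis_ar1(y, g, 0.0)
    rss0 = float(np.sum((y - c0) ** 2))
    if model.noise_sd <= 0 or rss0 >= target:
        s = _spikes_from_calcium(c0, g)
        return s, {"lambda": 0.0, "rss": rss0, "converged": True}
    # bracket: increase lambda until the residual exceeds the noise budget
    lam_lo, lam_hi = 0.0, max(1e-3 * (np.ptp(y) + 1e-12), 1e-6)
    converged = False
    for _ in range(max_outer):
        c = _oasis_ar1(y, g, lam_hi)
        rss = float(np.sum((y - c) ** 2))
        if rss >= target:
            converged = True
            break
        lam_lo, lam_hi = lam_hi, lam_hi * 2.0
    lam = lam_hi
    if converged:
        for _ in range(max_outer):
            lam = 0.5 * (lam_lo + lam_hi)
            c = _oasis_ar1(y, g, lam)
            rss = float(np.sum((y - c) ** 2))
            if abs(rss - target) <= tol * target:
                break
            if rss < target:
                lam_lo = lam
            else:
                lam_hi = lam
        lam = lam_lo  # keep the residual within (<=) the noise budget
    c = _oasis_ar1(y, g, lam)
    rss = float(np.sum((y - c) ** 2))
    s = _spikes_from_calcium(c, g)
    if not converged:
        warnings.warn("deconvolution sparsity search did not converge")
    return s, {"lambda": lam, "rss": rss, "converged": converged}


def count_spike_peaks(
    spike_train: np.ndarray, threshold: float = 0.0
) -> int:
    """Count spike peaks: local maxima of the deconvolved amplitude sequence.

    Deconvolution of a noisy trace leaves small "dust" amplitudes alongside
    genuine spikes; a local maximum counts only when it exceeds
    ``threshold``. With the default 0, every nonzero local maximum counts
    (appropriate for noiseless input, where the spike train is exact).
    Adjacent-frame amplitudes belonging to one transient share one local
    maximum and are counted once.
    """
    s = np.asarray(spike_train, dtype=float)
    if not (s > 0).any():
        return 0
    padded = np.concatenate([[0.0], s, [0.0]])
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    return int(np.count_nonzero(is_peak & (s > threshold)))


def spike_threshold(noise_sd: float, k: float = 1.5) -> float:
    """Amplitude below which a deconvolved event is treated as noise dust.

    Spurious spikes induced by observation noise of sd ``noise_sd`` carry
    amplitudes on the order of the noise itself; ``k`` times that separates
    them from genuine transients while remaining zero for noiseless input.
    """
    return k * max(noise_sd, 0.0)


def firing_rate(
    spike_train: np.ndarray,
    duration_s: float = 1445.0,
    threshold: float = 0.0,
) -> float:
    """Spike-peak count divided by the recording duration, in Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return count_spike_peaks(spike_train, threshold) / duration_s
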