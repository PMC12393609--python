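"""Synthetic inputs with planted ground truth for every pipeline stage.

No public recordings back this pipeline, so each consumed input can be
generated with known truth: two-group calcium cohorts (control vs
catecholamine-deficient) with planted region-restricted effects on
active-neuron counts and firing rates, tail-angle traces with planted
swim/flip/struggle events over a drifting baseline, a toy atlas of
disjoint base regions with neurotransmitter-class submasks, and rendered
open-field movies of a swimming larva. Every generator is fully
determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import ReferenceGrid, RegionMaskSet
from .tail_kinematics import TailTrace

# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

NT_CLASSES = ("gaba", "glut", "chol")


@dataclass
class ToyAtlas:
    """Disjoint box-shaped base regions with neurotransmitter submasks.

    ``labels`` holds the base-region label per voxel (0 = outside), and
    ``classes`` the neurotransmitter class per voxel (0 = unassigned,
    1..len(NT_CLASSES) per class) inside regions. Base regions are slabs
    along y, so the y axis doubles as the rostro-caudal axis used to split
    the volume into fore-, mid- and hindbrain thirds.
    """

    grid: ReferenceGrid
    labels: np.ndarray  # int16, shape = grid.shape_voxels
    classes: np.ndarray  # int8, same shape
    region_labels: list[int]
    region_boxes: dict[int, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def submask(self, label: int, cls: str) -> np.ndarray:
        ci = NT_CLASSES.index(cls) + 1
        return (self.labels == label) & (self.classes == ci)

    def division_masks(self) -> dict[str, np.ndarray]:
        ny = self.grid.shape_voxels[1]
        thirds = [0, ny // 3, 2 * ny // 3, ny]
        names = ("forebrain", "midbrain", "hindbrain")
        out = {}
        for name, lo, hi in zip(names, thirds[:-1], thirds[1:]):
            m = np.zeros(self.grid.shape_voxels, dtype=bool)
            m[:, lo:hi, :] = True
            out[name] = m
        return out

    def to_mask_set(self, include_submasks: bool = True) -> RegionMaskSet:
        masks, rows = {}, []
        div = self.division_masks()
        for lab in self.region_labels:
            name = f"region_{lab:02d}"
            base = self.region_mask(lab)
            masks[name] = base
            rows.append(
                {"name": name, "parent": None, "cls": None,
                 "division": _vol_division(base, div)}
            )
            if include_submasks:
                for cls in NT_CLASSES:
                    sm = self.submask(lab, cls)
                    if sm.any():
                        sname = f"{name}_{cls}"
                        masks[sname] = sm
                        rows.append(
                            {"name": sname, "parent": name, "cls": cls,
                             "division": _vol_division(sm, div)}
                        )
        return RegionMaskSet(
            grid=self.grid, masks=masks, manifest=pd.DataFrame(rows)
        )


def _vol_division(mask: np.ndarray, div: dict[str, np.ndarray]) -> str | None:
    tot = int(np.count_nonzero(mask))
    if tot == 0:
        return None
    for name, dm in div.items():
        if int(np.count_nonzero(mask & dm)) > tot / 2:
            return name
    return None


def generate_toy_atlas(
    shape_voxels: tuple[int, int, int] = (120, 240, 60),
    n_regions: int = 10,
    neurotransmitter_fraction: dict[str, float] | None = None,
    seed: int = 0,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 2.0),
    margin: int = 2,
) -> ToyAtlas:
    """Toy atlas of ``n_regions`` disjoint y-slabs with class submasks.

    Each base region is a full-x, full-z slab along y separated by
    ``margin`` empty voxels. Within each region, voxels are deterministically
    partitioned into neurotransmitter classes at the requested fractions
    (floor-quantized), with the remainder unassigned -- submask voxel counts
    therefore match the fractions up to quantization exactly.
    """
    if neurotransmitter_fraction is None:
        neurotransmitter_fraction = {"gaba": 0.3, "glut": 0.4, "chol": 0.2}
    if sum(neurotransmitter_fraction.values()) > 1.0 + 1e-9:
        raise ValueError("neurotransmitter fractions exceed 1")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape_voxels
    if n_regions * (margin + 1) > ny:
        raise ValueError("regions do not fit in the volume")
    labels = np.zeros(shape_voxels, dtype=np.int16)
    classes = np.zeros(shape_voxels, dtype=np.int8)
    slab = ny // n_regions
    boxes = {}
    region_labels = list(range(1, n_regions + 1))
    for lab in region_labels:
        y0 = (lab - 1) * slab + margin
        y1 = lab * slab - margin if lab < n_regions else ny - margin
        if y1 <= y0:
            raise ValueError("regions do not fit in the volume")
        labels[:, y0:y1, :] = lab
        boxes[lab] = ((0, nx), (y0, y1), (0, nz))
        # deterministic class split inside the region
        n_vox = nx * (y1 - y0) * nz
        perm = rng.permutation(n_vox)
        flat = np.zeros(n_vox, dtype=np.int8)
        pos = 0
        for ci, cls in enumerate(NT_CLASSES, start=1):
            frac = neurotransmitter_fraction.get(cls, 0.0)
            cnt = int(np.floor(frac * n_vox))
            flat[perm[pos : pos + cnt]] = ci
            pos += cnt
        classes[:, y0:y1, :] = flat.reshape(nx, y1 - y0, nz)
    return ToyAtlas(
        grid=ReferenceGrid(shape_voxels=shape_voxels, voxel_size_um=voxel_size_um),
        labels=labels,
        classes=classes,
        region_labels=region_labels,
        region_boxes=boxes,
    )


# ---------------------------------------------------------------------------
# calcium cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study conditions for a two-group synthetic calcium cohort.

    Defaults mirror the recorded cohorts: 11 control vs 9 deficient larvae,
    1-Hz volumetric imaging for 1445 s, a ~0.05-Hz mean event rate, AR1
    decay gamma = 0.9 (GCaMP6s at 1 Hz), and region-restricted planted
    effects: +30% active neurons and -25% event rate in the affected
    regions of the deficient group.
    """

    n_control: int = 11
    n_deficient: int = 9
    neurons_per_larva: int = 400
    effect_active_neurons: float = 0.30
    effect_firing_rate: float = -0.25
    affected_region_labels: tuple[int, ...] = (2, 5, 8)
    duration_s: float = 1445.0
    frame_rate_hz: float = 1.0
    firing_rate_hz: float = 0.05
    gamma: float = 0.9
    snr: float = 5.0
    drift_amp: float = 0.1
    drift_period_s: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_deficient, self.neurons_per_larva) <= 0:
            raise ValueError("counts must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")


@dataclass
class SynthNeuron:
    id: int
    centroid_um: tuple[float, float, float]
    region_label: int
    raw_trace: np.ndarray
    true_spikes: np.ndarray  # nonnegative amplitudes per frame
    true_rate_hz: float
    cum_dff_z: float | None = None
    firing_rate_hz: float | None = None


@dataclass
class SynthLarva:
    larva_id: int
    group: str  # "control" | "deficient"
    neurons: list[SynthNeuron]


@dataclass
class SyntheticGroundTruth:
    group_by_larva: dict[int, str]
    region_by_neuron: dict[tuple[int, int], int]  # (larva, neuron) -> label
    spike_counts: dict[tuple[int, int], int]
    effect_active_neurons: float
    effect_firing_rate: float
    affected_region_labels: tuple[int, ...]


def generate_calcium_cohort(
    spec: CohortSpec,
    atlas: ToyAtlas | None = None,
) -> tuple[list[SynthLarva], SyntheticGroundTruth, ToyAtlas]:
    """Two-group cohort of per-neuron calcium records with known truth.

    The generator inverts the AR1 inference model: per neuron, spikes s_t
    are Bernoulli events (rate scaled in affected regions of deficient
    larvae) with amplitudes ~ U(0.8, 1.2); calcium follows
    c_t = gamma*c_{t-1} + s_t; fluorescence is c plus a slow sinusoidal
    drift (period >= 5 min, exercising the 2-minute moving baseline) and
    white Gaussian noise of sd 1/snr. Active-neuron counts per region are
    Poisson around the per-region mean, scaled by the planted effect in
    affected regions of the deficient group.
    """
    rng = np.random.default_rng(spec.seed)
    if atlas is None:
        atlas = generate_toy_atlas(seed=spec.seed + 1)
    labels = atlas.region_labels
    T = int(round(spec.duration_s * spec.frame_rate_hz))
    vsize = np.asarray(atlas.grid.voxel_size_um)
    base_per_region = spec.neurons_per_larva / len(labels)
    noise_sd = 1.0 / spec.snr if spec.snr > 0 else 0.0

    larvae: list[SynthLarva] = []
    truth = SyntheticGroundTruth(
        group_by_larva={},
        region_by_neuron={},
        spike_counts={},
        effect_active_neurons=spec.effect_active_neurons,
        effect_firing_rate=spec.effect_firing_rate,
        affected_region_labels=tuple(spec.affected_region_labels),
    )
    groups = ["control"] * spec.n_control + ["deficient"] * spec.n_deficient
    for lid, group in enumerate(groups):
        neurons: list[SynthNeuron] = []
        nid = 0
        for lab in labels:
            affected = group == "deficient" and lab in spec.affected_region_labels
            lam = base_per_region * (
                1.0 + (spec.effect_active_neurons if affected else 0.0)
            )
            rate = spec.firing_rate_hz * (
                1.0 + (spec.effect_firing_rate if affected else 0.0)
            )
            n_r = rng.poisson(lam)
            (x0, x1), (y0, y1), (z0, z1) = atlas.region_boxes[lab]
            # keep cubes interior to the region in y (slab) and the volume
            vox = np.column_stack(
                [
                    rng.integers(2, x1 - x0 - 2, n_r) + x0,
                    rng.integers(2, y1 - y0 - 2, n_r) + y0,
                    rng.integers(1, z1 - z0 - 1, n_r) + z0,
                ]
            )
            cents = (vox + 0.5) * vsize
            cents[:, 2] -= 5.0  # undone by the assignment z offset
            p_spike = rate / spec.frame_rate_hz
            spikes_on = rng.random((n_r, T)) < p_spike
            amps = rng.uniform(0.8, 1.2, (n_r, T)) * spikes_on
            calcium = lfilter([1.0], [1.0, -spec.gamma], amps, axis=1)
            phase = rng.uniform(0, 2 * np.pi, n_r)
            t = np.arange(T) / spec.frame_rate_hz
            drift = spec.drift_amp * np.sin(
                2 * np.pi * t[None, :] / spec.drift_period_s + phase[:, None]
            )
            noise = rng.normal(0.0, noise_sd, (n_r, T)) if noise_sd else 0.0
            raw = calcium + drift + noise
            for j in range(n_r):
                neurons.append(
                    SynthNeuron(
                        id=nid,
                        centroid_um=tuple(cents[j]),
                        region_label=lab,
                        raw_trace=raw[j],
                        true_spikes=amps[j],
                        true_rate_hz=rate,
                    )
                )
                truth.region_by_neuron[(lid, nid)] = lab
                truth.spike_counts[(lid, nid)] = int(spikes_on[j].sum())
                nid += 1
        truth.group_by_larva[lid] = group
        larvae.append(SynthLarva(larva_id=lid, group=group, neurons=neurons))
    return larvae, truth, atlas


def save_cohort_h5(path, larvae: list[SynthLarva]) -> None:
    """Write a cohort bundle (centroids, traces, true spikes) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        for larva in larvae:
            g = fh.create_group(f"larva_{larva.larva_id:03d}")
            g.attrs["group"] = larva.group
            g.create_dataset(
                "centroid_um",
                data=np.array([n.centroid_um for n in larva.neurons]),
            )
            g.create_dataset(
                "region_label",
                data=np.array([n.region_label for n in larva.neurons]),
            )
            g.create_dataset(
                "raw_traces", data=np.vstack([n.raw_trace for n in larva.neurons])
            )
            g.create_dataset(
                "true_spikes",
                data=np.vstack([n.true_spikes for n in larva.neurons]),
            )


def load_cohort_h5(path) -> list[SynthLarva]:
    import h5py

    larvae = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            g = fh[key]
            cents = g["centroid_um"][()]
            labs = g["region_label"][()]
            raws = g["raw_traces"][()]
            spikes = g["true_spikes"][()]
            neurons = [
                SynthNeuron(
                    id=i,
                    centroid_um=tuple(cents[i]),
                    region_label=int(labs[i]),
                    raw_trace=raws[i],
                    true_spikes=spikes[i],
                    true_rate_hz=float(spikes[i].astype(bool).mean()),
                )
                for i in range(raws.shape[0])
            ]
            larvae.append(
                SynthLarva(
                    larva_id=int(key.split("_")[1]),
                    group=str(g.attrs["group"]),
                    neurons=neurons,
                )
            )
    return larvae


# ---------------------------------------------------------------------------
# tail traces
# ---------------------------------------------------------------------------

TAIL_EVENT_TYPES = ("swim", "left_flip", "right_flip", "struggle")


def _event_waveform(
    kind: str, n: int, amplitude: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / fs
    env = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
    if kind == "swim":
        f = rng.uniform(15.0, 25.0) if fs >= 60 else rng.uniform(1.0, 2.0)
        return amplitude * env * np.sin(2 * np.pi * f * t + rng.uniform(0, np.pi))
    if kind == "struggle":
        f = rng.uniform(4.0, 8.0) if fs >= 60 else rng.uniform(0.5, 1.5)
        return amplitude * np.sign(np.sin(2 * np.pi * f * t + 0.1)) * env
    sign = 1.0 if kind == "right_flip" else -1.0
    return sign * amplitude * env


def _tracking_noise(
    n: int, sd: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Angle-measurement noise: smooth, bounded jitter of the given sd.

    Tail-angle noise originates from pixel-level jitter of the skeleton,
    so it is temporally smooth (the tail cannot teleport between frames)
    and bounded rather than heavy-tailed. White Gaussian noise is low-pass
    filtered (~15 Hz), rescaled to ``sd``, and clipped at +-2.5 sd.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    x = rng.normal(0.0, 1.0, n)
    cutoff = min(15.0, 0.4 * fs / 2.0)
    if 0 < cutoff < fs / 2.0 and n > 12:
        from scipy.signal import butter, filtfilt

        b, a = butter(2, cutoff / (fs / 2.0))
        x = filtfilt(b, a, x)
    s = x.std()
    if s > 0:
        x = x / s * sd
    return np.clip(x, -2.5 * sd, 2.5 * sd)


def generate_tail_trace(
    event_plan: list[tuple[str, float, float, float]],
    noise_sd: float = 1.5,
    drift_amp: float = 3.0,
    drift_period_s: float = 360.0,
    frame_rate_hz: float = 200.0,
    duration_s: float | None = None,
    seed: int = 0,
    allow_overlap: bool = False,
    min_spacing_s: float = 2.0,
) -> tuple[TailTrace, list[dict]]:
    """Tail-angle trace with planted events over noise and slow drift.

    ``event_plan`` entries are (type, onset_s, duration_s, amplitude_deg)
    with type in {swim, left_flip, right_flip, struggle}. Amplitudes are
    peak degrees; because the realized noise floor tracks ``noise_sd``,
    amplitudes chosen as multiples of ``noise_sd`` deliberately straddle the
    3x/10x/20x classifier thresholds. Struggles are bidirectional square-ish
    oscillations and must be planted at >= 10x ``noise_sd``; flips are
    strictly one-sided humps. Events closer than ``min_spacing_s`` are
    rejected unless ``allow_overlap`` (for testing the merge rule).

    Returns the raw (drifting) trace and the list of planted-event records.
    """
    rng = np.random.default_rng(seed)
    plan = sorted(event_plan, key=lambda e: e[1])
    for kind, onset, dur, amp in plan:
        if kind not in TAIL_EVENT_TYPES:
            raise ValueError(f"unknown event type {kind!r}")
        if kind == "struggle" and amp < 10.0 * noise_sd:
            raise ValueError(
                "struggle amplitude below 10x the nominal noise floor"
            )
    if not allow_overlap:
        for (k1, o1, d1, _), (k2, o2, _, _) in zip(plan, plan[1:]):
            if o2 < o1 + d1 + min_spacing_s:
                raise ValueError(
                    f"events at {o1:.2f}s and {o2:.2f}s violate the "
                    f"{min_spacing_s}-s spacing (pass allow_overlap=True "
                    "to test the merge rule)"
                )
    if duration_s is None:
        duration_s = (plan[-1][1] + plan[-1][2] + 5.0) if plan else 10.0
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    x = _tracking_noise(n, noise_sd, frame_rate_hz, rng) + drift_amp * np.sin(
        2 * np.pi * t / drift_period_s + rng.uniform(0, 2 * np.pi)
    )
    records = []
    for kind, onset, dur, amp in plan:
        i0 = int(round(onset * frame_rate_hz))
        i1 = min(int(round((onset + dur) * frame_rate_hz)), n)
        if i1 <= i0:
            continue
        x[i0:i1] += _event_waveform(kind, i1 - i0, amp, frame_rate_hz, rng)
        records.append(
            {"type": kind, "onset_s": onset, "offset_s": onset + dur,
             "amplitude_deg": amp}
        )
    trace = TailTrace(angle_deg=x, frame_rate_hz=frame_rate_hz)
    return trace, records


# ---------------------------------------------------------------------------
# free-swimming movies
# ---------------------------------------------------------------------------


def render_arena_background(
    n_rows: int = 4,
    n_cols: int = 6,
    well_mm: float = 35.0,
    px_per_mm: float = 7.0,
    wall_px: int = 4,
    background: int = 220,
    wall_value: int = 30,
) -> np.ndarray:
    """Background image of a multi-well plate: bright wells, dark walls."""
    wp = int(round(well_mm * px_per_mm))
    h = n_rows * wp + (n_rows + 1) * wall_px
    w = n_cols * wp + (n_cols + 1) * wall_px
    img = np.full((h, w), wall_value, dtype=np.uint8)
    for r in range(n_rows):
        for c in range(n_cols):
            y0 = wall_px + r * (wp + wall_px)
            x0 = wall_px + c * (wp + wall_px)
            img[y0 : y0 + wp, x0 : x0 + wp] = background
    return img


def render_freeswim_movie(
    trajectory_mm: np.ndarray,
    arena_mm: float = 35.0,
    px_per_mm: float = 7.0,
    contrast: float = 30.0,
    background: int = 220,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Grayscale frames of one well with a dark eye blob along a trajectory.

    ``trajectory_mm`` is (n_frames, 2) positions inside a square well of
    side ``arena_mm``; the eye cluster is rendered as a 3x3-ish blob darker
    than the background by ``contrast`` grey levels (the tracker requires
    >= 10). Positions outside the well raise.
    """
    traj = np.asarray(trajectory_mm, dtype=float)
    if np.any(traj < 0) or np.any(traj > arena_mm):
        raise ValueError("trajectory leaves the arena")
    rng = np.random.default_rng(seed)
    side = int(round(arena_mm * px_per_mm))
    frames = np.empty((traj.shape[0], side, side), dtype=np.uint8)
    yy, xx = np.mgrid[0:side, 0:side]
    for i, (x_mm, y_mm) in enumerate(traj):
        img = background + rng.normal(0.0, noise_sd, (side, side))
        cx, cy = x_mm * px_per_mm, y_mm * px_per_mm
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        blob = np.exp(-d2 / (2 * 1.2**2))
        img -= contrast * (blob / blob.max())
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames
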