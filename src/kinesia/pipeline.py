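"""End-to-end pipeline runs with a single config and reproducible seeds.

A run generates (or loads) inputs, processes tail behavior, calcium
traces, atlas mapping, two-group comparison, and motor clustering, writing
each stage's outputs plus a manifest with per-file checksums. Every stage
draws its randomness from a seed derived from the master seed by stable
hashing, so stages are individually reproducible and two runs with the
same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import calcium, clustering, compare, synthetic, tail_events, tail_kinematics


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline thresholds, with the published defaults.

    Synthetic-cohort sizes default to a desk-scale demo (3 + 3 larvae,
    60 neurons, 300 s); the statistical thresholds default to the values
    used throughout the analysis (35% exploration cut-off, 2-s merge gap,
    10x/20x/3x event classifiers, 10-voxel mask overlap, 12-um heatmap
    voxels, alpha 0.05, clustering start t=3 with 20% stability, 0.8
    connectivity threshold).
    """

    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "tail", "calcium", "map", "compare", "cluster",
    )
    # synthetic cohort (demo scale)
    n_control: int = 3
    n_deficient: int = 3
    neurons_per_larva: int = 60
    duration_s: float = 300.0
    effect_active_neurons: float = 0.30
    effect_firing_rate: float = -0.25
    affected_region_labels: tuple[int, ...] = (2, 5, 8)
    atlas_shape: tuple[int, int, int] = (120, 240, 60)
    n_regions: int = 10
    # tail
    tail_frame_rate_hz: float = 200.0
    tail_noise_sd_deg: float = 1.5
    baseline_window_s: float = 60.0
    gap_s: float = 2.0
    peak_k: float = 3.0
    struggle_k: float = 10.0
    flip_ratio: float = 20.0
    flip_floor_k: float = 3.0
    resample_outlier_q: float = 0.90
    # freeswim
    cutoff_pct: float = 35.0
    # calcium
    calcium_window_s: float = 120.0
    spike_threshold_k: float = 1.5
    # atlas / comparison
    min_overlap: int = 10
    voxel_um: float = 12.0
    alpha: float = 0.05
    # clustering
    t0: int = 3
    stability: float = 0.2
    connectivity_threshold: float = 0.8

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        d = dict(d)
        for key in ("stages", "affected_region_labels", "atlas_shape"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stages", "affected_region_labels", "atlas_shape"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the configured stages, writing outputs and a manifest.

    Returns the manifest dict. Stage failure raises
    :class:`PipelineError` tagged with the stage name; earlier outputs are
    preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    written: list[Path] = []
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise ConfigError(f"unknown stage {stage!r}")
        try:
            written.extend(fn(config, state, out))
        except Exception as exc:  # noqa: BLE001 - tag and halt
            raise PipelineError(stage, exc) from exc
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "checksums": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    seed = stage_seed(cfg.seed, "simulate")
    toy = synthetic.generate_toy_atlas(
        shape_voxels=tuple(cfg.atlas_shape),
        n_regions=cfg.n_regions,
        seed=seed,
    )
    spec = synthetic.CohortSpec(
        n_control=cfg.n_control,
        n_deficient=cfg.n_deficient,
        neurons_per_larva=cfg.neurons_per_larva,
        duration_s=cfg.duration_s,
        effect_active_neurons=cfg.effect_active_neurons,
        effect_firing_rate=cfg.effect_firing_rate,
        affected_region_labels=tuple(cfg.affected_region_labels),
        seed=seed,
    )
    larvae, truth, toy = synthetic.generate_calcium_cohort(spec, toy)
    rng = np.random.default_rng(seed + 1)
    tails = []
    for larva in larvae:
        plan = []
        t = 5.0
        n_struggle = 2 if larva.group == "control" else 5
        while t < cfg.duration_s - 15:
            kind = rng.choice(["swim", "swim", "left_flip", "right_flip"])
            plan.append((str(kind), float(t), 1.0, float(rng.uniform(6, 9)) * cfg.tail_noise_sd_deg))
            t += float(rng.uniform(8, 15))
        slots = np.linspace(10, cfg.duration_s - 20, n_struggle)
        plan = [p for p in plan if all(abs(p[1] - s) > 6 for s in slots)]
        for s in slots:
            plan.append(("struggle", float(s), 2.0, 18.0 * cfg.tail_noise_sd_deg))
        plan.sort(key=lambda p: p[1])
        plan = _enforce_spacing(plan)
        trace, events = synthetic.generate_tail_trace(
            plan,
            noise_sd=cfg.tail_noise_sd_deg,
            frame_rate_hz=cfg.tail_frame_rate_hz,
            duration_s=cfg.duration_s,
            seed=int(rng.integers(2**31)),
        )
        tails.append((trace, events))
    state.update(atlas=toy, larvae=larvae, truth=truth, tails=tails)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                "groups": {str(k): v for k, v in truth.group_by_larva.items()},
                "effect_active_neurons": truth.effect_active_neurons,
                "effect_firing_rate": truth.effect_firing_rate,
                "affected_region_labels": list(truth.affected_region_labels),
                "n_neurons": [len(l.neurons) for l in larvae],
            },
            indent=2,
        )
    )
    return [gt_path]


def _enforce_spacing(plan: list, spacing: float = 4.5) -> list:
    kept = []
    for p in plan:
        if not kept or p[1] >= kept[-1][1] + kept[-1][2] + spacing:
            kept.append(p)
    return kept


def _stage_tail(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    written = []
    state["tail_1hz"] = []
    state["tail_summaries"] = []
    for i, (trace, _events) in enumerate(state["tails"]):
        filled = tail_kinematics.fill_nans(trace)
        corrected = tail_kinematics.remove_baseline(
            filled, window_s=cfg.baseline_window_s
        )
        evs, nf = tail_events.extract_events(
            corrected,
            gap_s=cfg.gap_s,
            peak_k=cfg.peak_k,
            struggle_k=cfg.struggle_k,
            flip_ratio=cfg.flip_ratio,
            flip_floor_k=cfg.flip_floor_k,
        )
        summary = tail_events.summarize(evs, corrected)
        resampled = tail_kinematics.resample_to_imaging(
            corrected, target_hz=1.0, outlier_q=cfg.resample_outlier_q
        )
        state["tail_1hz"].append(resampled)
        state["tail_summaries"].append(summary)
        ev_path = out / f"tail_events_larva{i:02d}.csv"
        tail_events.events_to_frame(evs).to_csv(ev_path, index=False)
        sm_path = out / f"tail_summary_larva{i:02d}.json"
        sm_path.write_text(json.dumps(summary.to_dict(), indent=2))
        written += [ev_path, sm_path]
    return written


def _stage_calcium(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    written = []
    for larva in state["larvae"]:
        dffs = []
        for n in larva.neurons:
            _, dff = calcium.normalize_and_baseline(
                n.raw_trace, window_s=cfg.calcium_window_s
            )
            dffs.append(dff)
            g = calcium.estimate_gamma(dff)
            sd = calcium.estimate_noise_sd(dff)
            spikes, _info = calcium.deconvolve_ar1(
                dff, calcium.DeconvModel(gamma=g, noise_sd=sd)
            )
            n.firing_rate_hz = calcium.firing_rate(
                spikes,
                duration_s=cfg.duration_s,
                threshold=calcium.spike_threshold(sd, cfg.spike_threshold_k),
            )
            n.dff_trace = dff
        z = calcium.cumulative_dff(dffs)
        for n, zi in zip(larva.neurons, z):
            n.cum_dff_z = float(zi)
        path = out / f"neurons_larva{larva.larva_id:02d}.csv"
        pd.DataFrame(
            {
                "id": [n.id for n in larva.neurons],
                "x_um": [n.centroid_um[0] for n in larva.neurons],
                "y_um": [n.centroid_um[1] for n in larva.neurons],
                "z_um": [n.centroid_um[2] for n in larva.neurons],
                "cum_dff_z": [n.cum_dff_z for n in larva.neurons],
                "firing_rate_hz": [n.firing_rate_hz for n in larva.neurons],
            }
        ).to_csv(path, index=False)
        written.append(path)
    return written


def _stage_map(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    toy = state["atlas"]
    masks = toy.to_mask_set()
    div = toy.division_masks()
    state["masks"] = masks
    tables = []
    written = []
    for larva in state["larvae"]:
        tbl = atlas_mod.region_table(
            larva.neurons, masks, min_overlap=cfg.min_overlap,
            division_masks=div,
        )
        tables.append(tbl)
        path = out / f"regions_larva{larva.larva_id:02d}.csv"
        tbl.to_csv(path)
        written.append(path)
    state["region_tables"] = tables
    return written


def _stage_compare(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    toy = state["atlas"]
    groups = [l.group for l in state["larvae"]]
    ctrl = [l.neurons for l in state["larvae"] if l.group == "control"]
    dfc = [l.neurons for l in state["larvae"] if l.group == "deficient"]
    h_ctrl = compare.build_heatmaps(ctrl, toy.grid, voxel_um=cfg.voxel_um)
    h_def = compare.build_heatmaps(dfc, toy.grid, voxel_um=cfg.voxel_um)
    vox = compare.voxelwise_test(h_ctrl, h_def, alpha=cfg.alpha)
    relevance = compare.map_to_masks(vox, state["masks"], voxel_um=cfg.voxel_um)
    rel_path = out / "relevance.csv"
    relevance.to_csv(rel_path)
    tables = state["region_tables"]
    t_ctrl = [t for t, g in zip(tables, groups) if g == "control"]
    t_def = [t for t, g in zip(tables, groups) if g == "deficient"]
    written = [rel_path]
    for metric in ("n_active", "cum_dff_z_sum", "firing_rate_mean_hz"):
        res = compare.region_test(
            t_ctrl, t_def, metric=metric, alpha=cfg.alpha,
            with_permutation=True,
            seed=stage_seed(cfg.seed, f"compare:{metric}"),
        )
        path = out / f"region_test_{metric}.csv"
        res.to_csv(path)
        written.append(path)
    return written


def _stage_cluster(cfg: RunConfig, state: dict, out: Path) -> list[Path]:
    written = []
    masks = state["masks"]
    for larva, tail in zip(state["larvae"], state["tail_1hz"]):
        act = np.vstack([n.dff_trace for n in larva.neurons])
        T = min(act.shape[1], tail.angle_deg.size)
        part = clustering.motor_partition(
            act[:, :T], tail.angle_deg[:T], t0=cfg.t0, stability=cfg.stability
        )
        path = out / f"motor_partition_larva{larva.larva_id:02d}.csv"
        pd.DataFrame(
            {
                "id": [n.id for n in larva.neurons],
                "label": np.where(part.motor, "motor", "non_motor"),
                "tail_rho": part.tail_corr,
            }
        ).to_csv(path, index=False)
        written.append(path)
    return written


_STAGES = {
    "simulate": _stage_simulate,
    "tail": _stage_tail,
    "calcium": _stage_calcium,
    "map": _stage_map,
    "compare": _stage_compare,
    "cluster": _stage_cluster,
}
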