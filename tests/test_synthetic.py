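import numpy as np
import pytest

from kinesia import synthetic, tail_events
from kinesia.calcium import deconvolve_ar1, DeconvModel
from kinesia.tail_kinematics import fill_nans, remove_baseline


class TestToyAtlas:
    def test_base_regions_disjoint(self, toy_atlas):
        # labels are exclusive by construction; verify the union leaves gaps
        assert (toy_atlas.labels >= 0).all()
        covered = np.count_nonzero(toy_atlas.labels)
        assert covered < toy_atlas.labels.size

    def test_submasks_subset_of_parent(self, toy_atlas):
        for lab in toy_atlas.region_labels:
            parent = toy_atlas.region_mask(lab)
            for cls in synthetic.NT_CLASSES:
                sub = toy_atlas.submask(lab, cls)
                assert not (sub & ~parent).any()

    def test_submask_fractions_quantized(self, toy_atlas):
        fr = {"gaba": 0.3, "glut": 0.4, "chol": 0.2}
        for lab in (1, 5):
            n_parent = int(toy_atlas.region_mask(lab).sum())
            for cls, f in fr.items():
                n_sub = int(toy_atlas.submask(lab, cls).sum())
                assert n_sub == int(np.floor(f * n_parent))

    def test_single_whole_volume_region_catches_every_cube(self):
        from kinesia.atlas import assign_all

        atlas = synthetic.generate_toy_atlas(
            shape_voxels=(40, 40, 20), n_regions=1, margin=0, seed=0
        )
        masks = atlas.to_mask_set(include_submasks=False)
        rng = np.random.default_rng(1)
        cents = np.column_stack(
            [rng.uniform(5, 35, 10), rng.uniform(5, 35, 10), rng.uniform(5, 25, 10)]
        )
        assigned = assign_all(cents, masks)
        assert all("region_01" in a for a in assigned)

    def test_determinism(self):
        a = synthetic.generate_toy_atlas(seed=5)
        b = synthetic.generate_toy_atlas(seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.classes, b.classes)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_toy_atlas(
                neurotransmitter_fraction={"gaba": 0.8, "glut": 0.5}
            )


class TestCohort:
    def test_determinism_bit_identical(self, toy_atlas):
        spec = synthetic.CohortSpec(
            n_control=2, n_deficient=2, neurons_per_larva=30,
            duration_s=100.0, seed=1,
        )
        a, _, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        b, _, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        for la, lb in zip(a, b):
            for na, nb in zip(la.neurons, lb.neurons):
                assert np.array_equal(na.raw_trace, nb.raw_trace)
                assert na.centroid_um == nb.centroid_um

    def test_null_effect_equal_rates(self, toy_atlas):
        spec = synthetic.CohortSpec(
            n_control=5, n_deficient=5, neurons_per_larva=200,
            duration_s=400.0, effect_firing_rate=0.0,
            effect_active_neurons=0.0, seed=2,
        )
        larvae, truth, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        rates = {"control": [], "deficient": []}
        for l in larvae:
            counts = [truth.spike_counts[(l.larva_id, n.id)] for n in l.neurons]
            rates[l.group].append(np.mean(counts) / spec.duration_s)
        diff = abs(np.mean(rates["control"]) - np.mean(rates["deficient"]))
        assert diff < 0.004  # sampling error at these sizes

    def test_expected_spike_count_vs_poisson_oracle(self, toy_atlas):
        spec = synthetic.CohortSpec(
            n_control=2, n_deficient=1, neurons_per_larva=200,
            duration_s=1445.0, firing_rate_hz=0.05,
            effect_active_neurons=0.0, effect_firing_rate=0.0, seed=3,
        )
        larvae, truth, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        counts = [c for c in truth.spike_counts.values()]
        # oracle: Bernoulli(0.05) over 1445 frames -> mean 72.25
        assert np.mean(counts) == pytest.approx(0.05 * 1445, rel=0.03)

    def test_planted_effects_in_affected_regions_only(self, toy_atlas):
        spec = synthetic.CohortSpec(
            n_control=10, n_deficient=10, neurons_per_larva=800,
            duration_s=60.0, seed=4,
        )
        larvae, truth, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        aff = set(spec.affected_region_labels)
        n_aff = {"control": [], "deficient": []}
        n_un = {"control": [], "deficient": []}
        for l in larvae:
            n_aff[l.group].append(sum(n.region_label in aff for n in l.neurons))
            n_un[l.group].append(sum(n.region_label not in aff for n in l.neurons))
        boost = np.mean(n_aff["deficient"]) / np.mean(n_aff["control"]) - 1
        null = np.mean(n_un["deficient"]) / np.mean(n_un["control"]) - 1
        assert boost == pytest.approx(0.30, abs=0.08)
        assert null == pytest.approx(0.0, abs=0.05)

    def test_noiseless_generator_inverts_through_deconvolution(self, toy_atlas):
        spec = synthetic.CohortSpec(
            n_control=1, n_deficient=1, neurons_per_larva=20,
            duration_s=300.0, snr=0.0, drift_amp=0.0, seed=5,
        )
        larvae, truth, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        for l in larvae:
            for n in l.neurons[:5]:
                s, info = deconvolve_ar1(
                    n.raw_trace, DeconvModel(gamma=spec.gamma, noise_sd=0.0)
                )
                assert np.allclose(s, n.true_spikes, atol=1e-8)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            synthetic.CohortSpec(gamma=1.2)

    def test_h5_roundtrip(self, toy_atlas, tmp_path):
        spec = synthetic.CohortSpec(
            n_control=1, n_deficient=1, neurons_per_larva=10,
            duration_s=50.0, seed=6,
        )
        larvae, _, _ = synthetic.generate_calcium_cohort(spec, toy_atlas)
        path = tmp_path / "cohort.h5"
        synthetic.save_cohort_h5(path, larvae)
        back = synthetic.load_cohort_h5(path)
        assert [l.group for l in back] == [l.group for l in larvae]
        for la, lb in zip(larvae, back):
            for na, nb in zip(la.neurons, lb.neurons):
                assert np.array_equal(na.raw_trace, nb.raw_trace)
                assert na.region_label == nb.region_label


class TestTailTraceGenerator:
    def test_empty_plan_stays_below_3x_noise_floor(self):
        trace, truth = synthetic.generate_tail_trace(
            [], noise_sd=1.0, drift_amp=0.0, duration_s=60.0, seed=0
        )
        nf = tail_events.noise_floor(trace)
        assert truth == []
        frac_above = np.mean(np.abs(trace.angle_deg) > 3.0 * nf.value_deg)
        assert frac_above <= 0.005  # chance level only

    def test_single_struggle_recovered(self):
        trace, _ = synthetic.generate_tail_trace(
            [("struggle", 20.0, 1.5, 50.0)],
            noise_sd=1.5, frame_rate_hz=200.0, duration_s=120.0, seed=1,
        )
        corrected = remove_baseline(fill_nans(trace))
        evs, _ = tail_events.extract_events(corrected)
        assert [e.type for e in evs] == ["struggle"]

    def test_close_swims_merge_downstream(self):
        trace, _ = synthetic.generate_tail_trace(
            [("swim", 60.0, 1.0, 9.0), ("swim", 62.5, 1.0, 9.0)],
            noise_sd=1.5, frame_rate_hz=200.0, duration_s=180.0, seed=2,
            allow_overlap=True,
        )
        corrected = remove_baseline(fill_nans(trace))
        evs, _ = tail_events.extract_events(corrected)
        assert len(evs) == 1

    def test_spacing_violation_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_tail_trace(
                [("swim", 5.0, 1.0, 9.0), ("swim", 6.5, 1.0, 9.0)],
                seed=0,
            )

    def test_weak_struggle_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_tail_trace(
                [("struggle", 5.0, 1.0, 10.0)], noise_sd=1.5, seed=0
            )

    def test_flip_is_one_sided(self):
        trace, _ = synthetic.generate_tail_trace(
            [("right_flip", 10.0, 1.0, 9.0)],
            noise_sd=0.5, drift_amp=0.0, duration_s=20.0, seed=3,
        )
        i0, i1 = int(10.0 * 200), int(11.0 * 200)
        seg = trace.angle_deg[i0:i1]
        assert seg.max() > 6.0
        assert seg.min() > -2.0  # only bounded noise on the other side


class TestFreeswimRender:
    def test_stationary_larva_recovers_zero_distance(self):
        from kinesia import freeswim as fs

        traj_mm = np.tile([17.5, 17.5], (40, 1))
        frames = synthetic.render_freeswim_movie(traj_mm, seed=0)
        layout = fs.ArenaLayout(
            wells=[(0, 0, frames.shape[1], frames.shape[2])], mm_per_px=1 / 7.0
        )
        traj = fs.track_larva(frames, layout.wells[0], layout, frame_rate_hz=40.0)
        m = fs.compute_metrics(traj, layout)
        assert m.total_distance_mm < 0.5

    def test_straight_path_length_recovered(self):
        from kinesia import freeswim as fs

        n = 80
        traj_mm = np.column_stack(
            [np.linspace(10, 20, n), np.full(n, 17.5)]
        )
        frames = synthetic.render_freeswim_movie(traj_mm, seed=1)
        layout = fs.ArenaLayout(
            wells=[(0, 0, frames.shape[1], frames.shape[2])], mm_per_px=1 / 7.0
        )
        traj = fs.track_larva(frames, layout.wells[0], layout, frame_rate_hz=40.0)
        m = fs.compute_metrics(traj, layout)
        assert m.total_distance_mm == pytest.approx(10.0, rel=0.02)
        # px-level recovery of the rendered path
        err = np.hypot(
            traj.x_mm - traj_mm[:, 0], traj.y_mm - traj_mm[:, 1]
        ) / layout.mm_per_px
        assert np.sqrt(np.mean(err**2)) < 1.0

    def test_low_contrast_flags_snr(self):
        from kinesia import freeswim as fs

        traj_mm = np.tile([17.5, 17.5], (20, 1))
        frames = synthetic.render_freeswim_movie(traj_mm, contrast=5.0, seed=2)
        layout = fs.ArenaLayout(
            wells=[(0, 0, frames.shape[1], frames.shape[2])], mm_per_px=1 / 7.0
        )
        traj = fs.track_larva(frames, layout.wells[0], layout, frame_rate_hz=40.0)
        assert traj.low_snr

    def test_trajectory_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            synthetic.render_freeswim_movie(np.array([[40.0, 10.0]]))
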