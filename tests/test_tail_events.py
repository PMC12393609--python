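import numpy as np
import pytest

from kinesia import tail_events as te
from kinesia.tail_kinematics import TailTrace

from conftest import planted_event_plan
from kinesia.synthetic import generate_tail_trace


def make_trace(x, fs=100.0):
    return TailTrace(
        angle_deg=np.asarray(x, float), frame_rate_hz=fs, baseline_removed=True
    )


def triangle(peak, half_width):
    up = np.linspace(0, peak, half_width, endpoint=False)
    return np.concatenate([up, [peak], up[::-1]])


class TestNoiseFloor:
    def test_zero_trace(self):
        assert te.noise_floor(make_trace(np.zeros(10))).value_deg == 0.0

    def test_hand_computed_rms(self):
        nf = te.noise_floor(make_trace([3, -4, 0, 5]))
        assert nf.value_deg == pytest.approx(np.sqrt(12.5))

    def test_gaussian_noise_converges_to_sd(self):
        rng = np.random.default_rng(0)
        nf = te.noise_floor(make_trace(rng.normal(0, 2.5, 200_000)))
        assert nf.value_deg == pytest.approx(2.5, rel=0.01)


class TestDetect:
    def _embed(self, wave, n=2000, at=1000, nf=1.0):
        x = np.zeros(n)
        x[at : at + wave.size] += wave
        return make_trace(x), te.NoiseFloor(nf)

    def test_single_peak_above_3nf_detected(self):
        trace, nf = self._embed(triangle(5.0, 20))
        evs = te.detect_events(trace, nf)
        assert len(evs) == 1
        assert evs[0].peak_deg == pytest.approx(5.0)

    def test_peak_below_3nf_ignored(self):
        trace, nf = self._embed(triangle(2.5, 20))
        assert te.detect_events(trace, nf) == []

    def test_low_prominence_second_peak_collapses(self):
        # two 4xNF peaks on one envelope; the dip between them is shallow
        # (< NF prominence for the second), so one event results
        wave = np.concatenate([triangle(4.0, 30)[:-10], triangle(4.0, 30)[10:]])
        trace, nf = self._embed(wave)
        evs = te.detect_events(trace, nf)
        assert len(evs) == 1

    def test_zero_noise_floor_rejected(self):
        with pytest.raises(ValueError):
            te.detect_events(make_trace(np.zeros(100)), te.NoiseFloor(0.0))

    def test_events_do_not_overlap(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 5000)
        for at in (500, 1500, 1520, 3000):
            x[at : at + 41] += triangle(8.0, 20)
        trace = make_trace(x)
        evs = te.detect_events(trace, te.noise_floor(trace))
        for a, b in zip(evs, evs[1:]):
            assert a.offset_idx <= b.onset_idx


class TestMerge:
    def _events(self, spans, fs=100.0):
        evs = []
        for lo, hi in spans:
            evs.append(
                te.TailEvent(
                    onset_s=lo / fs, offset_s=hi / fs, onset_idx=lo,
                    offset_idx=hi, peak_deg=5.0, prominence_deg=5.0,
                    peak_pos_deg=5.0, peak_neg_deg=0.0,
                    angle_sum_pos_deg=10.0, angle_sum_neg_deg=0.0,
                )
            )
        return evs

    def test_sub_gap_events_merge(self):
        out = te.merge_events(self._events([(0, 100), (250, 300)]), gap_s=2.0)
        assert len(out) == 1
        assert out[0].offset_s == pytest.approx(3.0)

    def test_exact_gap_stays_separate(self):
        out = te.merge_events(self._events([(0, 100), (300, 350)]), gap_s=2.0)
        assert len(out) == 2

    def test_transitive_chain(self):
        # gaps 1 s, 1 s, 3 s -> two events
        spans = [(0, 100), (200, 300), (400, 500), (800, 900)]
        out = te.merge_events(self._events(spans), gap_s=2.0)
        assert len(out) == 2


class TestClassify:
    def _event(self, pos, neg, sum_pos, sum_neg):
        return te.TailEvent(
            onset_s=0, offset_s=1, onset_idx=0, offset_idx=100,
            peak_deg=pos, prominence_deg=pos, peak_pos_deg=pos,
            peak_neg_deg=neg, angle_sum_pos_deg=sum_pos,
            angle_sum_neg_deg=sum_neg,
        )

    def test_bidirectional_large_event_is_struggle(self):
        ev = self._event(50.0, -48.0, 300.0, 280.0)
        assert te.classify_event(ev, te.NoiseFloor(4.5)) == "struggle"

    def test_one_sided_ratio_is_flip(self):
        ev = self._event(30.0, -5.0, 100.0, 3.0)
        assert te.classify_event(ev, te.NoiseFloor(4.5)) == "right_flip"
        ev = self._event(5.0, -30.0, 3.0, 100.0)
        assert te.classify_event(ev, te.NoiseFloor(4.5)) == "left_flip"

    def test_pure_one_sided_event_is_flip(self):
        ev = self._event(20.0, -1.0, 60.0, 0.0)
        assert te.classify_event(ev, te.NoiseFloor(4.5)) == "right_flip"

    def test_balanced_moderate_event_is_swim(self):
        ev = self._event(40.0, -35.0, 50.0, 40.0)
        assert te.classify_event(ev, te.NoiseFloor(4.5)) == "swim"


class TestSummarize:
    def test_no_events_only_whole_trace_cumulative(self):
        trace = make_trace([1.0, -2.0, 1.0])
        s = te.summarize([], trace)
        assert s.n_events == 0
        assert all(v == 0 for v in s.counts.values())
        assert s.cumulative_angle_deg == pytest.approx(4.0)

    def test_planted_counts_recovered(self):
        plan = [
            ("swim", 20.0, 1.0, 9.0),
            ("swim", 80.0, 1.0, 9.0),
            ("swim", 140.0, 1.0, 9.0),
            ("struggle", 200.0, 1.5, 27.0),
            ("struggle", 260.0, 1.5, 27.0),
        ]
        trace, _ = generate_tail_trace(
            plan, noise_sd=1.5, drift_amp=0.0, frame_rate_hz=200.0,
            duration_s=300.0, seed=2,
        )
        evs, _ = te.extract_events(make_trace(trace.angle_deg, fs=200.0))
        s = te.summarize(evs, trace)
        assert s.counts["swim"] == 3
        assert s.counts["struggle"] == 2

    def test_cumulative_additivity(self):
        a, b = make_trace([1, -1, 2]), make_trace([3, -4])
        whole = make_trace([1, -1, 2, 3, -4])
        assert te.summarize([], whole).cumulative_angle_deg == pytest.approx(
            te.summarize([], a).cumulative_angle_deg
            + te.summarize([], b).cumulative_angle_deg
        )


class TestProperties:
    def _planted_trace(self, seed):
        rng = np.random.default_rng(seed)
        plan = planted_event_plan(rng, duration_s=400.0)
        trace, truth = generate_tail_trace(
            plan, noise_sd=1.5, frame_rate_hz=200.0, duration_s=400.0,
            seed=seed,
        )
        from kinesia.tail_kinematics import fill_nans, remove_baseline

        return remove_baseline(fill_nans(trace)), truth

    def test_mirror_symmetry_swaps_flips(self):
        trace, _ = self._planted_trace(21)
        evs, _ = te.extract_events(trace)
        neg = TailTrace(
            angle_deg=-trace.angle_deg, frame_rate_hz=trace.frame_rate_hz,
            baseline_removed=True,
        )
        evs_n, _ = te.extract_events(neg)
        count = lambda evs, t: sum(e.type == t for e in evs)
        assert count(evs, "left_flip") == count(evs_n, "right_flip")
        assert count(evs, "right_flip") == count(evs_n, "left_flip")
        assert count(evs, "swim") == count(evs_n, "swim")
        assert count(evs, "struggle") == count(evs_n, "struggle")

    def test_scaling_invariance_of_labels(self):
        trace, _ = self._planted_trace(22)
        evs, nf = te.extract_events(trace)
        scaled = TailTrace(
            angle_deg=3.0 * trace.angle_deg, frame_rate_hz=trace.frame_rate_hz,
            baseline_removed=True,
        )
        evs_s, nf_s = te.extract_events(scaled)
        assert nf_s.value_deg == pytest.approx(3.0 * nf.value_deg)
        assert [e.type for e in evs_s] == [e.type for e in evs]
        assert [e.onset_idx for e in evs_s] == [e.onset_idx for e in evs]

    def test_classification_exhaustive(self):
        trace, _ = self._planted_trace(23)
        evs, _ = te.extract_events(trace)
        assert evs, "expected planted events to be detected"
        assert all(e.type in te.EVENT_TYPES for e in evs)
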