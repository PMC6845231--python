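import numpy as np
import pytest

import flyca as fc
from conftest import make_trace_set


class TestExtractTraces:
    def test_uniform_movie_cancels_to_zero(self):
        data = np.full((5, 16, 16), 3.0)
        labels = np.zeros((16, 16), dtype=int)
        labels[4:8, 4:8] = 1
        movie = fc.Movie(data=data, timestamps=np.arange(5) / 10)
        ts = fc.extract_traces(movie, fc.ROISet(labels=labels))
        assert np.allclose(ts.values, 0.0)

    def test_background_subtraction_arithmetic(self):
        data = np.full((4, 16, 16), 2.0)
        labels = np.zeros((16, 16), dtype=int)
        labels[4:8, 4:8] = 1
        data[:, 4:8, 4:8] = 10.0
        movie = fc.Movie(data=data, timestamps=np.arange(4) / 10)
        ts = fc.extract_traces(movie, fc.ROISet(labels=labels))
        assert np.allclose(ts.values[0], 8.0)

    def test_missing_roi_id_rejected(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:4, 2:4] = 1
        with pytest.raises(ValueError):
            fc.ROISet(labels=labels, roi_ids=[1, 2])

    def test_shape_mismatch_rejected(self):
        movie = fc.Movie(data=np.zeros((3, 8, 8)), timestamps=np.arange(3) / 10)
        with pytest.raises(ValueError):
            fc.extract_traces(movie, fc.ROISet(labels=np.zeros((9, 9), dtype=int)))

    def test_empty_background_warns(self):
        labels = np.ones((8, 8), dtype=int)
        movie = fc.Movie(data=np.full((3, 8, 8), 5.0),
                         timestamps=np.arange(3) / 10)
        with pytest.warns(UserWarning, match="background"):
            ts = fc.extract_traces(movie, fc.ROISet(labels=labels))
        assert np.allclose(ts.values, 5.0)


class TestResampleAndSegment:
    def test_native_ten_hz_is_identity(self):
        proto = fc.build_flash_protocol(1, 1.0)
        times = np.arange(0, 2.0, 0.1)
        vals = np.sin(times)
        ts = make_trace_set(vals, times, proto)
        segs = fc.resample_and_segment(ts, proto)
        s0 = [s for s in segs.segments if s.epoch_index == 0][0]
        assert np.allclose(s0.values, vals[:10])

    def test_constant_trace_is_interpolation_invariant(self):
        proto = fc.build_flash_protocol(1, 1.0)
        times = np.arange(0, 2.0, 1 / 15)
        ts = make_trace_set(np.full_like(times, 4.2), times, proto)
        segs = fc.resample_and_segment(ts, proto)
        for s in segs.segments:
            assert np.allclose(s.values, 4.2)

    def test_linear_ramp_is_exact(self):
        # linear interpolation reproduces affine signals exactly
        proto = fc.build_flash_protocol(1, 1.0)
        times = np.arange(0, 2.0, 1 / 12)
        ts = make_trace_set(times.copy(), times, proto)
        segs = fc.resample_and_segment(ts, proto)
        for s in segs.segments:
            onset = proto.onsets()[s.epoch_index]
            assert np.allclose(s.values, s.t + onset)

    def test_grid_locked_to_onset(self):
        proto = fc.build_flash_protocol(2, 5.0)
        times = np.arange(0, 20.0, 1 / 13)
        ts = make_trace_set(np.zeros_like(times), times, proto)
        segs = fc.resample_and_segment(ts, proto)
        for s in segs.segments:
            assert s.t[s.n_pre] == 0.0
            assert np.allclose(np.diff(s.t), 0.1)

    def test_epoch_outside_recording_dropped(self):
        proto = fc.build_flash_protocol(2, 5.0)  # needs 20 s
        times = np.arange(0, 12.0, 0.1)
        ts = make_trace_set(np.zeros_like(times), times, proto)
        with pytest.warns(UserWarning, match="dropped"):
            segs = fc.resample_and_segment(ts, proto)
        assert {s.epoch_index for s in segs.segments} == {0, 1}

    def test_pre_context_available_after_first_epoch(self):
        proto = fc.build_flash_protocol(2, 5.0)
        times = np.arange(0, 20.0, 0.1)
        ts = make_trace_set(np.zeros_like(times), times, proto)
        segs = fc.resample_and_segment(ts, proto)
        by_index = {s.epoch_index: s for s in segs.segments}
        assert by_index[0].n_pre == 0
        assert by_index[1].n_pre == 20   # full 2 s at 10 Hz
        assert by_index[2].n_pre == 20


class TestComputeDff:
    def _dff_of(self, values, times, proto, **kwargs):
        ts = make_trace_set(values, times, proto)
        segs = fc.resample_and_segment(ts, proto)
        return fc.compute_dff(segs, **kwargs)

    def test_whole_trace_mean_worked_example(self):
        proto = fc.build_flash_protocol(1, 0.2)
        dff = self._dff_of([1.0, 1.0, 3.0, 3.0], [0.0, 0.1, 0.2, 0.3], proto)
        concat = np.concatenate([s.epoch_values for s in sorted(
            dff.segments, key=lambda s: s.epoch_index)])
        assert np.allclose(concat, [-0.5, -0.5, 0.5, 0.5])
        assert dff.f0[1] == pytest.approx(2.0)

    def test_constant_trace_gives_zero_dff(self):
        proto = fc.build_flash_protocol(1, 1.0)
        times = np.arange(0, 2.0, 0.1)
        dff = self._dff_of(np.full_like(times, 5.0), times, proto)
        for s in dff.segments:
            assert np.allclose(s.values, 0.0)

    def test_whole_trace_mode_has_zero_mean_dff(self):
        proto = fc.build_flash_protocol(2, 5.0)
        times = np.arange(0, 20.0, 0.1)
        rng = np.random.default_rng(0)
        vals = 5.0 + rng.normal(0, 0.5, len(times))
        ts = make_trace_set(vals, times, proto)
        segs = fc.resample_and_segment(ts, proto)
        f0 = segs.whole_trace_mean[1]
        assert np.mean((vals - f0) / f0) == pytest.approx(0.0, abs=1e-12)

    def test_gain_invariance(self):
        proto = fc.build_flash_protocol(2, 5.0)
        times = np.arange(0, 20.0, 1 / 15)
        rng = np.random.default_rng(1)
        vals = 5.0 + rng.normal(0, 0.5, len(times))
        a = self._dff_of(vals, times, proto)
        b = self._dff_of(3.7 * vals, times, proto)
        for sa, sb in zip(a.segments, b.segments):
            assert np.allclose(sa.values, sb.values)

    def test_gray_last_second_worked_example(self, edge_protocol):
        times = np.arange(0, edge_protocol.total_duration_s, 0.1)
        vals = np.full_like(times, 2.0)
        onsets = edge_protocol.onsets()
        for e, on in zip(edge_protocol.epochs, onsets):
            if e.kind == "edge":
                vals[(times >= on) & (times < on + e.duration_s)] = 3.0
        dff = self._dff_of(vals, times, edge_protocol,
                           f0_mode="gray_last_second")
        s = dff.segments[0]
        assert s.kind == "edge"
        assert np.allclose(s.epoch_values, 0.5)   # (3 - 2) / 2

    def test_nonpositive_f0_excludes_roi(self):
        proto = fc.build_flash_protocol(1, 0.2)
        ts = make_trace_set([[-1.0, -1.0, 1.0, 0.0], [1.0, 1.0, 3.0, 3.0]],
                            [0.0, 0.1, 0.2, 0.3], proto)
        segs = fc.resample_and_segment(ts, proto)
        with pytest.warns(UserWarning, match="non-positive F0"):
            dff = fc.compute_dff(segs)
        assert dff.roi_ids == [2]

    def test_invalid_mode_rejected(self):
        proto = fc.build_flash_protocol(1, 0.2)
        with pytest.raises(ValueError):
            self._dff_of([1, 1, 1, 1], [0, 0.1, 0.2, 0.3], proto,
                         f0_mode="per_trial")


class TestTrialAverage:
    def test_identical_trials_average_to_one_trial(self, flash_protocol, on_cell):
        ts, _ = fc.simulate_trace_set([on_cell], flash_protocol,
                                      noise_dff_sd=0.0)
        dff = fc.compute_dff(fc.resample_and_segment(ts, flash_protocol))
        avgs = fc.trial_average(dff)
        ta = avgs[(1, "flash_on")]
        assert ta.n_trials == 7
        segs = [s for s in dff.segments if s.kind == "flash_on" and s.n_pre > 0]
        assert np.allclose(ta.epoch_values, segs[0].epoch_values, atol=1e-12)

    def test_symmetric_trials_cancel(self):
        proto = fc.build_flash_protocol(1, 1.0)
        v = np.sin(np.arange(10))
        seg = lambda vals, idx: fc.Segment(
            roi_id=1, epoch_index=idx, kind="flash_on", contrast=1.0,
            direction_deg=None, values=vals, n_pre=0, rate_hz=10.0,
            duration_s=1.0)
        dff = fc.DffTraceSet(segments=[seg(v, 0), seg(-v, 2)], rate_hz=10.0,
                             roi_ids=[1], f0_mode="whole_trace_mean")
        avg = fc.trial_average(dff)[(1, "flash_on")]
        assert np.allclose(avg.values, 0.0)

    def test_noisy_trial_mean_obeys_clt_bound(self, flash_protocol, on_cell):
        sigma = 0.1
        ts, gt = fc.simulate_trace_set([on_cell], flash_protocol,
                                       noise_dff_sd=sigma, seed=5)
        dff = fc.compute_dff(
            fc.resample_and_segment(ts, flash_protocol),
            f0_override={1: on_cell.f_baseline})
        avg = fc.trial_average(dff)[(1, "flash_on")]
        ideal_ts, _ = fc.simulate_trace_set([on_cell], flash_protocol,
                                            noise_dff_sd=0.0)
        ideal_dff = fc.compute_dff(
            fc.resample_and_segment(ideal_ts, flash_protocol),
            f0_override={1: on_cell.f_baseline})
        ideal = fc.trial_average(ideal_dff)[(1, "flash_on")]
        resid = avg.epoch_values - ideal.epoch_values
        assert np.all(np.abs(resid) < 4 * sigma / np.sqrt(7))

    def test_edge_trials_grouped_by_contrast_and_direction(self, edge_protocol, on_cell):
        ts, _ = fc.simulate_trace_set([on_cell], edge_protocol, noise_dff_sd=0.0)
        dff = fc.compute_dff(fc.resample_and_segment(ts, edge_protocol),
                             "gray_last_second")
        avgs = fc.trial_average(dff)
        edge_keys = [k for k in avgs if k[1] == "edge"]
        assert len(edge_keys) == 16           # 2 contrasts x 8 directions
        assert all(avgs[k].n_trials == 3 for k in edge_keys)
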