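"""Feature extraction: baseline/onset detection, peak logic, per-test features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imuperf as ip
from imuperf.synthetic import TraceSpec


def _flat_trace(value=9.81, seconds=20.0, fs=26.0, noise_sd=0.0, seed=0):
    n = int(seconds * fs) + 1
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    z = np.full(n, value) + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    accel = np.column_stack([np.zeros(n), np.zeros(n), z])
    return ip.ImuTrace(t=t, accel=accel, gyro=np.zeros((n, 3)), sampling_rate=fs)


class TestBaseline:
    def test_constant_lead_in(self):
        mean, sd = ip.detect_baseline(_flat_trace(), lead_s=10.0)
        assert mean == pytest.approx(9.81)
        assert sd == 0.0

    def test_noisy_lead_in_sampling_bound(self):
        trace = _flat_trace(noise_sd=0.05, seed=3)
        mean, _ = ip.detect_baseline(trace, lead_s=10.0)
        n = 10 * 26
        assert abs(mean - 9.81) < 3 * 0.05 / np.sqrt(n)

    def test_short_trace_error_names_lead_in(self):
        with pytest.raises(ValueError, match="lead-in"):
            ip.detect_baseline(_flat_trace(seconds=4.0), lead_s=10.0)


class TestOnset:
    def test_noise_free_onset_within_one_sample(self):
        # first pulse centered at 10.8 s, width 0.6 -> starts at 10.5 s
        spec = TraceSpec(protocol="STS30", event_times=(10.8,),
                         peak_amplitudes=(3.0,), snap_to_grid=False)
        trace, _ = ip.generate_trace(spec)
        onset = ip.detect_motion_onset(trace)
        assert abs(onset - 10.5) <= 1.0 / 26.0

    def test_pure_baseline_no_motion(self):
        with pytest.raises(ValueError, match="no motion detected"):
            ip.detect_motion_onset(_flat_trace(noise_sd=0.05, seed=1))

    def test_noisy_onset_within_two_samples_over_seeds(self):
        errs = []
        for seed in range(100):
            spec = TraceSpec(protocol="STS30", event_times=(10.8,),
                             peak_amplitudes=(3.0,), noise_sd=0.05, seed=seed,
                             snap_to_grid=False)
            trace, _ = ip.generate_trace(spec)
            errs.append(abs(ip.detect_motion_onset(trace) - 10.5))
        assert np.mean(errs) <= 2.0 / 26.0


class TestPeaks:
    def test_noise_free_sts_pulses(self):
        trace, truth = ip.generate_trace(ip.sts_trace_spec(11, noise_sd=0.0))
        peaks = ip.detect_vertical_peaks(trace, 1.0, 1.0)
        assert len(peaks) == 11
        assert np.allclose(peaks.times, truth.event_times, atol=1e-12)
        assert np.allclose(peaks.amplitudes, truth.peak_values, atol=1e-12)

    def test_flat_trace_empty(self):
        peaks = ip.detect_vertical_peaks(_flat_trace(), 1.0, 1.0)
        assert len(peaks) == 0

    def test_close_pulses_keep_larger(self):
        spec = TraceSpec(protocol="STS30", event_times=(11.0, 11.2),
                         peak_amplitudes=(2.0, 3.0), pulse_width_s=0.15)
        trace, _ = ip.generate_trace(spec)
        peaks = ip.detect_vertical_peaks(trace, 1.0, 1.0)
        assert len(peaks) == 1
        assert peaks.amplitudes[0] == pytest.approx(9.81 + 3.0, abs=1e-9)

    def test_offset_invariance(self):
        trace, _ = ip.generate_trace(ip.sts_trace_spec(7, noise_sd=0.05, seed=4))
        shifted = ip.ImuTrace(
            t=trace.t, accel=trace.accel + np.array([0.0, 0.0, 5.0]),
            gyro=trace.gyro, sampling_rate=trace.sampling_rate,
        )
        a = ip.detect_vertical_peaks(trace, 1.0, 1.0, cutoff_hz=5.0)
        b = ip.detect_vertical_peaks(shifted, 1.0, 1.0, cutoff_hz=5.0)
        assert np.array_equal(a.indices, b.indices)

    @settings(deadline=None, max_examples=20)
    @given(
        prominence=st.floats(0.2, 4.0),
        separation=st.floats(0.1, 3.0),
        seed=st.integers(0, 50),
    )
    def test_peak_count_monotone_in_thresholds(self, prominence, separation, seed):
        trace, _ = ip.generate_trace(ip.sts_trace_spec(9, noise_sd=0.15, seed=seed))
        base = ip.detect_vertical_peaks(trace, 1.0, 1.0)
        tighter_prom = ip.detect_vertical_peaks(trace, 1.0, 1.0 + prominence)
        assert len(tighter_prom) <= len(base)
        wider_sep = ip.detect_vertical_peaks(trace, 1.0 + separation, 1.0)
        assert len(wider_sep) <= len(base)

    def test_min_separation_floor(self):
        with pytest.raises(ValueError, match="2 samples"):
            ip.detect_vertical_peaks(_flat_trace(), 0.01, 1.0)


class TestStsFeatures:
    def test_eleven_pulses_count_and_mean(self):
        trace, truth = ip.generate_trace(
            ip.sts_trace_spec(11, mean_peak=13.0, noise_sd=0.0)
        )
        count, mean = ip.sts_features(trace)
        assert count == 11
        assert mean == pytest.approx(13.0, abs=1e-9)

    def test_no_pulses_missing_mean(self):
        count, mean = ip.sts_features(_flat_trace(seconds=46.0))
        assert count == 0 and mean is None

    def test_window_rule_excludes_late_peak(self):
        # 12 evenly spaced pulses, the last beyond onset + 30 s
        times = tuple(10.5 + 0.3 + np.arange(12) * 2.8)  # last at ~41.6 s
        spec = TraceSpec(protocol="STS30", event_times=times,
                         peak_amplitudes=(3.2,) * 12)
        trace, _ = ip.generate_trace(spec)
        count, _ = ip.sts_features(trace)
        assert count == 11


class TestGaitFeatures:
    def test_ideal_cadence_arithmetic(self):
        spec, marks, n_full, partial = ip.gait_trace_spec(
            430.0, step_duration_s=0.48, step_length_m=10.0 / 14.0
        )
        trace, _ = ip.generate_trace(spec)
        dur, length, count = ip.gait_features(trace, marks)
        assert dur == pytest.approx(0.48, abs=1.0 / 26.0)
        assert length == pytest.approx(10.0 / 14.0, abs=1e-9)
        assert count == 14 * len(marks)

    def test_single_shuttle_thirteen_steps(self):
        spec, marks, _, _ = ip.gait_trace_spec(
            10.0, step_length_m=10.0 / 13.0, step_duration_s=0.5
        )
        trace, _ = ip.generate_trace(spec)
        _, length, count = ip.gait_features(trace, marks)
        assert count == 13
        assert length == pytest.approx(10.0 / 13.0, abs=1e-9)

    def test_two_shuttle_unweighted_and_weighted_means(self):
        # hand-built trace: 12 steps then 14 steps, marks at the closing steps
        times = []
        t = 10.5
        for _ in range(12):
            times.append(t)
            t += 0.5
        for _ in range(14):
            times.append(t)
            t += 0.48
        spec = TraceSpec(protocol="SIXMWT", event_times=tuple(times),
                         peak_amplitudes=(2.5,) * 26, pulse_width_s=0.2)
        trace, truth = ip.generate_trace(spec)
        marks = [truth.event_times[11], truth.event_times[25]]
        _, unweighted, _ = ip.gait_features(trace, marks)
        assert unweighted == pytest.approx((10.0 / 12 + 10.0 / 14) / 2, abs=1e-9)
        _, weighted, _ = ip.gait_features(trace, marks, weighted=True)
        assert weighted == pytest.approx((12 * 10.0 / 12 + 14 * 10.0 / 14) / 26, abs=1e-9)

    def test_empty_shuttle_excluded_with_warning(self):
        spec, marks, _, _ = ip.gait_trace_spec(20.0, step_length_m=1.0,
                                               step_duration_s=0.5)
        trace, truth = ip.generate_trace(spec)
        # insert a bogus mark immediately after the first: contains no step
        bogus = marks[0] + 0.01
        with pytest.warns(UserWarning, match="no step peaks"):
            _, length, _ = ip.gait_features(trace, [marks[0], bogus, marks[1]])
        assert length == pytest.approx(10.0 / 10.0, abs=1e-9)


class TestSixMwtDistance:
    @pytest.mark.parametrize(
        "n_full,partial,expected",
        [(43, 5.0, 435.0), (0, 0.0, 0.0), (44, 1.35, 441.35)],
    )
    def test_arithmetic(self, n_full, partial, expected):
        assert ip.six_mwt_distance(n_full, partial) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ip.six_mwt_distance(-1, 0.0)
        with pytest.raises(ValueError):
            ip.six_mwt_distance(3, 10.0)


class TestTugDuration:
    def test_noise_free_duration_within_two_samples(self):
        trace, truth = ip.generate_trace(ip.tug_trace_spec(8.9))
        dur = ip.tug_duration(trace)
        assert abs(dur - 8.9) <= 2.0 / 26.0

    def test_all_static_trace_error(self):
        with pytest.raises(ValueError, match="no motion detected"):
            ip.tug_duration(_flat_trace(seconds=20.0))

    def test_noisy_mae_below_three_samples(self):
        errs = []
        for seed in range(100):
            trace, truth = ip.generate_trace(
                ip.tug_trace_spec(8.9, noise_sd=0.05, seed=seed)
            )
            truth_dur = truth.termination_time - truth.onset_time
            errs.append(abs(ip.tug_duration(trace) - truth_dur))
        assert np.mean(errs) < 3.0 / 26.0


class TestExtractFeatures:
    @staticmethod
    def _recordings(noise_sd=0.0, seed=0):
        sts_trace, sts_truth = ip.generate_trace(
            ip.sts_trace_spec(11, mean_peak=13.0, noise_sd=noise_sd, seed=seed)
        )
        walk_spec, marks, n_full, partial = ip.gait_trace_spec(
            430.0, noise_sd=noise_sd, seed=seed + 1
        )
        walk_trace, _ = ip.generate_trace(walk_spec)
        tugc, _ = ip.generate_trace(ip.tug_trace_spec(8.9, noise_sd=noise_sd, seed=seed + 2))
        tugf, _ = ip.generate_trace(
            ip.tug_trace_spec(7.1, step_duration_s=0.4, noise_sd=noise_sd, seed=seed + 3)
        )
        return {
            "STS30": ip.TestRecording(protocol="STS30", trace=sts_trace),
            "6MWT": ip.TestRecording(
                protocol="6MWT", trace=walk_trace, shuttle_marks=tuple(marks),
                n_full_shuttles=n_full, partial_m=partial,
            ),
            "TUG_COMFORT": ip.TestRecording(protocol="TUG_COMFORT", trace=tugc),
            "TUG_FAST": ip.TestRecording(protocol="TUG_FAST", trace=tugf),
        }

    def test_noise_free_set_matches_truth(self):
        fv = ip.extract_features(self._recordings())
        assert fv.sts_count == 11
        assert fv.sts_peak_accel_mean == pytest.approx(13.0, abs=1e-9)
        assert fv.six_mwt_distance == pytest.approx(420 + 9.76, abs=0.01)
        assert fv.step_duration_mean == pytest.approx(0.48, abs=1.0 / 26.0)
        assert fv.step_length_mean == pytest.approx(0.68, abs=0.02)
        assert fv.tug_comfort_s == pytest.approx(8.9, abs=2.0 / 26.0)
        assert fv.tug_fast_s == pytest.approx(7.1, abs=2.0 / 26.0)

    def test_missing_protocol_error_names_it(self):
        recs = self._recordings()
        del recs["TUG_FAST"]
        with pytest.raises(ValueError, match="TUG_FAST"):
            ip.extract_features(recs)

    def test_feature_frame_layout(self):
        fv = ip.extract_features(self._recordings())
        df = ip.features_to_frame([fv], ids=["P000"])
        assert list(df.columns) == ["participant_id", *ip.FEATURE_COLUMNS]
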