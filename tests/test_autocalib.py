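import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eogkit import autocalib, preprocess, synthetic
from eogkit.autocalib import (PeakCurve, ThresholdSet, build_peak_curve,
                              collect_peak_amplitudes, estimate_thresholds,
                              find_pivot, trim_artifacts)
from eogkit.exceptions import CalibrationError, InputError


def brute_force_pivot(values, n_min=10):
    """Independent oracle: per-split line fits via np.polyfit."""
    N = len(values)
    x = np.arange(1, N + 1, dtype=float)
    best_k, best_sse = None, np.inf
    for k in range(n_min, N - n_min + 1):
        sse = 0.0
        for xs, ys in ((x[:k], values[:k]), (x[k:], values[k:])):
            if len(ys) >= 2:
                c = np.polyfit(xs, ys, 1)
                r = ys - np.polyval(c, xs)
                sse += float(r @ r)
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k


class TestCollectPeaks:
    def test_monotone_sequence_has_no_maxima(self):
        assert len(collect_peak_amplitudes(np.arange(20.0))) == 0

    def test_signed_peaks_of_absolute_signal(self):
        out = collect_peak_amplitudes([0, 2, 0, -3, 0])
        assert out.tolist() == [2, 3]

    def test_plateau_counts_once(self):
        out = collect_peak_amplitudes([0, 1, 2, 2, 2, 1, 0])
        assert out.tolist() == [2]

    def test_abs_sine_maxima_against_neighbor_oracle(self):
        t = np.linspace(0, 3, 3000, endpoint=False)
        x = np.sin(2 * np.pi * t)
        out = collect_peak_amplitudes(x)
        # brute-force neighbor comparison on |x|
        a = np.abs(x)
        brute = [a[i] for i in range(1, len(a) - 1)
                 if a[i] > a[i - 1] and a[i] > a[i + 1]]
        assert len(out) == len(brute) == 6
        np.testing.assert_allclose(out, brute)
        np.testing.assert_allclose(out, 1.0, atol=1e-4)

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            collect_peak_amplitudes([1.0, 2.0])


class TestBuildCurve:
    def test_sorting_and_scaling(self):
        c = build_peak_curve([10, 5, 20], min_peaks=1)
        assert c.values.tolist() == [0.25, 0.5, 1.0]
        assert c.scale_max == 20
        assert c.n_raw == 3

    def test_all_equal_maps_to_one(self):
        c = build_peak_curve([7.0] * 40)
        assert np.all(c.values == 1.0)

    def test_random_input_sorted_property(self, rng):
        amps = rng.exponential(size=500)
        c = build_peak_curve(amps)
        assert np.all(np.diff(c.values) >= 0)
        np.testing.assert_allclose(np.sort(amps) / amps.max(), c.values)

    def test_too_few_peaks_raises(self):
        with pytest.raises(CalibrationError, match="longer recording"):
            build_peak_curve([1.0] * 10, min_peaks=30)


class TestTrimArtifacts:
    def test_spec_forced_example(self):
        c = PeakCurve(values=np.array([0.10, 0.60, 0.62, 0.80, 1.00]),
                      scale_max=100.0, n_raw=5)
        out = trim_artifacts(c, delta=0.03)
        np.testing.assert_allclose(out.values,
                                   np.array([0.10, 0.60, 0.62]) / 0.62)
        assert out.scale_max == pytest.approx(62.0)
        assert out.n == 3 and out.n_raw == 5

    def test_dense_curve_unchanged(self):
        vals = np.linspace(0, 1, 200)
        c = PeakCurve(values=vals, scale_max=50.0, n_raw=200)
        out = trim_artifacts(c, delta=0.03)
        assert np.array_equal(out.values, vals)
        assert out.scale_max == 50.0

    def test_isolated_artifacts_removed_exactly(self):
        # dense noise floor + 3 isolated huge artifacts
        floor = np.linspace(0.0, 0.1, 300)
        vals = np.concatenate([floor, [0.5, 0.7, 1.0]])
        c = PeakCurve(values=vals, scale_max=1000.0, n_raw=303)
        out = trim_artifacts(c, delta=0.03)
        assert out.n == 300
        assert out.scale_max == pytest.approx(100.0)

    def test_no_rescale_option(self):
        vals = np.concatenate([np.linspace(0, 0.1, 100), [1.0]])
        c = PeakCurve(values=vals, scale_max=200.0, n_raw=101)
        out = trim_artifacts(c, delta=0.03, rescale=False)
        assert out.scale_max == 200.0
        assert out.values.max() == pytest.approx(0.1)


class TestFindPivot:
    def test_two_segment_knee_recovered(self):
        y = np.concatenate([0.001 * np.arange(1, 71),
                            0.001 * 70 + 0.05 * np.arange(1, 31)])
        y = y / y[-1]
        p = find_pivot(PeakCurve(values=y, scale_max=1.0, n_raw=100))
        assert abs(p.n_star - 70) <= 3

    def test_collinear_curve_tie_breaks_to_n_min(self):
        y = np.linspace(0.0, 1.0, 80)
        p = find_pivot(PeakCurve(values=y, scale_max=1.0, n_raw=80), n_min=10)
        assert p.n_star == 10

    def test_two_percent_margin_arithmetic(self):
        # a curve engineered so the knee value is exactly 0.50
        y = np.concatenate([np.linspace(0.0, 0.5, 60),
                            np.linspace(0.9, 1.0, 15)])
        p = find_pivot(PeakCurve(values=y, scale_max=200.0, n_raw=75))
        assert p.d_n_amplitude == pytest.approx(0.5, abs=0.02)
        assert p.d_p_amplitude == pytest.approx(1.02 * p.d_n_amplitude)
        assert p.threshold == pytest.approx(p.d_p_amplitude * 200.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            N = int(rng.integers(25, 160))
            vals = np.sort(rng.random(N))
            c = PeakCurve(values=vals / vals[-1], scale_max=1.0, n_raw=N)
            assert find_pivot(c).n_star == brute_force_pivot(c.values)

    def test_too_few_points_rejected(self):
        c = PeakCurve(values=np.linspace(0, 1, 15), scale_max=1.0, n_raw=15)
        with pytest.raises(CalibrationError):
            find_pivot(c, n_min=10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_pivot_matches_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(24, 120))
        vals = np.sort(rng.random(N))
        c = PeakCurve(values=vals / vals[-1], scale_max=1.0, n_raw=N)
        assert find_pivot(c).n_star == brute_force_pivot(c.values)


class TestEstimateThresholds:
    def test_thresholds_separate_noise_from_events(self):
        from conftest import separation_config
        rec, truth = synthetic.generate(separation_config(0))
        pre = preprocess.preprocess_recording(rec)
        thr = estimate_thresholds(pre.clean, pre.vel_h, pre.vel_v)
        noise_vel = 4.5 * 0.3 * 500  # generous bound on white-noise velocity
        assert noise_vel < thr.h_saccade < 3000
        assert isinstance(thr, ThresholdSet)

    def test_scale_equivariance(self):
        from conftest import separation_config
        rec, _ = synthetic.generate(separation_config(1))
        pre1 = preprocess.preprocess_recording(rec)
        pre2 = preprocess.preprocess_recording(rec.scaled(2.0))
        t1 = estimate_thresholds(pre1.clean, pre1.vel_h, pre1.vel_v)
        t2 = estimate_thresholds(pre2.clean, pre2.vel_h, pre2.vel_v)
        assert t2.h_saccade == 2.0 * t1.h_saccade
        assert t2.v_saccade == 2.0 * t1.v_saccade
        assert t2.blink == 2.0 * t1.blink

    def test_channel_named_in_error(self):
        from eogkit.io import Recording
        from eogkit.preprocess import VelocitySignal
        flat = Recording(fs=500, eog_h=np.zeros(100), eog_v=np.zeros(100))
        vel = VelocitySignal(np.zeros(100), 500, "h")
        with pytest.raises(CalibrationError, match="h_vel"):
            estimate_thresholds(flat, vel,
                                VelocitySignal(np.zeros(100), 500, "v"))

    def test_details_filled(self):
        from conftest import separation_config
        rec, _ = synthetic.generate(separation_config(2))
        pre = preprocess.preprocess_recording(rec)
        det = {}
        estimate_thresholds(pre.clean, pre.vel_h, pre.vel_v, details=det)
        assert set(det) == {"h_vel", "v_vel", "v_pos"}
        pivot, curve = det["h_vel"]
        assert pivot.threshold == pytest.approx(
            pivot.d_p_amplitude * curve.scale_max)
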