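import numpy as np
import pytest

from eogkit import preprocess, synthetic
from eogkit.exceptions import InputError
from eogkit.io import Recording
from eogkit.preprocess import (differentiate, preprocess_recording,
                               remove_baseline, wavelet_denoise)


class TestRemoveBaseline:
    def test_polynomial_in_model_space_removed_exactly(self):
        t = np.linspace(-1, 1, 400)
        y = 5 - 3 * t + 0.5 * t ** 3
        fit = remove_baseline(y, degree=20)
        assert np.max(np.abs(fit.residual)) < 1e-9 * np.max(np.abs(y))
        assert fit.r_squared > 0.999999

    def test_constant_input_r_squared_zero_by_convention(self):
        fit = remove_baseline(np.full(100, 7.0), degree=5)
        np.testing.assert_allclose(fit.residual, 0, atol=1e-9)
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        # slow sinusoidal drift plus step events; oracle = explicit normal
        # equations (solved at a degree where V'V is well-conditioned)
        n, deg = 1500, 8
        t = np.linspace(-1, 1, n)
        y = 200 * np.sin(2 * np.pi * 0.05 * np.arange(n) / 500 + 1.0)
        y[700:] += 130.0
        y += rng.normal(0, 1, n)
        fit = remove_baseline(y, degree=deg)
        V = np.vander(t, deg + 1, increasing=True)
        coef = np.linalg.solve(V.T @ V, V.T @ y)
        np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-8,
                                   atol=1e-8 * np.abs(coef).max())

    def test_degree_20_fitted_values_match_lstsq_oracle(self, rng):
        # at degree 20 individual coefficients are ill-determined but the
        # fitted baseline itself is well-determined
        n = 1500
        y = 200 * np.sin(np.linspace(0, 2.5, n)) + rng.normal(0, 1, n)
        fit = remove_baseline(y, degree=20)
        t = np.linspace(-1, 1, n)
        V = np.polynomial.polynomial.polyvander(t, 20)
        ref = V @ np.linalg.lstsq(V, y, rcond=None)[0]
        np.testing.assert_allclose(y - fit.residual, ref, atol=1e-6)

    def test_residual_plus_fit_reconstructs_input(self, rng):
        y = rng.normal(size=300)
        fit = remove_baseline(y, degree=10)
        np.testing.assert_allclose(fit.residual + fit.fitted, y, atol=1e-9)

    def test_step_amplitude_preserved_under_drift(self):
        # a saccade-scale transient step (out-and-return, ~1.4 s) riding on
        # degree<=20 drift keeps its amplitude: the polynomial is far too
        # smooth to follow second-scale gaze structure
        n = 30000
        tt = np.arange(n) / 500.0
        drift = 150 * np.sin(2 * np.pi * 0.03 * tt + 0.3)
        step = np.zeros(n)
        step[15000:15700] = 130.0
        fit = remove_baseline(drift + step, degree=20)
        # compare levels immediately around the step edge: the polynomial
        # varies over seconds, so the local jump is what detection sees
        est = (np.median(fit.residual[15050:15250])
               - np.median(fit.residual[14750:14950]))
        assert abs(est - 130.0) / 130.0 < 0.05

    def test_too_short_input_rejected(self):
        with pytest.raises(InputError):
            remove_baseline(np.arange(10.0), degree=20)


class TestWaveletDenoise:
    def test_zero_input_stays_zero(self):
        out = wavelet_denoise(np.zeros(100), fs=500)
        assert np.array_equal(out, np.zeros(100))

    def test_150hz_band_energy_strongly_attenuated(self):
        # level-1 Haar truncation attenuates the 125-250 Hz band by ~88%
        fs, n = 500.0, 5000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 150 * t)
        y = wavelet_denoise(x, fs, cutoff_hz=100)
        f = np.fft.rfftfreq(n, 1 / fs)
        band = (f >= 125) & (f <= 250)
        ein = np.sum(np.abs(np.fft.rfft(x)[band]) ** 2)
        eout = np.sum(np.abs(np.fft.rfft(y)[band]) ** 2)
        assert 1 - eout / ein > 0.85

    def test_matches_pywavelets_oracle(self, rng):
        pywt = pytest.importorskip("pywt")
        x = rng.normal(size=1024)
        mine = wavelet_denoise(x, fs=500, cutoff_hz=100)
        cA, cD = pywt.dwt(x, "haar", mode="periodization")
        ref = pywt.idwt(cA, np.zeros_like(cD), "haar", mode="periodization")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @pytest.mark.parametrize("n", [64, 100, 1037])
    def test_idempotent_exactly(self, rng, n):
        x = rng.normal(size=n)
        once = wavelet_denoise(x, fs=500, cutoff_hz=100)
        twice = wavelet_denoise(once, fs=500, cutoff_hz=100)
        assert np.array_equal(once, twice)

    def test_identity_when_fs_too_low(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(wavelet_denoise(x, fs=300, cutoff_hz=100), x)

    def test_deeper_truncation_at_higher_fs(self, rng):
        # fs=1000: levels 1 (250-500) and 2 (125-250) are both zeroed
        x = rng.normal(size=256)
        out = wavelet_denoise(x, fs=1000, cutoff_hz=100)
        blocks = out.reshape(-1, 4)
        assert np.allclose(blocks, blocks[:, :1])  # constant on 4-blocks

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            wavelet_denoise(np.empty(0), fs=500)


class TestDifferentiate:
    def test_constant_gives_zero(self):
        assert np.all(differentiate(np.full(50, 3.0), fs=500) == 0)

    def test_ramp_gives_fs(self):
        v = differentiate(np.arange(100, dtype=float), fs=500)
        np.testing.assert_allclose(v, 500.0)

    def test_sampled_sinusoid_matches_analytic_derivative(self):
        fs, f = 500.0, 10.0
        t = np.arange(2000) / fs
        v = differentiate(np.sin(2 * np.pi * f * t), fs)
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        err = np.max(np.abs(v[1:-1] - expected[1:-1])) / (2 * np.pi * f)
        assert err <= np.pi * f / fs

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            differentiate(np.array([1.0]), fs=500)


class TestPreprocessRecording:
    def test_zeros_stay_zeros(self):
        rec = Recording(fs=500, eog_h=np.zeros(300), eog_v=np.zeros(300))
        pre = preprocess_recording(rec)
        assert np.allclose(pre.clean.eog_h, 0, atol=1e-12)
        assert np.allclose(pre.vel_v.samples, 0, atol=1e-9)

    def test_drift_only_recording_has_negligible_velocity(self):
        cfg = synthetic.SimConfig(seed=3, duration_s=30, n_saccades=0,
                                  n_blinks=0, n_artifacts=0,
                                  noise_white_sd_uV=0.0, powerline_amp_uV=0.0)
        rec, _ = synthetic.generate(cfg)
        pre = preprocess_recording(rec)
        blink_scale_vel = 4500.0  # ~300 uV blink over ~100 ms closing
        interior = slice(400, -400)
        assert np.max(np.abs(pre.vel_h.samples[interior])) < 0.05 * blink_scale_vel
        assert np.max(np.abs(pre.vel_v.samples[interior])) < 0.05 * blink_scale_vel

    def test_baseline_and_denoise_nearly_commute_without_drift(self, rng):
        # the polynomial projector and the block-average projector do not
        # commute exactly, but on drift-free input their order changes the
        # result by well under a tenth of the noise scale
        x = rng.normal(0, 1, 2000)
        a = wavelet_denoise(remove_baseline(x, 20).residual, 500)
        b = remove_baseline(wavelet_denoise(x, 500), 20).residual
        assert np.max(np.abs(a - b)) < 0.1 * x.std()

    def test_scale_equivariance_exact(self, rng):
        h, v = rng.normal(size=(2, 1024)) * 100
        rec = Recording(fs=500, eog_h=h, eog_v=v)
        p1 = preprocess_recording(rec)
        p2 = preprocess_recording(rec.scaled(2.0))
        assert np.array_equal(p2.clean.eog_h, 2.0 * p1.clean.eog_h)
        assert np.array_equal(p2.vel_h.samples, 2.0 * p1.vel_h.samples)
        assert np.array_equal(p2.vel_v.samples, 2.0 * p1.vel_v.samples)

    def test_denoising_preserves_saccade_peak_timing(self):
        # peak index of a saccade velocity pulse moves <= 2 samples
        h, v, _ = synthetic.saccade_waveform(10.0, 0.0, fs=500)
        pos = np.concatenate([np.zeros(300), h, np.full(300, h[-1])])
        raw_peak = np.argmax(differentiate(pos, 500))
        den_peak = np.argmax(differentiate(wavelet_denoise(pos, 500), 500))
        assert abs(int(raw_peak) - int(den_peak)) <= 2
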