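import numpy as np
import pytest
from scipy import linalg

from chunktrack.preprocess import (
    DSSResult,
    FIRFilterSpec,
    bandpass_fir,
    compensate_filter_response,
    dss_denoise,
    dss_transform,
    epoch_and_downsample,
    narrowband_filter,
    pca_waveform,
)

FS = 20.0


def sinusoid(freq, fs, duration, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.cos(2 * np.pi * freq * t + phase)


class TestFIRFilter:
    def test_minus_6db_at_cutoffs(self):
        spec = FIRFilterSpec()
        mag = spec.magnitude_response(np.array([0.3, 2.7]), FS)
        db = 20 * np.log10(mag)
        assert np.allclose(db, -6.0, atol=0.1)

    def test_passband_sinusoid_preserved(self):
        x = sinusoid(1.0, FS, 60.0)
        y = bandpass_fir(x, FS)
        mid = slice(300, 900)  # interior, away from edge effects
        assert np.max(np.abs(y[mid] - x[mid])) < 0.05

    def test_stopband_sinusoid_attenuated(self):
        x = sinusoid(0.05, FS, 120.0)
        y = bandpass_fir(x, FS)
        mid = slice(400, 2000)
        assert np.max(np.abs(y[mid])) < 0.1

    def test_zero_phase_in_band(self):
        # group-delay compensation leaves no net phase shift
        x = sinusoid(1.0, FS, 60.0, phase=0.7)
        y = bandpass_fir(x, FS)
        seg = slice(400, 800)
        xc = np.vdot(np.fft.rfft(x[seg]), np.fft.rfft(y[seg]))
        assert abs(np.angle(xc)) < 0.01

    def test_linearity(self, rng):
        a = rng.standard_normal((3, 600))
        b = rng.standard_normal((3, 600))
        lhs = bandpass_fir(a + b, FS)
        rhs = bandpass_fir(a, FS) + bandpass_fir(b, FS)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_too_short_data(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(100), FS)

    def test_rate_below_nyquist(self):
        with pytest.raises(ValueError):
            FIRFilterSpec().taps(4.0)

    def test_symmetric_impulse_response(self):
        taps = FIRFilterSpec().taps(FS)
        assert np.allclose(taps, taps[::-1])


class TestCompensation:
    def test_round_trip_recovers_amplitude(self):
        # filtered 0.5 Hz sinusoid, compensated -> original amplitude within 1%
        spec = FIRFilterSpec()
        x = sinusoid(0.5, FS, 40.0)
        y = bandpass_fir(x, FS)
        seg = y[200:400]  # 10 s interior window, integer cycles of 0.5 Hz
        coeffs = np.fft.rfft(seg)
        freqs = np.fft.rfftfreq(len(seg), 1 / FS)
        i = np.argmin(np.abs(freqs - 0.5))
        comp = compensate_filter_response(coeffs[i], freqs[i : i + 1], spec, FS)
        amp = 2 * np.abs(comp) / len(seg)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_unity_region_identity(self):
        spec = FIRFilterSpec()
        freqs = np.array([1.2, 1.5, 1.8])
        coeffs = np.array([1 + 1j, 2.0, -3j])
        comp = compensate_filter_response(coeffs, freqs, spec, FS)
        assert np.allclose(comp, coeffs, rtol=5e-3)  # within passband ripple

    def test_power_scales_with_inverse_square_magnitude(self):
        spec = FIRFilterSpec()
        freqs = np.array([0.3])
        mag = spec.magnitude_response(freqs, FS)
        comp = compensate_filter_response(np.array([1.0 + 0j]), freqs, spec, FS)
        assert np.abs(comp[0]) ** 2 == pytest.approx(1.0 / mag[0] ** 2, rel=1e-9)

    def test_floor_error(self):
        spec = FIRFilterSpec()
        with pytest.raises(ValueError):
            compensate_filter_response(np.array([1.0 + 0j]), np.array([0.01]), spec, FS)


class TestEpochDownsample:
    def test_shape(self):
        fs = 1000.0
        x = np.zeros((2, int(30 * fs)))
        out = epoch_and_downsample(x, fs, [0.0, 13.0], duration_s=12.0, target_rate=20.0)
        assert out.shape == (2, 2, 240)

    def test_phase_preserved(self):
        fs = 1000.0
        phase = 0.9
        x = sinusoid(1.0, fs, 30.0, phase=phase)
        out = epoch_and_downsample(x, fs, [2.0], duration_s=12.0, target_rate=20.0)[0]
        coeffs = np.fft.rfft(out[40:])  # drop 2 s, 10 s remain
        measured = np.angle(coeffs[10])
        expected = phase + 2 * np.pi * 1.0 * 4.0  # onset at 2 s + 2 s discard
        err = np.angle(np.exp(1j * (measured - expected)))
        assert abs(err) < 0.02

    def test_empty_events(self):
        out = epoch_and_downsample(np.zeros(1000), 20.0, [], duration_s=12.0)
        assert out.shape == (0, 240)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            epoch_and_downsample(np.zeros(100), 20.0, [2.0], duration_s=12.0)


def _dss_toy(rng, n_sensors=6, n_trials=20, n_time=200, noise=1.0):
    t = np.arange(n_time) / 20.0
    waveform = np.sin(2 * np.pi * 1.0 * t)
    pattern = rng.standard_normal(n_sensors)
    trials = (
        pattern[None, :, None] * waveform[None, None, :]
        + noise * rng.standard_normal((n_trials, n_sensors, n_time))
    )
    return trials, waveform


class TestDSS:
    def test_recovers_repeatable_component(self, rng):
        trials, waveform = _dss_toy(rng)
        result = dss_transform({"a": trials}, n_retained=1)
        comp = result.components(trials.mean(axis=0))[0]
        r = np.corrcoef(comp, waveform)[0, 1]
        assert abs(r) > 0.95

    def test_pure_noise_ratios_near_chance(self, rng):
        n_trials = 25
        trials = rng.standard_normal((n_trials, 5, 400))
        result = dss_transform({"a": trials}, n_retained=2)
        # trial averaging shrinks unrepeatable variance by ~1/n_trials
        assert np.all(result.ratios > 0.2 / n_trials)
        assert np.all(result.ratios < 5.0 / n_trials)

    def test_full_rank_round_trip(self, rng):
        trials, _ = _dss_toy(rng, n_sensors=4)
        denoised, _ = dss_denoise({"a": trials}, n_retained=4)
        assert np.allclose(denoised["a"], trials, atol=1e-8)

    def test_matches_generalized_eigendecomposition(self, rng):
        # brute-force oracle: eig(bias, total) up to sign/scale
        trials = {
            "a": rng.standard_normal((10, 5, 300)),
            "b": rng.standard_normal((10, 5, 300)),
        }
        result = dss_transform(trials, n_retained=5, shrinkage=0.0)
        bias, total = result.bias_cov, result.total_cov
        evals, evecs = linalg.eigh(bias, total)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(result.ratios, evals, atol=1e-8)
        for k in range(5):
            a = result.unmixing[k]
            b = evecs[:, k]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_common_transform_across_conditions(self, rng):
        trials, _ = _dss_toy(rng)
        denoised, result = dss_denoise({"a": trials, "b": trials + 0.0}, n_retained=2)
        assert set(denoised) == {"a", "b"}
        assert np.allclose(denoised["a"], denoised["b"])
        assert result.unmixing.shape[1] == 6

    def test_too_few_trials(self, rng):
        with pytest.raises(ValueError):
            dss_transform({"a": rng.standard_normal((1, 4, 100))})

    def test_retain_more_than_sensors(self, rng):
        trials, _ = _dss_toy(rng, n_sensors=3)
        with pytest.raises(ValueError):
            dss_transform({"a": trials}, n_retained=4)

    def test_linearity_of_denoising(self, rng):
        trials, _ = _dss_toy(rng)
        _, result = dss_denoise({"a": trials}, n_retained=3)
        x = rng.standard_normal((6, 50))
        y = rng.standard_normal((6, 50))
        assert np.allclose(
            result.denoise(x + y), result.denoise(x) + result.denoise(y), atol=1e-10
        )


class TestPCA:
    def test_rank_one(self, rng):
        pattern = rng.standard_normal(5)
        wave = np.sin(np.linspace(0, 10, 200))
        data = np.outer(pattern, wave)
        res = pca_waveform(data, n_components=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_onset_plus_oscillation_separated(self, rng):
        t = np.arange(240) / 20.0
        onset = np.exp(-((t - 0.5) ** 2) / 0.1)
        osc = np.sin(2 * np.pi * 1.0 * t) * (t > 2)
        p1, p2 = rng.standard_normal(8), rng.standard_normal(8)
        p2 -= p1 * (p1 @ p2) / (p1 @ p1)  # orthogonal patterns
        data = np.outer(p1, onset) + np.outer(p2, osc)
        res = pca_waveform(data, n_components=2)
        # one PC dominated by the onset, the other by the oscillation
        corr = np.abs(np.corrcoef(np.vstack([res.components, onset, osc]))[:2, 2:])
        assert corr.max(axis=1).min() > 0.95
        assert {corr[0].argmax(), corr[1].argmax()} == {0, 1}

    def test_sign_convention(self, rng):
        data = rng.standard_normal((4, 100))
        res = pca_waveform(data)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_narrowband_filter_passes_1hz(self):
        x = sinusoid(1.0, FS, 30.0)
        y = narrowband_filter(x, FS)
        mid = slice(100, 500)
        assert np.max(np.abs(y[mid] - x[mid])) < 0.1
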