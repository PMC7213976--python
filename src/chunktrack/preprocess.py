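"""Sensor-space preprocessing.

Linear-phase FIR bandpass (0.3–2.7 Hz, 10 s Hamming window, −6 dB at the
cutoffs) with exact group-delay compensation, magnitude-response
compensation of spectra, epoching/downsampling to the 20 Hz analysis grid,
DSS denoising (components ranked by trial-averaged/total variance ratio,
first six retained and back-projected), and PCA waveform extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import linalg, signal


@dataclass(frozen=True)
class FIRFilterSpec:
    """Linear-phase windowed-sinc bandpass specification.

    The Hamming windowed-sinc design puts the −6 dB points at the band
    edges. ``duration_s`` is the impulse-response length.
    """

    band: tuple[float, float] = (0.3, 2.7)
    duration_s: float = 10.0
    window: str = "hamming"

    def taps(self, sampling_rate: float) -> np.ndarray:
        if sampling_rate < 2.0 * self.band[1]:
            raise ValueError("sampling rate below twice the upper cutoff")
        n = int(round(self.duration_s * sampling_rate))
        if n % 2 == 0:
            n += 1  # odd length -> integer group delay, exactly linear phase
        return signal.firwin(
            n, self.band, pass_zero=False, window=self.window, fs=sampling_rate
        )

    def frequency_response(
        self, frequencies: np.ndarray, sampling_rate: float
    ) -> np.ndarray:
        """Complex response at the given frequencies (Hz)."""
        taps = self.taps(sampling_rate)
        w = 2.0 * np.pi * np.asarray(frequencies, dtype=float) / sampling_rate
        _, h = signal.freqz(taps, worN=w)
        return h

    def magnitude_response(
        self, frequencies: np.ndarray, sampling_rate: float
    ) -> np.ndarray:
        return np.abs(self.frequency_response(frequencies, sampling_rate))


def bandpass_fir(
    data: np.ndarray, sampling_rate: float, spec: FIRFilterSpec | None = None
) -> np.ndarray:
    """Forward FIR filtering with exact group-delay compensation.

    Zero-phase-equivalent: the symmetric (linear-phase) kernel is applied by
    full convolution and the constant delay removed, so in-band components
    keep their phase. Edges are zero-padded; callers should keep enough
    padding around the segment of interest (half the filter length).
    """
    spec = spec or FIRFilterSpec()
    taps = spec.taps(sampling_rate)
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if n < len(taps):
        raise ValueError(
            f"data length {n} shorter than the {len(taps)}-tap filter"
        )
    delay = (len(taps) - 1) // 2
    full = signal.fftconvolve(data, taps.reshape((1,) * (data.ndim - 1) + (-1,)), axes=-1)
    return full[..., delay : delay + n]


def compensate_filter_response(
    coefficients: np.ndarray,
    frequencies: np.ndarray,
    spec: FIRFilterSpec,
    sampling_rate: float,
    floor: float = 1e-2,
) -> np.ndarray:
    """Divide spectrum coefficients by the filter's magnitude response.

    Phase is already compensated by the delay correction, so only the
    magnitude is divided out. Raises if any requested bin's response falls
    below ``floor``.
    """
    mag = spec.magnitude_response(np.asarray(frequencies), sampling_rate)
    if np.any(mag < floor):
        bad = np.asarray(frequencies)[mag < floor]
        raise ValueError(
            f"filter response below floor {floor} at {bad} Hz; cannot compensate"
        )
    return np.asarray(coefficients) / mag


def epoch_and_downsample(
    data: np.ndarray,
    sampling_rate: float,
    onsets_s: np.ndarray,
    duration_s: float = 12.0,
    target_rate: float = 20.0,
) -> np.ndarray:
    """Cut epochs from continuous data and resample to the analysis rate.

    Returns (..., n_events, duration*target_rate). Resampling uses a
    polyphase anti-aliasing filter (zero phase).
    """
    data = np.asarray(data, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    n_out = int(round(duration_s * target_rate))
    n_in = int(round(duration_s * sampling_rate))
    frac = Fraction(target_rate / sampling_rate).limit_denominator(10**6)
    epochs = np.empty(data.shape[:-1] + (len(onsets), n_out))
    for k, onset in enumerate(onsets):
        start = int(round(onset * sampling_rate))
        if start < 0 or start + n_in > data.shape[-1]:
            raise ValueError(f"epoch at {onset} s exceeds the data span")
        seg = data[..., start : start + n_in]
        if frac == 1:
            epochs[..., k, :] = seg
        else:
            epochs[..., k, :] = signal.resample_poly(
                seg, frac.numerator, frac.denominator, axis=-1
            )[..., :n_out]
    return epochs


@dataclass(frozen=True)
class DSSResult:
    """Denoising-source-separation transforms and diagnostics.

    ``unmixing`` (components x sensors) extracts component time courses;
    ``mixing`` (sensors x components) back-projects. ``ratios`` are the
    biased/total variance ratios per component, descending.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    ratios: np.ndarray
    n_retained: int
    bias_cov: np.ndarray
    total_cov: np.ndarray

    def components(self, data: np.ndarray) -> np.ndarray:
        """Component time courses for (…, sensor, time) data."""
        return np.einsum("cs,...st->...ct", self.unmixing, data)

    def denoise(self, data: np.ndarray) -> np.ndarray:
        """Back-projection of the retained components."""
        k = self.n_retained
        proj = self.mixing[:, :k] @ self.unmixing[:k]
        return np.einsum("rs,...st->...rt", proj, data)


def _sensor_cov(x: np.ndarray) -> np.ndarray:
    """(sensor, time) -> sensor covariance (uncentered, per-sample)."""
    return x @ x.T / x.shape[-1]


def dss_transform(
    trials_by_condition: Mapping[object, np.ndarray],
    n_retained: int = 6,
    shrinkage: float = 1e-9,
    rank_tol: float = 1e-10,
) -> DSSResult:
    """Derive a common DSS from per-condition trial sets.

    For each condition (trials, sensors, time): the *bias* covariance is
    that of the trial-averaged response, the *total* covariance the mean of
    single-trial covariances; both are averaged over conditions. Components
    maximize the biased/total variance ratio (generalized eigenvectors of
    the pair).
    """
    bias_sum = None
    total_sum = None
    n_cond = 0
    for trials in trials_by_condition.values():
        trials = np.asarray(trials, dtype=float)
        if trials.ndim != 3:
            raise ValueError("each condition needs (trials, sensors, time) data")
        if trials.shape[0] < 2:
            raise ValueError("need at least two trials per condition")
        avg = trials.mean(axis=0)
        bias = _sensor_cov(avg)
        total = np.mean([_sensor_cov(t) for t in trials], axis=0)
        bias_sum = bias if bias_sum is None else bias_sum + bias
        total_sum = total if total_sum is None else total_sum + total
        n_cond += 1
    if n_cond == 0:
        raise ValueError("no conditions given")
    bias_cov = bias_sum / n_cond
    total_cov = total_sum / n_cond

    n_sensors = total_cov.shape[0]
    if n_retained > n_sensors:
        raise ValueError("cannot retain more components than sensors")
    # diagonal loading, then whitening with rank truncation
    load = shrinkage * np.trace(total_cov) / n_sensors
    total_reg = total_cov + load * np.eye(n_sensors)
    evals, evecs = linalg.eigh(total_reg)
    keep = evals > rank_tol * evals.max()
    if keep.sum() < n_retained:
        raise ValueError("total covariance too rank-deficient for n_retained")
    evals, evecs = evals[keep], evecs[:, keep]
    whiten = (evecs / np.sqrt(evals)).T  # (rank, sensors)
    biased_w = whiten @ bias_cov @ whiten.T
    ratios, rot = linalg.eigh(biased_w)
    order = np.argsort(ratios)[::-1]
    ratios, rot = ratios[order], rot[:, order]
    unmixing = rot.T @ whiten
    mixing = linalg.pinv(unmixing)
    return DSSResult(
        unmixing=unmixing,
        mixing=mixing,
        ratios=ratios,
        n_retained=n_retained,
        bias_cov=bias_cov,
        total_cov=total_cov,
    )


def dss_denoise(
    trials_by_condition: Mapping[object, np.ndarray],
    n_retained: int = 6,
) -> tuple[dict, DSSResult]:
    """Common DSS across conditions; retained components back-projected."""
    result = dss_transform(trials_by_condition, n_retained=n_retained)
    denoised = {
        key: result.denoise(np.asarray(trials, dtype=float))
        for key, trials in trials_by_condition.items()
    }
    return denoised, result


@dataclass(frozen=True)
class PCAWaveforms:
    components: np.ndarray  # (n_components, time)
    weights: np.ndarray  # (n_components, sensors)
    explained_variance_ratio: np.ndarray


def pca_waveform(data: np.ndarray, n_components: int | None = None) -> PCAWaveforms:
    """Principal components of the sensor dimension of (sensor, time) data.

    Sign convention: each component is flipped so its largest-magnitude
    sample is positive.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected (sensors, time) data")
    centered = data - data.mean(axis=1, keepdims=True)
    u, s, vt = linalg.svd(centered, full_matrices=False)
    var = s**2
    evr = var / var.sum()
    k = n_components or len(s)
    comps = vt[:k] * s[:k, None]
    weights = u[:, :k].T
    for i in range(comps.shape[0]):
        if comps[i, np.argmax(np.abs(comps[i]))] < 0:
            comps[i] *= -1
            weights[i] *= -1
    return PCAWaveforms(components=comps, weights=weights, explained_variance_ratio=evr[:k])


def narrowband_filter(
    data: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.75, 1.25),
    duration_s: float = 2.0,
) -> np.ndarray:
    """Display band filter for component waveforms (FIR, Hamming)."""
    return bandpass_fir(data, sampling_rate, FIRFilterSpec(band=band, duration_s=duration_s))
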