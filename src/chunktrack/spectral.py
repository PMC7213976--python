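"""Frequency-domain analysis and spectral-peak statistics.

Conventions: trials are 12 s at 20 Hz; the trial average is computed first,
the first 2 s are discarded to avoid the onset response, and the remaining
10 s are transformed with a plain DFT (no taper), giving a 0.1 Hz
resolution. Power is ``|X|^2`` and phase ``angle(X)`` of the raw (unscaled)
DFT coefficient.

The spectral-peak test compares target-bin power against the two neighbor
bins with the power ratio ``PR = 2 * sum_k |X_k(fT)|^2 /
sum_k (|X_k(fT-df)|^2 + |X_k(fT+df)|^2)``, F(2N, 4N)-distributed under the
null for N participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # avoid a runtime cycle: synth -> models -> spectral
    from chunktrack.synth import SensorLayout

SAMPLING_RATE = 20.0
TRIAL_DURATION = 12.0
DISCARD_S = 2.0
DELTA_F = 0.1


@dataclass(frozen=True)
class SpectrumResult:
    """Complex DFT coefficients with the frequency axis last."""

    frequencies: np.ndarray
    coefficients: np.ndarray
    sampling_rate: float = SAMPLING_RATE

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def freq_index(self, f: float) -> int:
        idx = int(np.argmin(np.abs(self.frequencies - f)))
        if not np.isclose(self.frequencies[idx], f, atol=1e-9):
            raise ValueError(f"frequency {f} Hz not on the {DELTA_F} Hz grid")
        return idx


def spectrum_of(
    data: np.ndarray,
    sampling_rate: float = SAMPLING_RATE,
    discard_s: float = DISCARD_S,
) -> SpectrumResult:
    """DFT of waveforms (time on the last axis) after onset removal."""
    data = np.asarray(data, dtype=float)
    n_skip = int(round(discard_s * sampling_rate))
    segment = data[..., n_skip:]
    n = segment.shape[-1]
    if n < 2:
        raise ValueError("segment too short after onset removal")
    coeffs = np.fft.rfft(segment, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return SpectrumResult(frequencies=freqs, coefficients=coeffs, sampling_rate=sampling_rate)


def compute_spectrum(
    trials: np.ndarray,
    sampling_rate: float = SAMPLING_RATE,
    trial_axis: int = -2,
    trial_duration: float = TRIAL_DURATION,
    discard_s: float = DISCARD_S,
) -> SpectrumResult:
    """Average trials, drop the first ``discard_s``, and DFT per channel.

    ``trials`` has time on the last axis and trials on ``trial_axis``.
    """
    trials = np.asarray(trials, dtype=float)
    n_expected = int(round(trial_duration * sampling_rate))
    if trials.shape[-1] != n_expected:
        raise ValueError(
            f"trials have {trials.shape[-1]} samples, expected {n_expected}"
        )
    avg = trials.mean(axis=trial_axis)
    return spectrum_of(avg, sampling_rate=sampling_rate, discard_s=discard_s)


def pair_gradiometer_power(power: np.ndarray, layout: "SensorLayout") -> np.ndarray:
    """Arithmetic mean of the two collocated gradiometers' power per position.

    ``power`` has the sensor axis second-to-last (…, sensor, freq).
    """
    power = np.asarray(power)
    if power.shape[-2] != layout.n_sensors:
        raise ValueError(
            f"expected {layout.n_sensors} sensors, got {power.shape[-2]}"
        )
    g1, g2 = layout.gradiometer_indices
    return 0.5 * (power[..., g1, :] + power[..., g2, :])


def position_phase(phase: np.ndarray, layout: "SensorLayout") -> np.ndarray:
    """Circular average of the collocated magnetometer+gradiometer triplet."""
    phase = np.asarray(phase)
    if phase.shape[-2] != layout.n_sensors:
        raise ValueError(
            f"expected {layout.n_sensors} sensors, got {phase.shape[-2]}"
        )
    z = np.exp(1j * phase)
    m = layout.magnetometer_indices
    g1, g2 = layout.gradiometer_indices
    resultant = z[..., m, :] + z[..., g1, :] + z[..., g2, :]
    return np.angle(resultant)


@dataclass(frozen=True)
class PowerRatioTest:
    f_target: float
    ratio: float
    dof: tuple[int, int]
    p_value: float
    n_participants: int


@dataclass(frozen=True)
class PowerDifferenceTest:
    f_target: float
    ratio: float
    dof: tuple[int, int]
    p_value: float
    n_participants: int


def _neighbor_indices(frequencies: np.ndarray, f_target: float, delta_f: float) -> tuple[int, int, int]:
    df = frequencies[1] - frequencies[0]
    i = int(np.argmin(np.abs(frequencies - f_target)))
    if not np.isclose(frequencies[i], f_target, atol=1e-9):
        raise ValueError(f"target frequency {f_target} Hz not on the grid")
    step = int(round(delta_f / df))
    lo, hi = i - step, i + step
    # DC and Nyquist are excluded as targets; both neighbors must exist.
    if i == 0 or i == len(frequencies) - 1 or lo < 0 or hi > len(frequencies) - 1:
        raise ValueError(f"target {f_target} Hz too close to the spectrum edge")
    return lo, i, hi


def power_ratio_test(
    power: np.ndarray,
    frequencies: np.ndarray,
    f_target: float,
    delta_f: float = DELTA_F,
) -> PowerRatioTest:
    """Spectral-peak F-test at ``f_target`` over participants.

    ``power`` is (n_participants, n_freqs): one power spectrum per
    participant (already averaged over sensors as desired). Under the null
    the ratio follows F(2N, 4N); p is the upper tail.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 2:
        raise ValueError("power must be (n_participants, n_freqs)")
    n = power.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    lo, i, hi = _neighbor_indices(np.asarray(frequencies), f_target, delta_f)
    num = 2.0 * power[:, i].sum()
    den = power[:, lo].sum() + power[:, hi].sum()
    if den <= 0:
        raise ValueError("neighbor-bin power is zero")
    ratio = num / den
    dof = (2 * n, 4 * n)
    p = float(stats.f.sf(ratio, *dof))
    return PowerRatioTest(f_target=f_target, ratio=float(ratio), dof=dof, p_value=p, n_participants=n)


def power_difference_test(
    power_a: np.ndarray,
    power_b: np.ndarray,
    frequencies: np.ndarray,
    f_target: float,
    pooled: bool = False,
) -> PowerDifferenceTest:
    """Two-sided between-condition F-test on summed target-bin power.

    dof are (2N, 2N), or (8N, 8N) for the four-cell pooled variant
    (``pooled=True``). The caller is responsible for only comparing
    conditions whose target-bin responses are individually significant.
    """
    power_a = np.asarray(power_a, dtype=float)
    power_b = np.asarray(power_b, dtype=float)
    if power_a.shape != power_b.shape or power_a.ndim != 2:
        raise ValueError("power arrays must both be (n_participants, n_freqs)")
    n = power_a.shape[0]
    freqs = np.asarray(frequencies)
    i = int(np.argmin(np.abs(freqs - f_target)))
    if not np.isclose(freqs[i], f_target, atol=1e-9):
        raise ValueError(f"target frequency {f_target} Hz not on the grid")
    den = power_b[:, i].sum()
    if den <= 0:
        raise ValueError("zero denominator power")
    ratio = power_a[:, i].sum() / den
    d = 8 * n if pooled else 2 * n
    dof = (d, d)
    p = float(min(1.0, 2.0 * min(stats.f.sf(ratio, *dof), stats.f.cdf(ratio, *dof))))
    return PowerDifferenceTest(f_target=f_target, ratio=float(ratio), dof=dof, p_value=p, n_participants=n)


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (reject, q_values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), q.reshape(p.shape)


def spectral_peaks(
    power: np.ndarray,
    frequencies: np.ndarray,
    rel_floor: float = 1e-6,
) -> np.ndarray:
    """Frequencies whose power exceeds both neighbor bins.

    DC and Nyquist are excluded; bins below ``rel_floor`` of the maximum
    power are ignored (guards against float noise on numerically-zero bins).
    """
    power = np.asarray(power, dtype=float)
    frequencies = np.asarray(frequencies)
    if power.ndim != 1:
        raise ValueError("power must be one-dimensional")
    floor = rel_floor * power.max()
    inner = np.arange(1, len(power) - 1)
    mask = (
        (power[inner] > power[inner - 1])
        & (power[inner] > power[inner + 1])
        & (power[inner] > floor)
    )
    return frequencies[inner[mask]]
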