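"""Synthetic multi-sensor trial data with known ground truth.

Emulates the statistical structure of the recorded dataset — 16
participants, a 306-sensor array of 102 magnetometer positions each with
two collocated gradiometers, 12 s trials at a 2 Hz word rate with
narrow-band 1 Hz and 2 Hz responses embedded in 1/f background noise — so
every analysis stage is testable without real recordings.

Each trial's sensor signal is ``m * s(t) + noise`` where ``s(t)`` is the
configured response-model waveform for that trial's sequence plus a word-
rate component and an onset transient, ``m`` is a per-participant smooth
random sensor topography, and the noise is 1/f^alpha Gaussian with unit
variance inside the 0.3–2.7 Hz analysis band. Trials carry ``pad_s``
seconds of signal-free padding on both sides so the 10 s FIR filter can be
applied per trial without contaminating the 12 s core.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from chunktrack import models as _models
from chunktrack import stimuli as _stimuli
from chunktrack.models import ResponseKernel, ResponseModel
from chunktrack.stimuli import Condition, OrderType, SEQUENCE_DURATION

ANALYSIS_BAND = (0.3, 2.7)
MAG_SCALE = 1.0
GRAD_SCALE = 0.7


@dataclass(frozen=True)
class SensorLayout:
    """Collocated magnetometer + two-gradiometer triplets.

    Sensors are ordered position-major: index 3p is the magnetometer at
    position p, 3p+1 and 3p+2 its gradiometers.
    """

    n_positions: int = 102

    @property
    def n_sensors(self) -> int:
        return 3 * self.n_positions

    @property
    def magnetometer_indices(self) -> np.ndarray:
        return np.arange(self.n_positions) * 3

    @property
    def gradiometer_indices(self) -> tuple[np.ndarray, np.ndarray]:
        base = np.arange(self.n_positions) * 3
        return base + 1, base + 2

    @property
    def sensor_types(self) -> np.ndarray:
        types = np.empty(self.n_sensors, dtype=object)
        types[self.magnetometer_indices] = "mag"
        g1, g2 = self.gradiometer_indices
        types[g1] = "grad"
        types[g2] = "grad"
        return types

    def sensor_names(self) -> list[str]:
        names = []
        for p in range(self.n_positions):
            names += [f"pos{p:03d}_mag", f"pos{p:03d}_grad1", f"pos{p:03d}_grad2"]
        return names


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth generation parameters."""

    n_participants: int = 16
    trials_per_cell: int = 22  # normal trials per condition x order type
    n_positions: int = 102
    source_model: str | Mapping[str, float] = ResponseModel.CHUNKING.value
    snr_db: float = 10.0
    noise_exponent: float = 1.0
    response_gain: float = 1.0
    word_rate_response_gain: float = 0.5
    onset_response_gain: float = 1.0
    phase_jitter_s: float = 0.0
    include_outlier_trials: bool = False
    outlier_trials_per_cell: int = 8
    sampling_rate: float = 20.0
    pad_s: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must be a real number or -inf")
        for g in (self.response_gain, self.word_rate_response_gain, self.onset_response_gain):
            if g < 0:
                raise ValueError("gains must be >= 0")
        weights = self.model_weights()
        if any(w < 0 for w in weights.values()):
            raise ValueError("model mixture weights must be >= 0")

    def model_weights(self) -> dict[str, float]:
        if isinstance(self.source_model, str):
            return {ResponseModel(self.source_model).value: 1.0}
        return {ResponseModel(k).value: float(v) for k, v in self.source_model.items()}


@dataclass
class TrialDataset:
    """participants x sensors x trials x time, with per-trial labels.

    ``data`` includes the padding; :meth:`core` crops to the 12 s trial.
    """

    data: np.ndarray
    labels: pd.DataFrame
    layout: SensorLayout
    config: SyntheticConfig
    mixing: np.ndarray  # (n_participants, n_sensors)
    sampling_rate: float
    pad_samples: int

    def core(self) -> np.ndarray:
        n = int(round(SEQUENCE_DURATION * self.sampling_rate))
        return self.data[..., self.pad_samples : self.pad_samples + n]

    def trial_indices(
        self,
        condition: Condition | str | None = None,
        order_type: OrderType | str | None = None,
        normal_only: bool = True,
    ) -> np.ndarray:
        mask = np.ones(len(self.labels), dtype=bool)
        if condition is not None:
            mask &= self.labels["condition"].values == Condition(condition).value
        if order_type is not None:
            mask &= self.labels["order_type"].values == OrderType(order_type).value
        if normal_only:
            mask &= ~self.labels["is_outlier"].values
        return np.flatnonzero(mask)

    # -- HDF5 container ----------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            lab = f.create_group("labels")
            str_dt = h5py.string_dtype("utf-8")
            lab.create_dataset("condition", data=self.labels["condition"].values.astype(object), dtype=str_dt)
            lab.create_dataset("order_type", data=self.labels["order_type"].values.astype(object), dtype=str_dt)
            lab.create_dataset("is_outlier", data=self.labels["is_outlier"].values.astype(bool))
            f.create_dataset("mixing", data=self.mixing)
            f.attrs["ground_truth"] = json.dumps(asdict(self.config))
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["pad_samples"] = self.pad_samples
            f.attrs["n_positions"] = self.layout.n_positions

    @classmethod
    def from_hdf5(cls, path) -> "TrialDataset":
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            labels = pd.DataFrame(
                {
                    "condition": [s.decode() if isinstance(s, bytes) else s for s in f["labels/condition"][...]],
                    "order_type": [s.decode() if isinstance(s, bytes) else s for s in f["labels/order_type"][...]],
                    "is_outlier": f["labels/is_outlier"][...].astype(bool),
                }
            )
            cfg = json.loads(f.attrs["ground_truth"])
            config = SyntheticConfig(**cfg)
            return cls(
                data=data,
                labels=labels,
                layout=SensorLayout(int(f.attrs["n_positions"])),
                config=config,
                mixing=f["mixing"][...],
                sampling_rate=float(f.attrs["sampling_rate"]),
                pad_samples=int(f.attrs["pad_samples"]),
            )

    def manifest(self) -> pd.DataFrame:
        out = self.labels.copy()
        out.insert(0, "trial", np.arange(len(out)))
        return out


def pink_noise(
    n_samples: int,
    alpha: float,
    rng: np.random.Generator,
    size: tuple[int, ...] = (),
    sampling_rate: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^alpha.

    Spectral-shaping construction: white rFFT coefficients are weighted by
    f^(-alpha/2) (DC weight 0) and inverted. Output is scaled to unit
    variance in expectation. Leading ``size`` axes give independent
    realizations.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    weights = np.zeros(n_freq)
    weights[1:] = freqs[1:] ** (-alpha / 2.0)
    shape = tuple(size) + (n_freq,)
    coeffs = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * weights
    x = np.fft.irfft(coeffs, n=n_samples, axis=-1)
    # E[var] via Parseval: a complex bin (unit-variance real and imaginary
    # parts, weight w) contributes 4 w^2 / n^2; the real DC/Nyquist bins w^2.
    w2 = weights**2 * 4.0
    w2[0] /= 4.0
    if n_samples % 2 == 0:
        w2[-1] /= 4.0
    expected_var = w2.sum() / n_samples**2
    return x / np.sqrt(expected_var)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def _inband_fraction(n_samples: int, alpha: float, sampling_rate: float) -> float:
    """Expected fraction of pink-noise variance inside the analysis band."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    w2 = np.zeros_like(freqs)
    w2[1:] = freqs[1:] ** (-alpha)
    total = w2.sum()
    return float(w2[_band_mask(freqs, ANALYSIS_BAND)].sum() / total)


def _smooth_topography(n_positions: int, rng: np.random.Generator, n_modes: int = 5) -> np.ndarray:
    """Random low-order cosine pattern over position index, unit RMS."""
    x = np.linspace(0.0, 1.0, n_positions)
    basis = np.stack([np.cos(np.pi * k * x) for k in range(n_modes)])
    v = rng.standard_normal(n_modes) @ basis
    return v / np.sqrt(np.mean(v**2))


def _mixing_vector(layout: SensorLayout, rng: np.random.Generator) -> np.ndarray:
    v = _smooth_topography(layout.n_positions, rng)
    m = np.empty(layout.n_sensors)
    m[layout.magnetometer_indices] = v * MAG_SCALE
    g1, g2 = layout.gradiometer_indices
    m[g1] = v * GRAD_SCALE
    m[g2] = v * GRAD_SCALE
    return m


def _source_waveform(
    sequence: _stimuli.StimulusSequence,
    config: SyntheticConfig,
    kernel: ResponseKernel,
) -> np.ndarray:
    """Model waveform + word-rate component + onset transient (12 s core)."""
    n = int(round(SEQUENCE_DURATION * config.sampling_rate))
    s = np.zeros(n)
    for name, w in config.model_weights().items():
        if w == 0:
            continue
        s += w * _models.simulate_waveform(sequence, name, kernel=kernel).samples
    s *= config.response_gain
    if config.word_rate_response_gain > 0:
        s += config.word_rate_response_gain * _models.convolve_with_kernel(
            _models.word_onset_pulses(sequence), kernel
        )
    if config.onset_response_gain > 0:
        k = kernel.samples
        s[: len(k)] += config.onset_response_gain * k[: min(len(k), n)]
    return s


def _cell_sequences(
    condition: Condition,
    order_type: OrderType,
    config: SyntheticConfig,
    vocabulary: _stimuli.Vocabulary,
    rng: np.random.Generator,
) -> list[_stimuli.StimulusSequence]:
    seqs = []
    for _ in range(config.trials_per_cell):
        if order_type is OrderType.ALTERNATING:
            seq = _stimuli.make_alternating_sequence(condition)
        else:
            seq = _stimuli.make_random_sequence(condition, rng)
        seqs.append(_stimuli.fill_words(seq, vocabulary, rng))
    if config.include_outlier_trials:
        for _ in range(config.outlier_trials_per_cell):
            if order_type is OrderType.ALTERNATING:
                seq = _stimuli.make_alternating_sequence(condition)
            else:
                seq = _stimuli.make_random_sequence(condition, rng)
            seqs.append(_stimuli.make_outlier(_stimuli.fill_words(seq, vocabulary, rng), rng))
    return seqs


def generate_dataset(config: SyntheticConfig) -> TrialDataset:
    """Generate the full trial dataset; bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    layout = SensorLayout(config.n_positions)
    fs = config.sampling_rate
    kernel = ResponseKernel(sampling_rate=fs)
    vocabulary = _stimuli.build_vocabulary(rng)

    n_core = int(round(SEQUENCE_DURATION * fs))
    pad = int(round(config.pad_s * fs))
    n_time = n_core + 2 * pad

    cells = [
        (c, o)
        for c in (Condition.SAME, Condition.DIFFERENT)
        for o in (OrderType.ALTERNATING, OrderType.RANDOM)
    ]
    per_cell = config.trials_per_cell + (
        config.outlier_trials_per_cell if config.include_outlier_trials else 0
    )
    n_trials = per_cell * len(cells)

    snr_linear = 10.0 ** (config.snr_db / 10.0) if np.isfinite(config.snr_db) else 0.0
    if np.isposinf(config.snr_db):
        raise ValueError("snr_db must be finite or -inf")
    inband = _inband_fraction(n_time, config.noise_exponent, fs)
    band = _band_mask(np.fft.rfftfreq(n_core, d=1.0 / fs), ANALYSIS_BAND)

    data = np.empty((config.n_participants, layout.n_sensors, n_trials, n_time), dtype=np.float32)
    mixing = np.empty((config.n_participants, layout.n_sensors))
    label_rows: list[dict] = []

    for p in range(config.n_participants):
        m = _mixing_vector(layout, rng)
        mixing[p] = m

        signals = np.zeros((n_trials, n_time))
        t = 0
        sig_power = 0.0
        for condition, order_type in cells:
            for seq in _cell_sequences(condition, order_type, config, vocabulary, rng):
                s = _source_waveform(seq, config, kernel)
                if config.phase_jitter_s > 0:
                    shift = int(round(rng.normal(0.0, config.phase_jitter_s) * fs))
                    s = np.roll(s, shift)
                # in-band signal power of the 12 s core (Parseval)
                coeffs = np.fft.rfft(s)
                w2 = np.abs(coeffs) ** 2 * 2.0
                w2[0] /= 2.0
                if n_core % 2 == 0:
                    w2[-1] /= 2.0
                sig_power += w2[band].sum() / n_core**2
                signals[t, pad : pad + n_core] = s
                if p == 0:
                    label_rows.append(
                        {
                            "condition": condition.value,
                            "order_type": order_type.value,
                            "is_outlier": seq.is_outlier,
                        }
                    )
                t += 1
        sig_power /= n_trials

        mean_m2 = float(np.mean(m**2))
        if snr_linear > 0 and sig_power > 0:
            amp = np.sqrt(snr_linear / (mean_m2 * sig_power))
        else:
            amp = 0.0

        # noise: unit in-band variance per sensor/trial
        noise = pink_noise(
            n_time,
            config.noise_exponent,
            rng,
            size=(layout.n_sensors, n_trials),
            sampling_rate=fs,
        ) / np.sqrt(inband)
        data[p] = (amp * m[:, None, None] * signals[None, :, :] + noise).astype(np.float32)

    labels = pd.DataFrame(label_rows)
    return TrialDataset(
        data=data,
        labels=labels,
        layout=layout,
        config=config,
        mixing=mixing,
        sampling_rate=fs,
        pad_samples=pad,
    )
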