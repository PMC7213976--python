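# chunktrack

Frequency-tagging analysis of chunk-rate neural tracking. The package
generates chunk-structured word-sequence stimuli, simulates three competing
neural-response models (lexical property, semantic relatedness, rule-based
chunking), synthesizes multi-sensor MEG-like trial data with known ground
truth, and runs the spectral and circular-phase statistics that adjudicate
between the models.

## Design summary

Stimuli are 12 s sequences of 24 half-second word tokens from two semantic
categories (living `L` / nonliving `N`), grouped into twelve 1 s chunks.
The *same-category* rule admits `LL`/`NN` chunks; the *different-category*
rule admits `NL`/`LN`. Sequences come in alternating order (`NNLL`x6 or
`NLLN`x6) or random order (i.i.d. draws of the two valid chunks), and
blocks mix 44 normal with 16 outlier sequences (one L/N word swap that
invalidates exactly two chunks).

Each model is a pulse train on the word/chunk-onset grid convolved with a
500 ms Gaussian kernel. At the 1 Hz chunk rate the models make orthogonal
predictions for the between-condition phase difference — 0° (rule-based
chunking), 180° (semantic relatedness), undefined (lexical property, which
instead peaks at 0.5 Hz) — tested by a power-ratio F(2N, 4N) statistic on
neighboring spectral bins and a participant-resampling bootstrap of whether
the phase difference is closer to 0° or 180°.

## Modules

| module | contents |
| --- | --- |
| `chunktrack.stimuli` | vocabulary, sequence/block generation, outliers, validity checking, JSON/CSV serialization |
| `chunktrack.models` | pulse trains, Gaussian kernel, waveform simulation, predicted spectra and phase differences |
| `chunktrack.synth` | sensor layout, 1/f noise, ground-truth trial datasets, HDF5 container |
| `chunktrack.preprocess` | FIR bandpass with group-delay compensation, spectrum compensation, epoching/downsampling, DSS denoising, PCA waveforms |
| `chunktrack.spectral` | DFT conventions, gradiometer pairing, power-ratio and power-difference F-tests, BH-FDR |
| `chunktrack.phase` | circular means, wrapped phase differences, bootstrap closer-to-0° test, shortest-arc CI |
| `chunktrack.pipeline` / `chunktrack.cli` | YAML-configured end-to-end runs and the `chunktrack` command |

## CLI

```sh
# model-prediction summary (spectra, peaks, 1 Hz phase differences)
chunktrack predict --seed 0 --out out/predictions.json

# synthetic dataset -> full analysis -> human-readable summary
chunktrack generate --config config.yaml --out out/data.h5
chunktrack analyze --config config.yaml --data out/data.h5 --out out/analysis.json
chunktrack report --analysis out/analysis.json
```

A minimal `config.yaml`:

```yaml
seed: 1
synthetic:
  n_participants: 16
  trials_per_cell: 22
  n_positions: 102
  source_model: rule_based_chunking
  snr_db: 10.0
analysis:
  n_resamples: 100000
```

`analyze` runs the stages in order: bandpass FIR (0.3–2.7 Hz, 10 s Hamming,
−6 dB at the cutoffs, delay-compensated) → crop to the 12 s trial → common
DSS across the four condition/order cells (six components retained) →
trial-average DFT with filter-response compensation → power-ratio tests at
0.5/1/2 Hz with FDR → bootstrap phase test at 1 Hz. Outlier trials are
generated but excluded from analysis.

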