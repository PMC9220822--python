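# Methods

## Problem and pipeline

The package classifies 1-s EEG trials (64 channels sampled at 256 Hz) as
*alcoholic* (positive) or *control* (negative).  The pipeline is:
standardize → multilevel DWT denoising → CNN-Bi-LSTM → sigmoid
probability → threshold at 0.5 → confusion-matrix metrics.

### Standardization

Per-feature z-scoring with the **population** standard deviation
(`ddof=0`): `X ← (X − μ)/σ`.  The scaler is fitted on the **training split
only** and applied to all splits; fitting on pooled data would leak test
statistics into training, which the permutation control below would
expose.  Zero-variance features transform to 0 with a warning rather than
an error: degenerate but recoverable (a flat channel should not abort a
run).

### Discrete wavelet transform

The analysis bank convolves the signal with an orthogonal low/high-pass
pair and decimates by two (dyadic scales); only the approximation branch
is decomposed further at each level (approximation cascade).  The deepest
approximation coefficients are the denoised feature vector.  Retaining
the approximation is a low-pass operation: the discarded detail bands are
where measurement noise, muscle and line artifacts concentrate.

Conventions (all verified coefficient-wise at 1e-8 against an independent
third-party DWT implementation in the test suite, which is the only place
that library is used):

* filters are stored as the analysis low-pass `dec_lo` in a plain-text
  table (`data/wavelets.txt`); the high-pass is the quadrature-mirror
  alternating-sign flip, synthesis filters are time reversals;
* padding modes: `zero`, `symmetric` (edge sample repeated), `periodic`
  (orthonormal — Parseval holds, coefficient count is `ceil(n/2)` per
  step; odd lengths repeat the final sample first);
* `zero`/`symmetric` produce `floor((n + L − 1)/2)` coefficients per step
  (`L` = filter length);
* synthesis (`idwt`) is implemented to invert analysis exactly (max abs
  reconstruction error < 1e-8 over all shipped wavelets, levels 1–4,
  lengths 64/100/256; in practice ~1e-15).

**Defaults: db4, level 2, symmetric padding** — Daubechies-4 at shallow
depth is the de-facto standard for EEG denoising, and two levels keep
frequencies below ~32 Hz (the physiological delta–beta range) in the
approximation at 256 Hz.  All three are config knobs.

A 256-sample trial gives 69 features under the default (symmetric, two
cascades of `floor((n+7)/2)`) and 64 under periodic padding.  No standard
single wavelet/level/padding combination yields a 76-sample vector from
256 inputs; because the classifier was originally specified for a 76×1
input, the front-end exposes `target_length` (pad/truncate to a fixed
width such as 76) for strict architectural replication, and the network otherwise
sizes its input layer from `feature_length(n, spec, level)` rather than a
hard-coded constant.

### Network

`ModelConfig` defaults encode the reference architecture: conv
64→pool→conv 64→conv 128→conv 128→pool (kernel 3, stride 1), dense 256 +
dropout, reshape to a 4×64 sequence, two stacked Bi-LSTMs of 64 units per
direction (first returns the full sequence, second only its final step),
dense 256/128/64 each + dropout, sigmoid unit; Adam lr 0.001, 100 epochs,
batch 200 at full scale.  Decisions where the published description is
silent:

* **vector→sequence reshape**: a 256-wide dense activation feeds a
  recurrent stack; the smallest faithful reading is a fixed reshape,
  default (timesteps=4, features=64), configurable;
* **conv padding**: default `same` (pooling is then the only length
  reducer); `valid` supported, and the shape table for both is asserted
  against the closed-form recurrences `L' = floor((L − k)/s) + 1` and
  `L' = L` in the tests;
* **dropout rate**: 0.5 (the common default), configurable;
* **dense activations**: ReLU;
* **loss**: binary cross-entropy (implied by the sigmoid output);
* **input topology**: by default every channel of every trial is one
  (length × 1) sample inheriting the trial label; a `multichannel` mode
  (length × n_channels) is provided via `input_channels`;
* **initialization**: Glorot-uniform kernels, orthogonal recurrent
  matrices, zero biases except the forget gate at 1; fully seeded, so
  builds and training runs are bit-reproducible.

The training stack is NumPy throughout (`alcoeeg.nn`): explicit forward/
backward passes for every layer, backpropagation through time for the
LSTM, Adam with bias correction, probability clipping at 1e-7 in the
loss.  Every layer's analytic gradient is checked against centred finite
differences in the suite.  The LSTM appears twice on purpose: a per-gate
*reference cell* (`network.lstm_cell_step`) transcribing the gate
equations, and the fused-matrix training layer (`nn.LSTM`); their
step-for-step agreement (≤1e-5 over random draws) is the bridge showing
the trained models implement those equations.

### Metrics

Accuracy, precision, recall, F1 from TP/FP/TN/FN, with the convention
that a zero denominator yields 0 (flagged `zero_division` in the report).
Threshold default 0.5.  Metrics are asserted equal to brute-force
per-sample counting on random draws.

## Synthetic data

`synthgen.generate` emulates the trial geometry of the public alcoholism
EEG corpus (64 channels × 256 samples at 256 Hz; standard 10-20-derived
channel names).  Per channel a trial sums:

* an AR(2) background, poles at 0.6 ± 0 (coefficients 1.2, −0.36, noise
  sd 4 µV), giving the 1/f-like spectral rolloff of resting EEG so the
  denoiser has realistic broadband structure to remove;
* band-limited rhythms: theta 6±1 Hz (6 µV), alpha 10±1 Hz (10 µV), beta
  20±2 Hz (4 µV), each with per-channel random frequency, phase and ±10%
  amplitude jitter — amplitudes in the range of scalp EEG;
* optionally (10% of trials) a smooth Gaussian eye-blink transient
  (40 µV) on frontal channels;
* a log-normal per-subject amplitude scale (sd 0.1) for between-subject
  variability.

The class difference is a single multiplier `effect` on the alpha-band
amplitude of the positive class, reflecting the altered rhythm band power
reported for alcoholism; `effect=1` makes the classes statistically
identical (the null), `effect=3` makes them strongly separable.  What the
generator does **not** model: volume-conduction correlations between
channels, event-related potentials of the stimulus paradigm, non-blink
artifacts, non-stationarity across a session.  Passing tests therefore
demonstrate that the pipeline recovers band-power class structure from
noisy multichannel signals — not clinical performance on real recordings.

`band_power` (test instrumentation) measures mean squared amplitude in a
band with an ideal frequency-domain filter; for an on-grid sinusoid of
amplitude A it returns A²/2 exactly.

## Benchmarks and controls

`benchmarks.py` fixes the desk-scale study conditions (sizes chosen to
run in minutes on one CPU; the architecture is never changed):

* **separable**: effect=3, 5 subjects/class × 10 trials × 20 channels =
  2,000 channel-samples, 80/20 stratified trial-wise split, 15 epochs,
  batch 64.  Expectation: held-out accuracy ≥ 0.95 and no worse than the
  CNN-only ablation under identical seeds.
* **null**: effect=1, 100 trials × 8 channels, 20 independent seeds
  (fresh dataset, split and initialization each).  Pooled held-out
  accuracy must lie inside the 95% binomial band around 0.5.
* **permutation control**: separable data at the null size but with
  training labels shuffled; test labels intact.  Chance-level accuracy
  here is the leakage guard — a standardizer fitted on pooled data, or
  any other train/test contamination, would push it above the band.

Null/permutation runs train 6 epochs instead of 15: chance-level
behaviour does not depend on schedule length, and the controls' power
comes from the number of seeds and pooled predictions, not the schedule.

The split protocol is stratified trial-wise 80/20 by default because the
benchmark generator assigns subjects disjoint trials anyway; for real
recordings the `subject_wise` mode is the recommended protocol, since
subject identity leakage is known to inflate EEG classification scores.

## External data

With the public UCI SMNI corpus downloaded (plain-text trial files, read
by `eeg_io.read_smni_directory`), the full-scale configuration (100
epochs, batch 200, 5 seeds) is the intended experiment; published results
on this corpus report high-90s accuracy for this architecture family with
the ordering proposed > CNN+Bi-LSTM > CNN > Bi-LSTM > LSTM.  That
experiment needs the download and hours of CPU, so it is documented here
rather than run in the suite; no test or script in this repository
depends on external data.

## Known limitations

* Stride-1 convolutions and size-2/stride-2 pooling only (what the
  architecture uses); no GPU path; pure-NumPy training is practical at
  desk scale (~10⁵–10⁶ parameters, thousands of samples) but not for
  large corpora.
* The SMNI reader handles the single-trial-per-file dialect (optionally
  gzipped); EDF/BDF and streaming input are out of scope.
* CSV containers store voltages at 12 significant digits (round-trip to
  1e-9); HDF5 is exact.  CSV does not carry the sampling rate and assumes
  the 256 Hz default on read.
* The trained-model checkpoint format is JSON (text): portable and
  adequate at these sizes, slow for very large models.
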