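"""Seeded two-class synthetic EEG generator.

Each trial is the sum of three components per channel:

* an AR(2) background whose poles give a 1/f-like spectrum (so low-pass
  denoising has realistic structure to act on),
* band-limited oscillations (theta/alpha/beta by default) whose amplitudes
  carry the class difference: the positive class multiplies selected band
  amplitudes by ``effect`` (``effect=1`` makes the classes statistically
  identical — the null configuration),
* an optional smooth eye-blink transient on the frontal channels.

Between-subject variability enters as a log-normal per-subject amplitude
scale.  Everything is driven by one seed, so a dataset is bit-reproducible.

The class difference is encoded as band-power modulation because altered
rhythm band power is the established EEG signature of alcoholism; the
single ``effect`` knob makes the separation strength interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .eeg_io import EEGDataset, EEGTrial, NEGATIVE, POSITIVE

#: 61 standard 10-20-derived electrode sites plus reference/extras, matching
#: the montage geometry of 64-electrode recordings; the first entries are
#: frontal (blink-artifact carriers).
CHANNEL_NAMES_64 = [
    "FP1", "FP2", "F7", "F8", "AF1", "AF2", "FZ", "F4", "F3", "FC6", "FC5",
    "FC2", "FC1", "T8", "T7", "CZ", "C3", "C4", "CP5", "CP6", "CP1", "CP2",
    "P3", "P4", "PZ", "P8", "P7", "PO2", "PO1", "O2", "O1", "X", "AF7",
    "AF8", "F5", "F6", "FT7", "FT8", "FPZ", "FC4", "FC3", "C6", "C5", "F2",
    "F1", "TP8", "TP7", "AFZ", "CP3", "CP4", "P5", "P6", "C1", "C2", "PO7",
    "PO8", "FCZ", "POZ", "OZ", "P2", "P1", "CPZ", "nd", "Y",
]

_FRONTAL = ("FP1", "FP2", "FPZ", "AF1", "AF2", "AF7", "AF8", "AFZ")


@dataclass
class Band:
    center: float  # Hz
    bandwidth: float  # Hz (full width)
    amplitude: float  # microvolts


@dataclass
class SynthConfig:
    """Generation parameters; defaults emulate the 64-channel, 256-sample,
    256-Hz trial geometry of the public alcoholism EEG corpus."""

    n_subjects_per_class: int = 5
    trials_per_subject: int = 10
    n_channels: int = 64
    n_samples: int = 256
    sampling_rate: float = 256.0
    ar_coeffs: tuple[float, float] = (1.2, -0.36)  # poles at 0.6, 0.6: 1/f-ish
    ar_noise_sd: float = 4.0
    bands: tuple[Band, ...] = (
        Band(6.0, 2.0, 6.0),    # theta
        Band(10.0, 2.0, 10.0),  # alpha
        Band(20.0, 4.0, 4.0),   # beta
    )
    effect: float = 1.0
    effect_bands: tuple[int, ...] = (1,)  # indices into `bands`; default alpha
    artifact_rate: float = 0.1
    artifact_amplitude: float = 40.0
    subject_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")
        nyquist = self.sampling_rate / 2.0
        for band in self.bands:
            if band.center >= nyquist:
                raise ValueError(
                    f"band center {band.center} Hz at or above Nyquist ({nyquist} Hz)"
                )


def _ar2_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                    coeffs: tuple[float, float], noise_sd: float) -> np.ndarray:
    a1, a2 = coeffs
    burn = 64
    eps = rng.normal(scale=noise_sd, size=(n_channels, n_samples + burn))
    # x_t = a1 x_{t-1} + a2 x_{t-2} + eps_t  <=>  AR filter 1/(1 - a1 z^-1 - a2 z^-2)
    x = sp_signal.lfilter([1.0], [1.0, -a1, -a2], eps, axis=1)
    return x[:, burn:]


def _blink(rng: np.random.Generator, n_samples: int, rate: float,
           amplitude: float) -> np.ndarray | None:
    if rng.random() >= rate:
        return None
    center = rng.uniform(0.2, 0.8) * n_samples
    width = rng.uniform(0.03, 0.08) * n_samples
    t = np.arange(n_samples)
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


def generate(config: SynthConfig) -> EEGDataset:
    """Generate a two-class dataset; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    names = (CHANNEL_NAMES_64 * ((config.n_channels // 64) + 1))[: config.n_channels]
    if len(set(names)) != len(names):  # > 64 channels: disambiguate
        names = [f"{n}_{i}" for i, n in enumerate(names)]
    frontal_rows = [i for i, n in enumerate(names) if n in _FRONTAL] or [0]
    t = np.arange(config.n_samples) / config.sampling_rate

    trials: list[EEGTrial] = []
    for label, prefix in ((POSITIVE, "a"), (NEGATIVE, "c")):
        for subj in range(config.n_subjects_per_class):
            subject_id = f"{prefix}{subj:03d}"
            subj_scale = float(np.exp(rng.normal(scale=config.subject_sd)))
            for _ in range(config.trials_per_subject):
                data = _ar2_background(rng, config.n_channels, config.n_samples,
                                       config.ar_coeffs, config.ar_noise_sd)
                for bi, band in enumerate(config.bands):
                    amp = band.amplitude * subj_scale
                    if label == POSITIVE and bi in config.effect_bands:
                        amp *= config.effect
                    freqs = rng.uniform(band.center - band.bandwidth / 2.0,
                                        band.center + band.bandwidth / 2.0,
                                        size=config.n_channels)
                    phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
                    chan_amp = amp * (1.0 + 0.1 * rng.normal(size=config.n_channels))
                    data += chan_amp[:, None] * np.sin(
                        2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
                    )
                blink = _blink(rng, config.n_samples, config.artifact_rate,
                               config.artifact_amplitude)
                if blink is not None:
                    data[frontal_rows] += blink
                trials.append(EEGTrial(
                    subject_id=subject_id, label=label, data=data,
                    channel_names=list(names),
                    condition="synthetic",
                    sampling_rate=config.sampling_rate,
                ))
    return EEGDataset(trials, provenance=f"synthetic seed={config.seed}")


def band_power(trial: EEGTrial, band: Band) -> np.ndarray:
    """Mean squared amplitude of the band-filtered signal, per channel.

    The band is isolated with an ideal (brick-wall) frequency-domain filter,
    which avoids the edge transients an IIR filter would introduce on a
    short 1-s trial; for a pure sinusoid of amplitude A at the band center
    this returns A^2/2 per channel (up to spectral leakage of off-grid
    frequencies).
    """
    lo = band.center - band.bandwidth / 2.0
    hi = band.center + band.bandwidth / 2.0
    n = trial.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / trial.sampling_rate)
    mask = (freqs >= lo) & (freqs <= hi)
    spectrum = np.fft.rfft(trial.data, axis=1) * mask[None, :]
    filtered = np.fft.irfft(spectrum, n=n, axis=1)
    return np.mean(filtered**2, axis=1)
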