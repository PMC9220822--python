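"""Standardization and from-scratch multilevel discrete wavelet transform.

Two preprocessing stages precede the classifier:

1. *Standard-deviation standardization*: ``X -> (X - mu) / sigma`` per
   feature column, with the population standard deviation, so each feature
   has mean 0 and standard deviation 1 on the data the scaler was fitted on.

2. *Approximation-cascade DWT denoising*: the signal is run through an
   orthogonal two-channel filter bank (Mallat pyramid); only the low-pass
   (approximation) branch is decomposed further at each level, and the
   deepest approximation coefficients become the feature vector fed to the
   network.  Discarding the detail branches suppresses the high-frequency
   part of the signal where measurement noise and muscle artifacts live,
   which raises the signal-to-noise ratio of the retained component.

The filter bank is implemented here directly (convolution + dyadic
decimation) rather than delegated to a wavelet library; its conventions
(padding modes, coefficient ordering, output lengths) match the de-facto
standard ones so third-party implementations can be used as oracles in
tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

PADDING_MODES = ("periodic", "symmetric", "zero")


# ---------------------------------------------------------------------------
# Wavelet specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletSpec:
    """A named orthogonal wavelet realized by its filter bank.

    ``dec_lo``/``dec_hi`` are the analysis low/high-pass filters,
    ``rec_lo``/``rec_hi`` the synthesis pair.  For an orthogonal wavelet the
    high-pass is the alternating-sign flip of the low-pass (quadrature
    mirror) and the synthesis filters are the time-reversed analysis ones;
    with periodic padding the resulting transform is orthonormal, i.e.
    energy-preserving.
    """

    name: str
    dec_lo: tuple[float, ...]
    dec_hi: tuple[float, ...]
    rec_lo: tuple[float, ...]
    rec_hi: tuple[float, ...]
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.padding not in PADDING_MODES:
            raise ValueError(
                f"unknown padding mode {self.padding!r}; expected one of {PADDING_MODES}"
            )
        if len(self.dec_lo) % 2 != 0:
            raise ValueError("orthogonal wavelet filters must have even length")

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)

    @classmethod
    def from_dec_lo(
        cls, name: str, dec_lo: Sequence[float], padding: str = "symmetric"
    ) -> "WaveletSpec":
        """Derive the full orthogonal filter bank from the analysis low-pass."""
        lo = tuple(float(c) for c in dec_lo)
        rec_lo = lo[::-1]
        # quadrature mirror: dec_hi[k] = (-1)^(k+1) rec_lo[k]
        dec_hi = tuple(((-1) ** (k + 1)) * c for k, c in enumerate(rec_lo))
        rec_hi = dec_hi[::-1]
        return cls(name=name, dec_lo=lo, dec_hi=dec_hi, rec_lo=rec_lo, rec_hi=rec_hi,
                   padding=padding)

    def with_padding(self, padding: str) -> "WaveletSpec":
        return WaveletSpec(self.name, self.dec_lo, self.dec_hi, self.rec_lo,
                           self.rec_hi, padding)


def _load_wavelet_table() -> dict[str, tuple[float, ...]]:
    table: dict[str, tuple[float, ...]] = {}
    text = resources.files("alcoeeg").joinpath("data/wavelets.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, *coeffs = line.split()
        table[name] = tuple(float(c) for c in coeffs)
    return table


_WAVELET_TABLE = _load_wavelet_table()


def available_wavelets() -> list[str]:
    return sorted(_WAVELET_TABLE)


def get_wavelet(name: str, padding: str = "symmetric") -> WaveletSpec:
    """Look up a shipped wavelet by name (``haar``, ``db2``, ``db4``)."""
    try:
        dec_lo = _WAVELET_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown wavelet {name!r}; shipped wavelets: {available_wavelets()}"
        ) from None
    return WaveletSpec.from_dec_lo(name, dec_lo, padding=padding)


# ---------------------------------------------------------------------------
# Standardizer
# ---------------------------------------------------------------------------

@dataclass
class StandardizerState:
    """Fitted per-feature mean and population standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    fitted_on: int
    zero_variance: np.ndarray = field(default=None)  # boolean mask

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = self.sigma == 0.0
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be non-negative")


def fit_standardizer(matrix: np.ndarray) -> StandardizerState:
    """Fit per-feature mean/standard deviation on a samples x features matrix.

    The *population* standard deviation (``ddof=0``) is used.  Features with
    zero variance are recorded; their transformed value is defined as 0 and a
    warning is emitted at fit time.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D samples x features matrix, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a standardizer")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population (ddof=0)
    zero_var = sigma == 0.0
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); their standardized "
            "values are defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return StandardizerState(mu=mu, sigma=sigma, fitted_on=X.shape[0],
                             zero_variance=zero_var)


def apply_standardizer(state: StandardizerState, matrix: np.ndarray) -> np.ndarray:
    """Apply ``(X - mu) / sigma`` elementwise; zero-variance features map to 0."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != state.mu.shape[0]:
        raise ValueError(
            f"feature count mismatch: matrix has {X.shape[1]}, "
            f"standardizer fitted on {state.mu.shape[0]}"
        )
    safe_sigma = np.where(state.zero_variance, 1.0, state.sigma)
    out = (X - state.mu) / safe_sigma
    if np.any(state.zero_variance):
        out[:, state.zero_variance] = 0.0
    return out


def invert_standardizer(state: StandardizerState, matrix: np.ndarray) -> np.ndarray:
    """Algebraic inverse ``X * sigma + mu`` (undefined features return mu)."""
    X = np.asarray(matrix, dtype=float)
    safe_sigma = np.where(state.zero_variance, 1.0, state.sigma)
    return X * safe_sigma + state.mu


# ---------------------------------------------------------------------------
# DWT filter bank
# ---------------------------------------------------------------------------

def _analysis_extend(x: np.ndarray, filt_len: int, padding: str) -> np.ndarray:
    """Extend the signal along its last axis for one analysis step."""
    p = filt_len - 1
    if padding == "zero":
        pad = [(0, 0)] * (x.ndim - 1) + [(p, p)]
        return np.pad(x, pad)
    if padding == "symmetric":
        # whole-point-free reflection with the edge sample repeated:
        # [x2 x1 | x1 x2 ... xn | xn xn-1]
        pad = [(0, 0)] * (x.ndim - 1) + [(p, p)]
        return np.pad(x, pad, mode="symmetric")
    if padding == "periodic":
        if x.shape[-1] % 2 == 1:  # odd length: repeat the last sample first
            x = np.concatenate([x, x[..., -1:]], axis=-1)
        L = filt_len
        return np.concatenate([x[..., -L:], x, x[..., :L]], axis=-1)
    raise ValueError(f"unknown padding mode {padding!r}")


def _conv_decimate(ext: np.ndarray, filt: np.ndarray, start: int, count: int) -> np.ndarray:
    """Valid convolution along the last axis, then take every other sample."""
    # convolution (filter flipped) via sliding windows: out[i] = sum_k ext[i+k] f[L-1-k]
    L = len(filt)
    win = np.lib.stride_tricks.sliding_window_view(ext, L, axis=-1)
    out = win @ filt[::-1]
    return out[..., start : start + 2 * count : 2]


def dwt_coeff_len(n: int, filter_length: int, padding: str) -> int:
    """Output length of one analysis step (per branch)."""
    if padding == "periodic":
        return (n + 1) // 2
    return (n + filter_length - 1) // 2


def dwt_single_level(signal: np.ndarray, spec: WaveletSpec) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: convolve with the low/high-pass pair, decimate by 2.

    Operates along the last axis, so a matrix of signals is transformed
    row-wise in one call.  Returns ``(approx, detail)``.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty signal")
    if n < spec.filter_length:
        raise ValueError(
            f"signal length {n} shorter than filter length {spec.filter_length}"
        )
    lo = np.asarray(spec.dec_lo)
    hi = np.asarray(spec.dec_hi)
    L = spec.filter_length
    ext = _analysis_extend(x, L, spec.padding)
    out_len = dwt_coeff_len(n, L, spec.padding)
    if spec.padding == "periodic":
        start = L // 2 + 1
    else:
        start = 1
    approx = _conv_decimate(ext, lo, start, out_len)
    detail = _conv_decimate(ext, hi, start, out_len)
    return approx, detail


@dataclass
class DWTDecomposition:
    """Approximation at the deepest level plus per-level details.

    ``details[0]`` is the level-1 (finest) detail.  ``original_length``
    stores the per-level signal lengths needed for exact reconstruction.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    level: int
    spec: WaveletSpec
    original_length: int
    _level_lengths: list[int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.level != len(self.details):
            raise ValueError("level must equal the number of detail vectors")
        if self._level_lengths is None:
            lengths = [self.original_length]
            for _ in range(self.level - 1):
                lengths.append(dwt_coeff_len(lengths[-1], self.spec.filter_length,
                                             self.spec.padding))
            self._level_lengths = lengths


def max_dwt_level(n: int, filter_length: int) -> int:
    """Deepest admissible level before the cascade degenerates."""
    if n < filter_length:
        return 0
    return int(np.floor(np.log2(n / (filter_length - 1))))


def dwt_multilevel(signal: np.ndarray, spec: WaveletSpec, level: int) -> DWTDecomposition:
    """Mallat cascade: decompose, then keep decomposing the approximation.

    Only the low-pass branch is re-analysed at each level (approximation
    cascade); the detail coefficients of every level are retained.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if level < 1:
        raise ValueError("level must be a positive integer")
    admissible = max_dwt_level(n, spec.filter_length)
    if level > admissible:
        raise ValueError(
            f"level {level} too deep for length {n} with a length-"
            f"{spec.filter_length} filter; maximum admissible level is {admissible}"
        )
    details: list[np.ndarray] = []
    approx = x
    for _ in range(level):
        approx, detail = dwt_single_level(approx, spec)
        details.append(detail)
    return DWTDecomposition(approx=approx, details=details, level=level, spec=spec,
                            original_length=n)


def _idwt_single(approx: np.ndarray, detail: np.ndarray, spec: WaveletSpec,
                 out_len: int) -> np.ndarray:
    """One synthesis step: upsample both branches, convolve, sum, trim."""
    if approx.shape != detail.shape:
        raise ValueError("approximation/detail length mismatch in synthesis")
    rl = np.asarray(spec.rec_lo)
    rh = np.asarray(spec.rec_hi)
    L = spec.filter_length
    m = approx.shape[-1]

    def upsample(c: np.ndarray, total: int) -> np.ndarray:
        up = np.zeros(c.shape[:-1] + (total,), dtype=float)
        up[..., ::2] = c
        return up

    if spec.padding == "periodic":
        ua = upsample(approx, 2 * m)
        ud = upsample(detail, 2 * m)
        exta = np.concatenate([ua[..., -L:], ua, ua[..., :L]], axis=-1)
        extd = np.concatenate([ud[..., -L:], ud, ud[..., :L]], axis=-1)
        win_a = np.lib.stride_tricks.sliding_window_view(exta, L, axis=-1)
        win_d = np.lib.stride_tricks.sliding_window_view(extd, L, axis=-1)
        y = win_a @ rl[::-1] + win_d @ rh[::-1]
        off = L // 2
        y = y[..., off : off + 2 * m]
        return y[..., :out_len]
    # zero / symmetric: full convolution of the upsampled branches, trim L-2
    ua = upsample(approx, 2 * m - 1)
    ud = upsample(detail, 2 * m - 1)
    pad = [(0, 0)] * (ua.ndim - 1) + [(L - 1, L - 1)]
    win_a = np.lib.stride_tricks.sliding_window_view(np.pad(ua, pad), L, axis=-1)
    win_d = np.lib.stride_tricks.sliding_window_view(np.pad(ud, pad), L, axis=-1)
    y = win_a @ rl[::-1] + win_d @ rh[::-1]
    start = L - 2
    return y[..., start : start + out_len]


def idwt(decomposition: DWTDecomposition) -> np.ndarray:
    """Invert the analysis cascade; returns a signal of the original length."""
    spec = decomposition.spec
    approx = decomposition.approx
    lengths = decomposition._level_lengths
    for lvl in range(decomposition.level - 1, -1, -1):
        detail = decomposition.details[lvl]
        approx = _idwt_single(approx, detail, spec, lengths[lvl])
    return approx


# ---------------------------------------------------------------------------
# Denoising front-end
# ---------------------------------------------------------------------------

def feature_length(n_samples: int, spec: WaveletSpec, level: int,
                   target_length: int | None = None) -> int:
    """Length of the feature vector `denoise_features` produces.

    The network input layer sizes itself from this value rather than from a
    hard-coded constant.  ``target_length`` (e.g. the 76-sample preset used
    for strict architectural replication) overrides the natural cascade
    length.
    """
    if target_length is not None:
        return int(target_length)
    length = n_samples
    for _ in range(level):
        length = dwt_coeff_len(length, spec.filter_length, spec.padding)
    return length


def denoise_features(signal: np.ndarray, spec: WaveletSpec, level: int,
                     target_length: int | None = None) -> np.ndarray:
    """Level-`level` approximation coefficients as the network input vector.

    The detail branches are dropped: the retained approximation is the
    low-pass, denoised representation of the standardized signal.  With
    ``target_length`` set, the vector is zero-padded or truncated to that
    length (architectural-replication preset).  Works on a single vector or
    row-wise on a matrix.
    """
    dec = dwt_multilevel(signal, spec, level)
    feats = dec.approx
    if target_length is not None:
        cur = feats.shape[-1]
        if cur > target_length:
            feats = feats[..., :target_length]
        elif cur < target_length:
            pad = [(0, 0)] * (feats.ndim - 1) + [(0, target_length - cur)]
            feats = np.pad(feats, pad)
    return feats
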