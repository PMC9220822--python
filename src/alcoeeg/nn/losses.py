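"""Binary cross-entropy on sigmoid probabilities."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7  # probability clip, keeps log and gradient finite


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean BCE; ``p`` are predicted probabilities, ``y`` binary labels."""
    p = np.clip(p.ravel(), _EPS, 1.0 - _EPS)
    y = y.ravel()
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def binary_cross_entropy_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the probabilities (same shape as ``p``)."""
    shape = p.shape
    pc = np.clip(p.ravel(), _EPS, 1.0 - _EPS)
    y = y.ravel()
    g = (pc - y) / (pc * (1.0 - pc)) / pc.shape[0]
    return g.reshape(shape)
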