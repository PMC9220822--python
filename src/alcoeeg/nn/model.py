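"""Sequential container: seeded builds, prediction, layer introspection."""

from __future__ import annotations

import json

import numpy as np

from .layers import Layer


class Sequential:
    """Ordered layer stack with deterministic seeded initialization."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...],
                 seed: int = 0, name: str = "model") -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.name = name
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.build(rng)

    # -- inference ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for start in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[start : start + batch_size], training=False))
        return np.concatenate(outs, axis=0)

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    # -- introspection / persistence ---------------------------------------

    def describe(self) -> list[tuple[str, tuple[int, ...], int]]:
        """Ordered (layer name, output shape, parameter count) rows."""
        rows = []
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
            rows.append((layer.name, tuple(shape), layer.n_params))
        return rows

    def summary(self) -> str:
        rows = self.describe()
        width = max([len(r[0]) for r in rows] + [10])
        lines = [f"{'layer':<{width}}  {'output shape':<16}  params"]
        for name, shape, n in rows:
            lines.append(f"{name:<{width}}  {str(shape):<16}  {n}")
        lines.append(f"total parameters: {self.n_params}")
        return "\n".join(lines)

    def save_weights(self, path: str) -> None:
        """JSON checkpoint (portable, text-only)."""
        payload = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "weights": [p.tolist() for p in self.params],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def load_weights(self, path: str) -> None:
        with open(path) as fh:
            payload = json.load(fh)
        self.set_weights([np.asarray(w) for w in payload["weights"]])
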