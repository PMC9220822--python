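"""Trainable layers with explicit forward/backward passes.

A deliberately small layer zoo — exactly what the EEG classifier needs:
1-D convolution (stride 1, 'same'/'valid'), max pooling, dense, dropout,
ReLU/sigmoid activations, an LSTM layer with full backpropagation through
time, and a bidirectional wrapper.  Data layout is channels-last:
sequence tensors are ``(batch, length, channels)``, dense tensors
``(batch, features)``.

Every layer exposes ``params``/``grads`` (parallel lists of arrays) for the
optimizer, ``forward(x, training)`` and ``backward(grad)``; sequence state
needed by the backward pass is cached on the instance during forward.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.normal(size=shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def build(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, input_shape: tuple[int, ...]) -> tuple[int, ...]:
        return input_shape

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, in_features: int, units: int, name: str = "dense") -> None:
        super().__init__()
        self.in_features = in_features
        self.units = units
        self.name = name

    def build(self, rng: np.random.Generator) -> None:
        W = glorot_uniform(rng, (self.in_features, self.units),
                           self.in_features, self.units)
        b = np.zeros(self.units)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ W.T

    def output_shape(self, input_shape):
        return (self.units,)


class Conv1D(Layer):
    """1-D convolution, stride 1, padding 'same' or 'valid'."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 padding: str = "same", name: str = "conv1d") -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown conv padding {padding!r}")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.padding = padding
        self.name = name

    def build(self, rng: np.random.Generator) -> None:
        k, cin, cout = self.kernel_size, self.in_channels, self.filters
        W = glorot_uniform(rng, (k, cin, cout), k * cin, k * cout)
        b = np.zeros(cout)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def _pad_amounts(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        k = self.kernel_size
        total = k - 1
        return total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        W, b = self.params
        k = self.kernel_size
        left, right = self._pad_amounts()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp_shape = xp.shape
        self._xp = xp
        L_out = xp.shape[1] - k + 1
        out = np.broadcast_to(b, (x.shape[0], L_out, self.filters)).copy()
        for j in range(k):
            out += xp[:, j : j + L_out, :] @ W[j]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        W, _ = self.params
        k = self.kernel_size
        xp = self._xp
        L_out = grad.shape[1]
        dxp = np.zeros(self._xp_shape)
        gflat = grad.reshape(-1, self.filters)
        for j in range(k):
            seg = xp[:, j : j + L_out, :]
            self.grads[0][j] = seg.reshape(-1, self.in_channels).T @ gflat
            dxp[:, j : j + L_out, :] += grad @ W[j].T
        self.grads[1][...] = grad.sum(axis=(0, 1))
        left, right = self._pad_amounts()
        if right == 0:
            return dxp[:, left:, :]
        return dxp[:, left:-right, :]

    def output_shape(self, input_shape):
        L, _ = input_shape
        if self.padding == "same":
            return (L, self.filters)
        return (L - self.kernel_size + 1, self.filters)


class MaxPool1D(Layer):
    def __init__(self, size: int = 2, stride: int = 2, name: str = "maxpool") -> None:
        super().__init__()
        if size != stride:
            raise NotImplementedError("only size == stride pooling is supported")
        self.size = size
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        L_out = L // self.size
        xt = x[:, : L_out * self.size, :].reshape(B, L_out, self.size, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return xt.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        L_out = grad.shape[1]
        dx = np.zeros((B, L_out, self.size, C))
        bi, li, ci = np.ogrid[:B, :L_out, :C]
        dx[bi, li, self._argmax, ci] = grad
        dx = dx.reshape(B, L_out * self.size, C)
        if L_out * self.size < L:
            dx = np.pad(dx, ((0, 0), (0, L - L_out * self.size), (0, 0)))
        return dx

    def output_shape(self, input_shape):
        L, C = input_shape
        return (L // self.size, C)


class ReLU(Layer):
    def __init__(self, name: str = "relu") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def __init__(self, name: str = "sigmoid") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._out = _sigmoid(x)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)


class Reshape(Layer):
    """(batch, features) -> (batch, timesteps, per_step) for the RNN stage."""

    def __init__(self, timesteps: int, features: int, name: str = "reshape") -> None:
        super().__init__()
        self.timesteps = timesteps
        self.features = features
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.timesteps * self.features:
            raise ValueError(
                f"cannot reshape {x.shape[1]} features into "
                f"{self.timesteps}x{self.features}"
            )
        return x.reshape(x.shape[0], self.timesteps, self.features)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(grad.shape[0], -1)

    def output_shape(self, input_shape):
        return (self.timesteps, self.features)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, name: str = "dropout") -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name
        self.rng: np.random.Generator | None = None

    def build(self, rng: np.random.Generator) -> None:
        self.rng = np.random.default_rng(rng.integers(2**31))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class LSTM(Layer):
    """LSTM layer over (batch, T, F) with full backpropagation through time.

    Gate pre-activations are computed with fused kernels
    ``z = x_t @ U + h_{t-1} @ W + b`` and split in gate order
    (forget, input, candidate, output):

        f = sigma(z_f),  i = sigma(z_i),  a = tanh(z_a),  o = sigma(z_o)
        c_t = c_{t-1} * f + i * a
        h_t = o * tanh(c_t)

    Initial states are zero.  ``return_sequences`` selects per-step hidden
    states (T x H) versus the final hidden state only.
    """

    def __init__(self, input_size: int, units: int, return_sequences: bool = False,
                 name: str = "lstm") -> None:
        super().__init__()
        self.input_size = input_size
        self.units = units
        self.return_sequences = return_sequences
        self.name = name

    def build(self, rng: np.random.Generator) -> None:
        F, H = self.input_size, self.units
        U = glorot_uniform(rng, (F, 4 * H), F, 4 * H)
        W = np.concatenate([orthogonal(rng, (H, H)) for _ in range(4)], axis=1)
        b = np.zeros(4 * H)
        b[:H] = 1.0  # forget-gate bias 1: remember by default, standard practice
        self.params = [U, W, b]
        self.grads = [np.zeros_like(U), np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        U, W, b = self.params
        B, T, F = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        x_proj = x.reshape(B * T, F) @ U  # input contribution for all steps
        x_proj = x_proj.reshape(B, T, 4 * H)
        for t in range(T):
            z = x_proj[:, t, :] + h @ W + b
            f = _sigmoid(z[:, :H])
            i = _sigmoid(z[:, H : 2 * H])
            a = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = c_prev * f + i * a
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            self._cache.append((h_prev, c_prev, f, i, a, o, tanh_c))
            hs[:, t, :] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        U, W, b = self.params
        B, T, F = self._x.shape
        H = self.units
        if self.return_sequences:
            dhs = grad
        else:
            dhs = np.zeros((B, T, H))
            dhs[:, -1, :] = grad
        dU = np.zeros_like(U)
        dW = np.zeros_like(W)
        db = np.zeros_like(b)
        dx = np.empty((B, T, F))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, f, i, a, o, tanh_c = self._cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            df = dc * c_prev
            di = dc * a
            da = dc * i
            dz = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    da * (1.0 - a**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            x_t = self._x[:, t, :]
            dU += x_t.T @ dz
            dW += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ U.T
            dh_next = dz @ W.T
            dc_next = dc * f
        self.grads[0][...] = dU
        self.grads[1][...] = dW
        self.grads[2][...] = db
        return dx

    def output_shape(self, input_shape):
        T, _ = input_shape
        return (T, self.units) if self.return_sequences else (self.units,)


class Bidirectional(Layer):
    """Two independent LSTMs over opposite time directions, concatenated.

    With ``return_sequences`` the outputs are aligned per original time step;
    otherwise the final forward state (t = T) is concatenated with the final
    backward state (which summarizes the sequence seen from t = T down to 1).
    """

    def __init__(self, forward_layer: LSTM, backward_layer: LSTM,
                 name: str = "bilstm") -> None:
        super().__init__()
        if forward_layer.return_sequences != backward_layer.return_sequences:
            raise ValueError("forward/backward return_sequences must match")
        self.fw = forward_layer
        self.bw = backward_layer
        self.return_sequences = forward_layer.return_sequences
        self.name = name

    def build(self, rng: np.random.Generator) -> None:
        self.fw.build(rng)
        self.bw.build(rng)
        self.params = self.fw.params + self.bw.params
        self.grads = self.fw.grads + self.bw.grads

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out_f = self.fw.forward(x, training)
        out_b = self.bw.forward(x[:, ::-1, :], training)
        if self.return_sequences:
            out_b = out_b[:, ::-1, :]
            return np.concatenate([out_f, out_b], axis=2)
        return np.concatenate([out_f, out_b], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        H = self.fw.units
        if self.return_sequences:
            gf = grad[..., :H]
            gb = grad[..., H:][:, ::-1, :]
        else:
            gf = grad[:, :H]
            gb = grad[:, H:]
        dx_f = self.fw.backward(gf)
        dx_b = self.bw.backward(gb)[:, ::-1, :]
        return dx_f + dx_b

    def output_shape(self, input_shape):
        T, _ = input_shape
        H2 = self.fw.units + self.bw.units
        return (T, H2) if self.return_sequences else (H2,)
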