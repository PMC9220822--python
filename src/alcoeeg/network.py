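"""Reference LSTM kernels and the CNN-Bi-LSTM architecture builder.

The LSTM cell here is a direct, per-gate transcription of the standard
gate equations

    f_t = sigma(W_f h_{t-1} + U_f x_t + b_f)
    i_t = sigma(W_i h_{t-1} + U_i x_t + b_i)
    a_t = tanh (W_a h_{t-1} + U_a x_t + b_a)
    o_t = sigma(W_o h_{t-1} + U_o x_t + b_o)
    c_t = c_{t-1} * f_t + i_t * a_t
    h_t = o_t * tanh(c_t)

with sigma the logistic function and ``*`` the Hadamard product.  It is a
*reference numerical kernel*: tests verify that the vectorized training
layer (``alcoeeg.nn.LSTM``, an independent fused-matrix implementation)
reproduces it step for step, which is the bridge establishing that the
trained models implement these equations.

``build_model`` assembles the proposed DWT-CNN-Bi-LSTM classifier and the
four comparison architectures (CNN, LSTM, Bi-LSTM, CNN+Bi-LSTM) from a
declarative :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import numpy as np

from . import nn

ARCHITECTURES = ("proposed", "cnn", "lstm", "bilstm", "cnn_bilstm")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# Reference cell
# ---------------------------------------------------------------------------

@dataclass
class LSTMWeights:
    """Per-gate weights: W_* act on h_{t-1} (hidden x hidden), U_* on x_t
    (hidden x input), b_* are bias vectors of length hidden."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_a: np.ndarray
    W_o: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_a: np.ndarray
    U_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_a: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, F = self.hidden_size, self.input_size
        for name in ("W_f", "W_i", "W_a", "W_o"):
            if getattr(self, name).shape != (H, H):
                raise ValueError(f"{name} must be hidden x hidden ({H}, {H})")
        for name in ("U_f", "U_i", "U_a", "U_o"):
            if getattr(self, name).shape != (H, F):
                raise ValueError(f"{name} must be hidden x input ({H}, {F})")
        for name in ("b_f", "b_i", "b_a", "b_o"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have length hidden ({H})")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.U_f.shape[1]

    @classmethod
    def zeros(cls, hidden_size: int, input_size: int) -> "LSTMWeights":
        H, F = hidden_size, input_size
        z = np.zeros
        return cls(z((H, H)), z((H, H)), z((H, H)), z((H, H)),
                   z((H, F)), z((H, F)), z((H, F)), z((H, F)),
                   z(H), z(H), z(H), z(H))

    @classmethod
    def random(cls, hidden_size: int, input_size: int,
               rng: np.random.Generator, scale: float = 0.5) -> "LSTMWeights":
        H, F = hidden_size, input_size
        r = lambda *shape: rng.normal(scale=scale, size=shape)
        return cls(r(H, H), r(H, H), r(H, H), r(H, H),
                   r(H, F), r(H, F), r(H, F), r(H, F),
                   r(H), r(H), r(H), r(H))

    def to_fused(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pack into the (U, W, b) fused layout of ``alcoeeg.nn.LSTM``
        (gate order forget, input, candidate, output; kernels transposed
        to act on row vectors)."""
        U = np.concatenate([self.U_f.T, self.U_i.T, self.U_a.T, self.U_o.T], axis=1)
        W = np.concatenate([self.W_f.T, self.W_i.T, self.W_a.T, self.W_o.T], axis=1)
        b = np.concatenate([self.b_f, self.b_i, self.b_a, self.b_o])
        return U, W, b


@dataclass
class LSTMState:
    """Hidden state h(t) and cell state c(t)."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_size), c=np.zeros(hidden_size))


def lstm_cell_step(x_t: np.ndarray, prev: LSTMState, w: LSTMWeights) -> LSTMState:
    """One LSTM time step, evaluated gate by gate from the equations."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (w.input_size,):
        raise ValueError(f"x_t must have shape ({w.input_size},), got {x_t.shape}")
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(prev.h))
            and np.all(np.isfinite(prev.c))):
        raise ValueError("non-finite inputs to LSTM cell")
    f = _sigmoid(w.W_f @ prev.h + w.U_f @ x_t + w.b_f)
    i = _sigmoid(w.W_i @ prev.h + w.U_i @ x_t + w.b_i)
    a = np.tanh(w.W_a @ prev.h + w.U_a @ x_t + w.b_a)
    o = _sigmoid(w.W_o @ prev.h + w.U_o @ x_t + w.b_o)
    c = prev.c * f + i * a
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def lstm_forward(sequence: np.ndarray, w: LSTMWeights) -> np.ndarray:
    """Run the reference cell over a T x F sequence; returns T x H hidden states."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    state = LSTMState.zeros(w.hidden_size)
    out = np.empty((seq.shape[0], w.hidden_size))
    for t in range(seq.shape[0]):
        state = lstm_cell_step(seq[t], state, w)
        out[t] = state.h
    return out


def bilstm_forward(sequence: np.ndarray, fw: LSTMWeights, bw: LSTMWeights,
                   merge: str = "concat") -> np.ndarray:
    """Two independent LSTMs over opposite directions, merged per step.

    The forward pass reads t = 1..T with ``fw``; the backward pass reads the
    reversed sequence with ``bw`` and its outputs are re-aligned to the
    original time axis.  Returns a T x 2H matrix (forward block first).
    """
    if merge != "concat":
        raise ValueError("only 'concat' merging is supported")
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    if fw.input_size != bw.input_size:
        raise ValueError("forward/backward input sizes differ")
    out_f = lstm_forward(seq, fw)
    out_b = lstm_forward(seq[::-1], bw)[::-1]
    return np.concatenate([out_f, out_b], axis=1)


# ---------------------------------------------------------------------------
# Architecture configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameter bundle for the classifier and its baselines.

    Defaults reproduce the published architecture: four 1-D convolutions
    (64, 64, 128, 128 filters, kernel 3, stride 1) with max pooling
    (window 2, stride 2) after the first and fourth, a 256-unit dense
    mapping + dropout reshaped into a (timesteps, features) sequence for two
    stacked 64-unit Bi-LSTMs, a 256/128/64 dense head with dropout after
    each layer, and a single sigmoid output unit; Adam with learning rate
    0.001, 100 epochs, batch size 200.
    """

    input_length: int = 76
    input_channels: int = 1  # 1 = channel-as-sample mode; 64 = multichannel trials
    conv_stack: tuple = ((64, 3, 1), (64, 3, 1), (128, 3, 1), (128, 3, 1))
    pool: tuple[int, int] = (2, 2)
    pre_rnn_dense: int = 256
    bilstm_units: tuple[int, int] = (64, 64)
    head_dense: tuple[int, ...] = (256, 128, 64)
    dropout_rate: float = 0.5
    rnn_reshape: tuple[int, int] = (4, 64)
    padding_mode: str = "same"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_stack) != 4:
            raise ValueError("conv_stack must list four convolution layers")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")
        t, f = self.rnn_reshape
        if t * f != self.pre_rnn_dense:
            raise ValueError(
                f"rnn_reshape {self.rnn_reshape} incompatible with the "
                f"{self.pre_rnn_dense}-unit dense layer (timesteps x features "
                "must equal its width)"
            )
        for s in (c[2] for c in self.conv_stack):
            if s != 1:
                raise ValueError("only stride-1 convolutions are supported")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_stack"] = tuple(tuple(c) for c in d["conv_stack"])
        for key in ("pool", "bilstm_units", "head_dense", "rnn_reshape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def scaled_config(input_length: int, seed: int = 0, epochs: int = 15,
                  batch_size: int = 64) -> ModelConfig:
    """Desk-scale training schedule (same architecture, shorter run)."""
    return ModelConfig(input_length=input_length, epochs=epochs,
                       batch_size=batch_size, seed=seed)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _conv_backbone(config: ModelConfig) -> tuple[list[nn.Layer], tuple[int, int]]:
    layers: list[nn.Layer] = []
    shape = (config.input_length, config.input_channels)
    pool_size, pool_stride = config.pool
    pool_after = (0, 3)  # after conv1 and conv4
    in_ch = config.input_channels
    for idx, (filters, kernel, _stride) in enumerate(config.conv_stack):
        conv = nn.Conv1D(in_ch, filters, kernel, padding=config.padding_mode,
                         name=f"conv{idx + 1}")
        layers.append(conv)
        layers.append(nn.ReLU(name=f"relu{idx + 1}"))
        shape = conv.output_shape(shape)
        if idx in pool_after:
            pool = nn.MaxPool1D(pool_size, pool_stride, name=f"maxpool{1 + (idx > 0)}")
            layers.append(pool)
            shape = pool.output_shape(shape)
        in_ch = filters
    return layers, shape


def _dense_head(config: ModelConfig, in_features: int) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    width = in_features
    for idx, units in enumerate(config.head_dense):
        layers.append(nn.Dense(width, units, name=f"dense_head{idx + 1}"))
        layers.append(nn.ReLU(name=f"relu_head{idx + 1}"))
        layers.append(nn.Dropout(config.dropout_rate, name=f"dropout_head{idx + 1}"))
        width = units
    layers.append(nn.Dense(width, 1, name="output"))
    layers.append(nn.Sigmoid(name="sigmoid"))
    return layers


def _bilstm(input_size: int, units: int, return_sequences: bool,
            name: str) -> nn.Bidirectional:
    return nn.Bidirectional(
        nn.LSTM(input_size, units, return_sequences, name=f"{name}_fw"),
        nn.LSTM(input_size, units, return_sequences, name=f"{name}_bw"),
        name=name,
    )


def build_model(config: ModelConfig, architecture: str = "proposed") -> nn.Sequential:
    """Assemble an untrained model for one of the comparison architectures.

    ``proposed`` is the full conv -> pool -> dense(256) -> Bi-LSTM x2 ->
    dense head stack operating on DWT feature vectors; ``cnn_bilstm`` is the
    identical network applied to raw standardized input (no DWT front-end,
    so only ``input_length`` differs); ``cnn`` keeps the convolutional
    backbone and dense head only; ``lstm``/``bilstm`` treat the input vector
    as a length-T sequence of scalars feeding recurrent units directly.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}"
        )
    L = config.input_length
    input_shape = (L, config.input_channels)
    layers: list[nn.Layer]

    if architecture in ("proposed", "cnn_bilstm"):
        layers, shape = _conv_backbone(config)
        flat = int(np.prod(shape))
        layers.append(nn.Flatten())
        layers.append(nn.Dense(flat, config.pre_rnn_dense, name="dense_map"))
        layers.append(nn.ReLU(name="relu_map"))
        layers.append(nn.Dropout(config.dropout_rate, name="dropout_map"))
        t, f = config.rnn_reshape
        layers.append(nn.Reshape(t, f))
        u1, u2 = config.bilstm_units
        layers.append(_bilstm(f, u1, True, "bilstm1"))
        layers.append(_bilstm(2 * u1, u2, False, "bilstm2"))
        layers.extend(_dense_head(config, 2 * u2))
    elif architecture == "cnn":
        layers, shape = _conv_backbone(config)
        layers.append(nn.Flatten())
        layers.extend(_dense_head(config, int(np.prod(shape))))
    elif architecture == "lstm":
        u1 = config.bilstm_units[0]
        layers = [nn.LSTM(config.input_channels, u1, return_sequences=False,
                          name="lstm")]
        layers.extend(_dense_head(config, u1))
    else:  # bilstm
        u1 = config.bilstm_units[0]
        layers = [_bilstm(config.input_channels, u1, False, "bilstm")]
        layers.extend(_dense_head(config, 2 * u1))

    return nn.Sequential(layers, input_shape=input_shape, seed=config.seed,
                         name=architecture)


def describe_model(model: nn.Sequential) -> list[tuple[str, tuple[int, ...], int]]:
    """Ordered (layer name, output shape, parameter count) table."""
    return model.describe()
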