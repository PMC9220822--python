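"""Step the reference LSTM cell by hand and check it against the training layer.

The cell evaluates the gate equations one by one (forget, input, candidate,
output); the training layer computes the same thing with fused matrices.
Their agreement is what certifies that trained models implement the
equations.
"""

import numpy as np

from alcoeeg import nn
from alcoeeg.network import LSTMState, LSTMWeights, lstm_cell_step, lstm_forward

# scalar walk-through: all recurrent weights 0, input weights 1, x = 0.5
w = LSTMWeights.zeros(1, 1)
for gate in ("U_f", "U_i", "U_a", "U_o"):
    getattr(w, gate)[...] = 1.0
state = lstm_cell_step(np.array([0.5]), LSTMState.zeros(1), w)
print(f"gates sigma(0.5) = {1 / (1 + np.exp(-0.5)):.5f}, "
      f"candidate tanh(0.5) = {np.tanh(0.5):.5f}")
print(f"cell state c = {state.c[0]:.6f}, hidden state h = {state.h[0]:.6f}")

# random weights: reference loop vs vectorized layer over 20 steps
rng = np.random.default_rng(42)
wref = LSTMWeights.random(hidden_size=8, input_size=5, rng=rng)
layer = nn.LSTM(5, 8, return_sequences=True)
layer.build(np.random.default_rng(0))
U, W, b = wref.to_fused()
layer.params[0][...] = U
layer.params[1][...] = W
layer.params[2][...] = b
seq = rng.normal(size=(20, 5))
dev = np.max(np.abs(lstm_forward(seq, wref) - layer.forward(seq[None])[0]))
print(f"reference vs training layer, 20 steps: max deviation {dev:.2e}")
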