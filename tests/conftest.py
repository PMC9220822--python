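"""Shared fixtures: toy SMNI files and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from alcoeeg import synthgen

# 3 channels x 4 samples; voltages chosen so every cell is distinct.
SMNI_TOY = """\
# a0000001.rd
# 1 trials, 3 chans, 4 samples
# 3.906000 msecs uV
# S1 obj , trial 0
# FP1 chan 0
0 FP1 0 1.5
0 FP1 1 -2.25
0 FP1 2 3.75
0 FP1 3 0.125
# FP2 chan 1
0 FP2 0 4.5
0 FP2 1 5.25
0 FP2 2 -6.625
0 FP2 3 7.0
# F7 chan 2
0 F7 0 -8.5
0 F7 1 9.125
0 F7 2 10.0
0 F7 3 -11.375
"""

SMNI_TOY_MATRIX = np.array([
    [1.5, -2.25, 3.75, 0.125],
    [4.5, 5.25, -6.625, 7.0],
    [-8.5, 9.125, 10.0, -11.375],
])


@pytest.fixture()
def smni_toy_file(tmp_path):
    path = tmp_path / "a0000001.rd"
    path.write_text(SMNI_TOY)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """Two-class synthetic dataset, small enough for fast io/split tests."""
    config = synthgen.SynthConfig(n_subjects_per_class=3, trials_per_subject=2,
                                  n_channels=4, n_samples=64, seed=7)
    return synthgen.generate(config)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separated two-class dataset for quick training tests."""
    config = synthgen.SynthConfig(n_subjects_per_class=3, trials_per_subject=4,
                                  n_channels=6, n_samples=256, effect=3.0,
                                  seed=13)
    return synthgen.generate(config)
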