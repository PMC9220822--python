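"""Read an SMNI-dialect trial file and round-trip a dataset through HDF5/CSV.

Writes a toy 3-channel trial file in the UCI plain-text dialect, parses it,
and shows the lossless container round-trip.  Point `read_smni_directory`
at a directory of real co2a…/co2c… files to build a full dataset the same
way.
"""

import tempfile
from pathlib import Path

import numpy as np

from alcoeeg import eeg_io

TOY = """\
# co2a0000364.rd
# 1 trials, 3 chans, 4 samples
# 3.906000 msecs uV
# S1 obj , trial 0
# FP1 chan 0
0 FP1 0 -8.921
0 FP1 1 -8.433
0 FP1 2 -2.574
0 FP1 3 5.239
# FP2 chan 1
0 FP2 0 0.834
0 FP2 1 3.276
0 FP2 2 5.717
0 FP2 3 7.182
# F7 chan 2
0 F7 0 -1.953
0 F7 1 -4.395
0 F7 2 -5.859
0 F7 3 -4.883
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "co2a0000364.rd"
    path.write_text(TOY)
    trial = eeg_io.read_smni_trial(path)
    print(f"subject {trial.subject_id}: label={trial.label} "
          f"({'alcoholic' if trial.label else 'control'}), "
          f"condition '{trial.condition}'")
    print(f"channels {trial.channel_names}, data shape {trial.data.shape}")
    print(f"data[1][2] = {trial.data[1][2]} (FP2, sample 2)")

    dataset = eeg_io.EEGDataset([trial], provenance=str(path))
    h5 = Path(tmp) / "toy.h5"
    eeg_io.write_dataset(dataset, h5, format="hdf5")
    back = eeg_io.read_dataset(h5, format="hdf5")
    err = np.max(np.abs(back.to_array() - dataset.to_array()))
    print(f"HDF5 round-trip max voltage error: {err:.1e}")
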