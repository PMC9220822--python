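"""Readers and writers for EEG trial data.

Supports the UCI SMNI plain-text trial dialect (one file per trial,
``#``-prefixed headers, whitespace-delimited ``trial channel sample value``
rows, optionally gzip-compressed) plus two package-internal containers: a
long-format CSV and an HDF5 file with a 3-D voltage cube.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = 1  # alcoholic
NEGATIVE = 0  # control

#: Default mapping from a subject-id letter code to the class label.
DEFAULT_LABEL_MAP = {"a": POSITIVE, "c": NEGATIVE}

# UCI subject ids look like co2a0000364 / co3c0000392: the letter after the
# co<digit> prefix encodes the group.  Toy/synthetic ids may simply start
# with the letter.
_UCI_ID_RE = re.compile(r"^co\d*([ac])", re.IGNORECASE)


class SMNIParseError(ValueError):
    """Malformed SMNI file content (names the offending line)."""


class IncompleteTrialError(ValueError):
    """A channel is missing samples."""


class LabelingError(ValueError):
    """Subject identifier does not map to a class label."""


@dataclass
class EEGTrial:
    """One recording epoch: channels x samples voltages plus metadata."""

    subject_id: str
    label: int
    data: np.ndarray  # n_channels x n_samples, microvolts
    channel_names: list[str]
    condition: str = ""
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE} or {NEGATIVE}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def reorder_channels(self, names: Sequence[str]) -> "EEGTrial":
        """Return a copy with rows permuted into the given channel order."""
        index = {name: i for i, name in enumerate(self.channel_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ValueError(f"trial lacks channels {missing}")
        rows = [index[n] for n in names]
        return EEGTrial(self.subject_id, self.label, self.data[rows],
                        list(names), self.condition, self.sampling_rate)


@dataclass
class EEGDataset:
    """Ordered trial collection sharing sampling rate and channel order."""

    trials: list[EEGTrial]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trials:
            rate = self.trials[0].sampling_rate
            names = self.trials[0].channel_names
            for t in self.trials:
                if t.sampling_rate != rate:
                    raise ValueError("trials have mixed sampling rates")
                if t.channel_names != names:
                    raise ValueError("trials have mismatched channel orderings")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.trials]

    @property
    def channel_names(self) -> list[str]:
        return self.trials[0].channel_names if self.trials else []

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate if self.trials else 0.0

    def to_array(self) -> np.ndarray:
        """3-D cube (n_trials, n_channels, n_samples)."""
        return np.stack([t.data for t in self.trials])

    def voltage_checksum(self) -> str:
        """SHA-256 over the voltage cube rounded to 9 decimals."""
        cube = np.round(self.to_array(), 9)
        return hashlib.sha256(cube.tobytes()).hexdigest()

    def subset(self, indices: Iterable[int], provenance: str | None = None) -> "EEGDataset":
        idx = list(indices)
        return EEGDataset([self.trials[i] for i in idx],
                          provenance=provenance or self.provenance)


def default_label_fn(subject_id: str,
                     label_map: dict[str, int] | None = None) -> int:
    """Map a subject identifier to its class label.

    The UCI convention embeds the group letter after the ``co<digit>``
    prefix (``co2a...`` alcoholic, ``co2c...`` control); identifiers without
    that prefix are classified by their first letter.  The letter-to-label
    map is configurable.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    m = _UCI_ID_RE.match(subject_id)
    key = m.group(1).lower() if m else subject_id[:1].lower()
    if key not in label_map:
        raise LabelingError(
            f"cannot infer label from subject id {subject_id!r} "
            f"(letter {key!r} not in label map {label_map})"
        )
    return label_map[key]


# ---------------------------------------------------------------------------
# SMNI reader
# ---------------------------------------------------------------------------

def read_smni_trial(path: str | os.PathLike, gzip_ok: bool = True,
                    label_map: dict[str, int] | None = None,
                    default_label: int | None = None,
                    sampling_rate: float = 256.0) -> EEGTrial:
    """Parse one SMNI trial file into an :class:`EEGTrial`.

    Header lines start with ``#``; the first carries the subject/file id,
    later ones the stimulus condition (``# S1 obj , trial 0``) and channel
    markers (``# FP1 chan 0``).  Data rows have exactly four whitespace-
    separated fields: trial index, channel name, sample index, voltage.
    Channel order follows header order; rows are placed by their sample
    index, so physical row order within a channel is irrelevant.

    The label comes from the subject id via :func:`default_label_fn`
    (configurable ``label_map``); ``default_label`` overrides when the id is
    unmappable.
    """
    path = os.fspath(path)
    opener = gzip.open if (gzip_ok and path.endswith(".gz")) else open
    with opener(path, "rt") as fh:
        lines = fh.read().splitlines()

    subject_id = ""
    condition = ""
    channel_order: list[str] = []
    samples: dict[str, dict[int, float]] = {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if not subject_id and body:
                subject_id = body.split()[0]
                subject_id = re.sub(r"\.(rd|gz)\b.*$", "", subject_id)
                continue
            mchan = re.match(r"^(\S+)\s+chan\s+(\d+)\s*$", body)
            if mchan:
                name = mchan.group(1)
                if name not in samples:
                    channel_order.append(name)
                    samples[name] = {}
                continue
            mtrial = re.match(r"^(.*?)\s*,\s*trial\s+\d+\s*$", body)
            if mtrial:
                condition = mtrial.group(1).strip()
            continue
        fields = line.split()
        if len(fields) != 4:
            raise SMNIParseError(
                f"{path}:{lineno}: expected 4 fields "
                f"(trial channel sample value), got {len(fields)}"
            )
        _, chan, sample_s, value_s = fields
        try:
            sample = int(sample_s)
            value = float(value_s)
        except ValueError as exc:
            raise SMNIParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
        if chan not in samples:
            channel_order.append(chan)
            samples[chan] = {}
        if sample < 0:
            raise SMNIParseError(f"{path}:{lineno}: negative sample index")
        samples[chan][sample] = value

    if not channel_order:
        raise SMNIParseError(f"{path}: no channel data found")

    n_samples = max(max(s) for s in samples.values() if s) + 1
    data = np.empty((len(channel_order), n_samples))
    for row, name in enumerate(channel_order):
        chan_samples = samples[name]
        if len(chan_samples) != n_samples:
            missing = sorted(set(range(n_samples)) - set(chan_samples))
            raise IncompleteTrialError(
                f"{path}: channel {name!r} has {len(chan_samples)} of "
                f"{n_samples} samples (first missing index: {missing[0]})"
            )
        for idx, value in chan_samples.items():
            data[row, idx] = value

    try:
        label = default_label_fn(subject_id, label_map)
    except LabelingError:
        if default_label is None:
            raise
        label = default_label

    return EEGTrial(subject_id=subject_id, label=label, data=data,
                    channel_names=channel_order, condition=condition,
                    sampling_rate=sampling_rate)


def is_erroneous(trial: EEGTrial) -> bool:
    """Trials flagged as artifact-rejected carry 'err' in their condition."""
    return "err" in trial.condition.lower().split()


def read_smni_directory(directory: str | os.PathLike, gzip_ok: bool = True,
                        keep_err: bool = False,
                        label_map: dict[str, int] | None = None) -> EEGDataset:
    """Read every SMNI trial file in a directory into one dataset.

    Trials whose condition header marks them erroneous are skipped with a
    logged warning unless ``keep_err``.  Channel ordering is re-indexed to
    the first file's header order.
    """
    directory = os.fspath(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".") and os.path.isfile(os.path.join(directory, f))
    )
    trials: list[EEGTrial] = []
    reference_order: list[str] | None = None
    for p in paths:
        trial = read_smni_trial(p, gzip_ok=gzip_ok, label_map=label_map)
        if is_erroneous(trial) and not keep_err:
            logger.warning("skipping erroneous trial %s (%s)", p, trial.condition)
            continue
        if reference_order is None:
            reference_order = trial.channel_names
        elif trial.channel_names != reference_order:
            trial = trial.reorder_channels(reference_order)
        trials.append(trial)
    return EEGDataset(trials, provenance=directory)


# ---------------------------------------------------------------------------
# CSV / HDF5 containers
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["trial_id", "subject_id", "label", "condition", "channel",
               "sample", "value"]


def write_dataset(dataset: EEGDataset, path: str | os.PathLike,
                  format: str = "hdf5") -> str:
    """Persist a dataset as long-format CSV or an HDF5 cube.

    CSV stores one row per (trial, channel, sample) with 12 significant
    digits; HDF5 is lossless.
    """
    path = os.fspath(path)
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    if format == "csv":
        frames = []
        for tid, trial in enumerate(dataset.trials):
            n_ch, n_s = trial.data.shape
            frames.append(pd.DataFrame({
                "trial_id": tid,
                "subject_id": trial.subject_id,
                "label": trial.label,
                "condition": trial.condition,
                "channel": np.repeat(trial.channel_names, n_s),
                "sample": np.tile(np.arange(n_s), n_ch),
                "value": trial.data.ravel(),
            }))
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(path, index=False, float_format="%.12g")
        return path
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=dataset.to_array())
            fh.create_dataset("labels", data=dataset.labels)
            meta = fh.create_group("meta")
            str_dt = h5py.string_dtype()
            meta.create_dataset("subject_ids", data=dataset.subject_ids, dtype=str_dt)
            meta.create_dataset("conditions",
                                data=[t.condition for t in dataset.trials],
                                dtype=str_dt)
            meta.create_dataset("channel_names", data=dataset.channel_names,
                                dtype=str_dt)
            meta.attrs["sampling_rate"] = dataset.sampling_rate
            meta.attrs["provenance"] = dataset.provenance
        return path
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'hdf5'")


def read_dataset(path: str | os.PathLike, format: str = "hdf5") -> EEGDataset:
    """Inverse of :func:`write_dataset`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing columns {sorted(missing)}")
        trials = []
        for tid, group in df.groupby("trial_id", sort=True):
            channels = list(dict.fromkeys(group["channel"]))
            pivot = group.pivot(index="channel", columns="sample", values="value")
            pivot = pivot.loc[channels]
            trials.append(EEGTrial(
                subject_id=str(group["subject_id"].iloc[0]),
                label=int(group["label"].iloc[0]),
                data=pivot.to_numpy(),
                channel_names=[str(c) for c in channels],
                condition=str(group["condition"].iloc[0])
                if not pd.isna(group["condition"].iloc[0]) else "",
            ))
        return EEGDataset(trials, provenance=path)
    if format == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            cube = fh["data"][...]
            labels = fh["labels"][...]
            meta = fh["meta"]
            subject_ids = [s.decode() for s in meta["subject_ids"][...]]
            conditions = [s.decode() for s in meta["conditions"][...]]
            channel_names = [s.decode() for s in meta["channel_names"][...]]
            rate = float(meta.attrs["sampling_rate"])
            provenance = str(meta.attrs.get("provenance", path))
        trials = [
            EEGTrial(subject_id=subject_ids[i], label=int(labels[i]),
                     data=cube[i], channel_names=list(channel_names),
                     condition=conditions[i], sampling_rate=rate)
            for i in range(cube.shape[0])
        ]
        return EEGDataset(trials, provenance=provenance)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'hdf5'")
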