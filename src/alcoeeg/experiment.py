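"""Training, evaluation and the multi-architecture comparison harness.

Ties the pieces together: split a dataset (trial-wise or subject-wise,
stratified, seeded), turn trials into per-channel training samples,
standardize on the training split only, apply the DWT denoising front-end,
train with Adam/binary cross-entropy while logging per-epoch curves, and
score with confusion-matrix metrics

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the zero-denominator convention that the affected metric is 0 (and
flagged in the report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn, preprocess
from .eeg_io import EEGDataset
from .network import ARCHITECTURES, ModelConfig, build_model


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """How to carve train/test sets.

    ``trial_wise`` stratifies by class over trials; ``subject_wise``
    partitions whole subjects so none contributes to both sides (the
    leakage-safe protocol recommended for EEG).
    """

    mode: str = "trial_wise"
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("trial_wise", "subject_wise"):
            raise ValueError("mode must be 'trial_wise' or 'subject_wise'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def make_split(dataset: EEGDataset, plan: SplitPlan) -> tuple[EEGDataset, EEGDataset]:
    """Deterministic stratified split; both sides must contain both classes."""
    rng = np.random.default_rng(plan.seed)
    labels = dataset.labels
    if plan.mode == "subject_wise":
        subj_label: dict[str, int] = {}
        for t in dataset.trials:
            subj_label.setdefault(t.subject_id, t.label)
        train_subjects: set[str] = set()
        for cls in np.unique(labels):
            subjects = sorted(s for s, l in subj_label.items() if l == cls)
            if len(subjects) < 2:
                raise ValueError(
                    f"subject-wise split needs >= 2 subjects per class; "
                    f"class {cls} has {len(subjects)}"
                )
            rng.shuffle(subjects)
            n_train = max(1, min(len(subjects) - 1,
                                 round(plan.train_fraction * len(subjects))))
            train_subjects.update(subjects[:n_train])
        train_idx = [i for i, t in enumerate(dataset.trials)
                     if t.subject_id in train_subjects]
        test_idx = [i for i, t in enumerate(dataset.trials)
                    if t.subject_id not in train_subjects]
    else:
        train_idx, test_idx = [], []
        classes = np.unique(labels) if plan.stratified else [None]
        for cls in classes:
            idx = (np.flatnonzero(labels == cls) if cls is not None
                   else np.arange(len(labels)))
            if len(idx) < 2:
                raise ValueError("need >= 2 trials per class for a trial-wise split")
            idx = idx.copy()
            rng.shuffle(idx)
            n_train = max(1, min(len(idx) - 1, round(plan.train_fraction * len(idx))))
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
        train_idx.sort()
        test_idx.sort()

    train = dataset.subset(train_idx)
    test = dataset.subset(test_idx)
    for side, name in ((train, "train"), (test, "test")):
        if len(np.unique(side.labels)) < 2:
            raise ValueError(f"{name} side would be single-class; adjust the plan")
    return train, test


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def dataset_to_samples(dataset: EEGDataset, mode: str = "channels"
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a dataset into (X, y, trial_index) training samples.

    ``channels`` mode (default): every channel of every trial is one sample
    of length n_samples, inheriting the trial label — matching a
    one-dimensional (length x 1) network input.  ``multichannel`` mode keeps
    whole trials as (n_samples x n_channels) samples.
    """
    cube = dataset.to_array()  # trials x channels x samples
    labels = dataset.labels
    if mode == "channels":
        n_t, n_c, n_s = cube.shape
        X = cube.reshape(n_t * n_c, n_s)
        y = np.repeat(labels, n_c)
        trial_index = np.repeat(np.arange(n_t), n_c)
        return X, y, trial_index
    if mode == "multichannel":
        X = cube.transpose(0, 2, 1)  # trials x samples x channels
        return X, labels.copy(), np.arange(len(dataset))
    raise ValueError("mode must be 'channels' or 'multichannel'")


@dataclass
class FeaturePipeline:
    """Standardize-then-denoise front-end fitted on the training split only.

    ``use_dwt=False`` (the raw CNN+Bi-LSTM variant) standardizes but skips
    the wavelet stage.  ``target_length`` activates the fixed-length preset
    (e.g. 76) by padding/truncating the approximation coefficients.
    """

    wavelet: str = "db4"
    level: int = 2
    padding: str = "symmetric"
    use_dwt: bool = True
    target_length: int | None = None
    standardizer: preprocess.StandardizerState | None = None

    def fit(self, X_train: np.ndarray) -> "FeaturePipeline":
        flat = X_train.reshape(-1, X_train.shape[-1]) if X_train.ndim == 3 else X_train
        self.standardizer = preprocess.fit_standardizer(flat)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.standardizer is None:
            raise RuntimeError("pipeline not fitted")
        shape3 = X.ndim == 3
        flat = X.reshape(-1, X.shape[-1]) if shape3 else X
        Z = preprocess.apply_standardizer(self.standardizer, flat)
        if self.use_dwt:
            spec = preprocess.get_wavelet(self.wavelet, padding=self.padding)
            Z = preprocess.denoise_features(Z, spec, self.level,
                                            target_length=self.target_length)
        if shape3:
            Z = Z.reshape(X.shape[0], X.shape[1], -1)
        return Z

    def output_length(self, n_samples: int) -> int:
        if not self.use_dwt:
            return n_samples if self.target_length is None else self.target_length
        spec = preprocess.get_wavelet(self.wavelet, padding=self.padding)
        return preprocess.feature_length(n_samples, spec, self.level,
                                         target_length=self.target_length)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5
    zero_division: bool = False
    curves: pd.DataFrame | None = None

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(tp: int, fp: int, tn: int, fn: int
                    ) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall, F1 from confusion counts.

    Zero-denominator convention: precision/recall/F1 are 0 when undefined.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2.0 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return accuracy, precision, recall, f1


def report_from_counts(tp: int, fp: int, tn: int, fn: int,
                       threshold: float = 0.5,
                       curves: pd.DataFrame | None = None) -> EvalReport:
    accuracy, precision, recall, f1 = compute_metrics(tp, fp, tn, fn)
    zero_div = (tp + fp == 0) or (tp + fn == 0) or (precision + recall == 0)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                      precision=precision, recall=recall, f1=f1,
                      threshold=threshold, zero_division=zero_div, curves=curves)


def binomial_band(n: int, p: float = 0.5, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% band for a proportion under Binomial(n, p)."""
    half = z * math.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def train_model(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
                config: ModelConfig, seed: int | None = None) -> pd.DataFrame:
    """Adam / binary-cross-entropy minibatch training.

    Shuffling, dropout and initialization all derive from seeds, so two runs
    with the same seed produce identical weights.  Returns the per-epoch
    curve table (epoch, train_acc, train_loss).
    """
    if X.ndim == 2:
        X = X[..., None]  # (B, L) -> (B, L, 1)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    opt = nn.Adam(model.params, model.grads, learning_rate=config.learning_rate)
    n = X.shape[0]
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            p = model.forward(xb, training=True).ravel()
            loss = nn.binary_cross_entropy(p, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}: loss={loss}, "
                    f"pred range [{p.min()}, {p.max()}]"
                )
            grad = nn.binary_cross_entropy_grad(p, yb).reshape(-1, 1)
            model.backward(grad)
            opt.step()
            losses.append(loss * len(idx))
            correct += int(np.sum((p >= 0.5) == (yb > 0.5)))
        rows.append({
            "epoch": epoch + 1,
            "train_acc": correct / n,
            "train_loss": float(np.sum(losses) / n),
        })
    return pd.DataFrame(rows)


def evaluate(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
             threshold: float = 0.5,
             curves: pd.DataFrame | None = None) -> EvalReport:
    """Threshold sigmoid outputs, tally the confusion matrix, derive metrics."""
    if X.ndim == 2:
        X = X[..., None]
    y = np.asarray(y).astype(int)
    p = model.predict(X).ravel()
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return report_from_counts(tp, fp, tn, fn, threshold=threshold, curves=curves)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    architecture: str
    seed: int
    report: EvalReport
    feature_pipeline: FeaturePipeline
    model: nn.Sequential


def run_pipeline(dataset: EEGDataset, architecture: str = "proposed",
                 config: ModelConfig | None = None,
                 plan: SplitPlan | None = None,
                 features: FeaturePipeline | None = None,
                 sample_mode: str = "channels",
                 seed: int = 0,
                 permute_labels: bool = False) -> PipelineResult:
    """Split -> standardize -> (DWT) -> train -> evaluate, in one call.

    The feature pipeline is fitted on the training split only.  The raw
    ``cnn_bilstm`` variant skips the DWT automatically.  ``permute_labels``
    shuffles the *training* labels (leakage/negative control): test labels
    stay intact, so chance-level accuracy is the expected outcome.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    plan = plan or SplitPlan(seed=seed)
    features = features or FeaturePipeline(use_dwt=architecture != "cnn_bilstm")
    train_set, test_set = make_split(dataset, plan)
    X_train, y_train, _ = dataset_to_samples(train_set, sample_mode)
    X_test, y_test, _ = dataset_to_samples(test_set, sample_mode)
    features.fit(X_train)
    Z_train = features.transform(X_train)
    Z_test = features.transform(X_test)
    if permute_labels:
        y_train = np.random.default_rng(seed + 1).permutation(y_train)
        if len(np.unique(y_train)) < 2:  # pragma: no cover - balanced inputs
            raise ValueError("permuted training labels are single-class")
    input_length = Z_train.shape[1]
    input_channels = Z_train.shape[2] if Z_train.ndim == 3 else 1
    if config is None:
        config = ModelConfig(input_length=input_length,
                             input_channels=input_channels, seed=seed)
    else:
        config = replace(config, input_length=input_length,
                         input_channels=input_channels, seed=seed)
    model = build_model(config, architecture)
    curves = train_model(model, Z_train, y_train, config, seed=seed)
    report = evaluate(model, Z_test, y_test, curves=curves)
    return PipelineResult(architecture=architecture, seed=seed, report=report,
                          feature_pipeline=features, model=model)


def run_comparison(dataset: EEGDataset, architectures: list[str],
                   config: ModelConfig | None = None,
                   plan: SplitPlan | None = None,
                   seeds: list[int] | None = None,
                   sample_mode: str = "channels") -> pd.DataFrame:
    """Architecture x seed sweep; returns per-run rows plus aggregate rows.

    Aggregates report mean and standard deviation per architecture over
    seeds, mirroring an accuracy/precision/recall/F1 comparison table.
    """
    seeds = seeds if seeds is not None else [0, 1, 2, 3, 4]
    rows = []
    for arch in architectures:
        if arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {arch!r}")
        for seed in seeds:
            run_plan = replace(plan, seed=seed) if plan else SplitPlan(seed=seed)
            result = run_pipeline(dataset, arch, config=config, plan=run_plan,
                                  sample_mode=sample_mode, seed=seed)
            r = result.report
            rows.append({
                "architecture": arch, "seed": seed, "kind": "run",
                "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                "accuracy": r.accuracy, "precision": r.precision,
                "recall": r.recall, "f1": r.f1,
            })
    df = pd.DataFrame(rows)
    aggregates = []
    for arch in architectures:
        sub = df[df["architecture"] == arch]
        agg = {"architecture": arch, "seed": -1, "kind": "aggregate",
               "tp": -1, "fp": -1, "tn": -1, "fn": -1}
        for metric in ("accuracy", "precision", "recall", "f1"):
            agg[metric] = sub[metric].mean()
            agg[f"{metric}_sd"] = sub[metric].std(ddof=1) if len(sub) > 1 else 0.0
        aggregates.append(agg)
    return pd.concat([df, pd.DataFrame(aggregates)], ignore_index=True)


def format_comparison(table: pd.DataFrame) -> str:
    """Text table of the aggregate rows (accuracy/precision/recall/F1)."""
    agg = table[table["kind"] == "aggregate"]
    lines = [f"{'Methods':<14}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1-Score':>10}"]
    for _, row in agg.iterrows():
        lines.append(
            f"{row['architecture']:<14}"
            f"{row['accuracy'] * 100:>9.2f}%"
            f"{row['precision'] * 100:>10.2f}%"
            f"{row['recall'] * 100:>8.2f}%"
            f"{row['f1'] * 100:>9.2f}%"
        )
    return "\n".join(lines)


def save_results(table: pd.DataFrame, path: str) -> str:
    table.to_csv(path, index=False)
    return path


def save_curves(curves: pd.DataFrame, path: str) -> str:
    curves.to_csv(path, index=False)
    return path
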