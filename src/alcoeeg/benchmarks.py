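"""Canonical desk-scale benchmark experiments.

These fix the study conditions used to validate the pipeline end to end on
synthetic data, at a size that runs on one CPU in minutes:

* *separable* condition: effect = 3 band-power boost, 100 trials x 20
  channels = 2,000 channel-samples, 15-epoch schedule — the architecture
  must essentially solve it (held-out accuracy >= 0.95) and must not lose
  to its CNN-only ablation;
* *null* condition: effect = 1 (classes identical), 20 independent seeds —
  held-out accuracy pooled over seeds must stay inside the 95% binomial
  band around 0.5;
* *permutation* control: separable data but with the training labels
  shuffled — also chance level; a deviation would reveal information
  leaking through the pipeline (e.g. a standardizer fitted on all data).

Null/permutation runs use a shorter 6-epoch schedule: chance-level
behaviour does not depend on how long a model is trained, and 20 seeds at
the full schedule would buy nothing.
"""

from __future__ import annotations

from . import experiment, synthgen
from .experiment import SplitPlan, binomial_band, run_pipeline
from .network import ModelConfig

EFFECT_SIZE = 3.0
FULL_EPOCHS = 15
CONTROL_EPOCHS = 6
BATCH_SIZE = 64
N_CONTROL_SEEDS = 20


def separable_config(seed: int) -> synthgen.SynthConfig:
    """100 trials x 20 channels = 2,000 channel-samples, effect = 3."""
    return synthgen.SynthConfig(n_subjects_per_class=5, trials_per_subject=10,
                                n_channels=20, effect=EFFECT_SIZE, seed=seed)


def null_config(seed: int) -> synthgen.SynthConfig:
    """100 trials x 8 channels, classes identical (effect = 1)."""
    return synthgen.SynthConfig(n_subjects_per_class=5, trials_per_subject=10,
                                n_channels=8, effect=1.0, seed=seed)


def control_config(seed: int) -> synthgen.SynthConfig:
    """Separable data at the null-condition size, for the permutation control."""
    return synthgen.SynthConfig(n_subjects_per_class=5, trials_per_subject=10,
                                n_channels=8, effect=EFFECT_SIZE, seed=seed)


def model_config(epochs: int = FULL_EPOCHS, seed: int = 0) -> ModelConfig:
    return ModelConfig(epochs=epochs, batch_size=BATCH_SIZE, seed=seed)


def run_separable(seed: int, architectures: tuple[str, ...] = ("proposed", "cnn")
                  ) -> dict[str, experiment.EvalReport]:
    """Train each architecture on the same separable dataset and seed."""
    dataset = synthgen.generate(separable_config(seed))
    reports = {}
    for arch in architectures:
        result = run_pipeline(dataset, arch, config=model_config(seed=seed),
                              plan=SplitPlan(seed=seed), seed=seed)
        reports[arch] = result.report
    return reports


def _pooled_control_accuracy(make_config, base_seed: int, n_seeds: int,
                             permute_labels: bool) -> dict:
    correct = 0
    total = 0
    per_seed = []
    for k in range(n_seeds):
        seed = (base_seed + 7919 * k) % (2**31)
        dataset = synthgen.generate(make_config(seed))
        result = run_pipeline(dataset, "proposed",
                              config=model_config(epochs=CONTROL_EPOCHS, seed=seed),
                              plan=SplitPlan(seed=seed), seed=seed,
                              permute_labels=permute_labels)
        r = result.report
        correct += r.tp + r.tn
        total += r.n_samples
        per_seed.append(r.accuracy)
    lo, hi = binomial_band(total)
    return {
        "mean_accuracy": correct / total,
        "per_seed": per_seed,
        "n_predictions": total,
        "band": (lo, hi),
        "in_band": lo <= correct / total <= hi,
    }


def run_null_control(base_seed: int, n_seeds: int = N_CONTROL_SEEDS) -> dict:
    """Effect=1 datasets: pooled held-out accuracy vs the binomial band."""
    return _pooled_control_accuracy(null_config, base_seed, n_seeds,
                                    permute_labels=False)


def run_permutation_control(base_seed: int, n_seeds: int = N_CONTROL_SEEDS) -> dict:
    """Separable datasets, permuted training labels: leakage guard."""
    return _pooled_control_accuracy(control_config, base_seed, n_seeds,
                                    permute_labels=True)
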