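"""Splits, metrics, training loop and comparison harness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alcoeeg import experiment, synthgen
from alcoeeg.experiment import (
    FeaturePipeline,
    SplitPlan,
    compute_metrics,
    dataset_to_samples,
    evaluate,
    make_split,
    report_from_counts,
    run_comparison,
    run_pipeline,
    train_model,
)
from alcoeeg.network import ModelConfig, build_model


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

class TestMakeSplit:
    def _dataset(self, n_subjects=5, trials=4):
        config = synthgen.SynthConfig(n_subjects_per_class=n_subjects,
                                      trials_per_subject=trials, n_channels=2,
                                      n_samples=64, seed=3)
        return synthgen.generate(config)

    def test_subject_wise_subject_counts(self):
        ds = self._dataset(n_subjects=5)
        train, test = make_split(ds, SplitPlan(mode="subject_wise",
                                               train_fraction=0.8, seed=0))
        # 10 subjects total, 80% -> 8 train / 2 test
        assert len(set(train.subject_ids)) == 8
        assert len(set(test.subject_ids)) == 2
        assert not set(train.subject_ids) & set(test.subject_ids)

    def test_same_seed_gives_identical_split(self):
        ds = self._dataset()
        plan = SplitPlan(seed=42)
        a = make_split(ds, plan)
        b = make_split(ds, plan)
        for x, y in zip(a, b):
            assert x.subject_ids == y.subject_ids
            np.testing.assert_array_equal(x.to_array(), y.to_array())

    def test_stratification_preserves_class_ratio(self):
        ds = self._dataset()
        train, test = make_split(ds, SplitPlan(train_fraction=0.8, seed=1))
        for side in (train, test):
            labels = side.labels
            assert abs(int(np.sum(labels == 1)) - int(np.sum(labels == 0))) <= 1

    def test_disjoint_and_exhaustive(self):
        ds = self._dataset()
        train, test = make_split(ds, SplitPlan(seed=2))
        assert len(train) + len(test) == len(ds)

    def test_single_class_side_rejected(self):
        config = synthgen.SynthConfig(n_subjects_per_class=1, trials_per_subject=1,
                                      n_channels=2, n_samples=64, seed=0)
        ds = synthgen.generate(config)
        with pytest.raises(ValueError):
            make_split(ds, SplitPlan(seed=0))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_hand_derived_counts(self):
        # tp=90 fp=20 tn=80 fn=10: direct evaluation of the four ratios
        acc, prec, rec, f1 = compute_metrics(90, 20, 80, 10)
        assert acc == pytest.approx(0.85)
        assert prec == pytest.approx(0.81818, abs=1e-5)
        assert rec == pytest.approx(0.90)
        assert f1 == pytest.approx(0.85714, abs=1e-5)

    def test_perfect_classifier(self):
        assert compute_metrics(50, 0, 50, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_tp_with_fp_gives_zero_metrics(self):
        acc, prec, rec, f1 = compute_metrics(0, 5, 10, 3)
        assert prec == 0.0 and rec == 0.0 and f1 == 0.0
        report = report_from_counts(0, 5, 10, 3)
        assert report.zero_division

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError, match="zero"):
            compute_metrics(0, 0, 0, 0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_metrics(-1, 0, 1, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_per_sample_counting(self, seed):
        """Oracle: tally agreement sample by sample from raw prediction and
        label lists, then compare every metric."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 1000))
        y = (rng.random(n) < 0.5).astype(int)
        pred = (rng.random(n) < 0.5).astype(int)
        tp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 1)
        fp = sum(1 for p, t in zip(pred, y) if p == 1 and t == 0)
        tn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 0)
        fn = sum(1 for p, t in zip(pred, y) if p == 0 and t == 1)
        acc, prec, rec, f1 = compute_metrics(tp, fp, tn, fn)
        assert acc == pytest.approx(float(np.mean(pred == y)))
        n_pred_pos = tp + fp
        n_pos = tp + fn
        assert prec == pytest.approx(tp / n_pred_pos if n_pred_pos else 0.0)
        assert rec == pytest.approx(tp / n_pos if n_pos else 0.0)
        if prec + rec > 0:
            assert f1 == pytest.approx(2 * prec * rec / (prec + rec))

    def test_invariant_to_sample_ordering(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.5).astype(int)
        p = rng.random(200)
        order = rng.permutation(200)

        def counts(pred, yy):
            return (int(np.sum((pred == 1) & (yy == 1))),
                    int(np.sum((pred == 1) & (yy == 0))),
                    int(np.sum((pred == 0) & (yy == 0))),
                    int(np.sum((pred == 0) & (yy == 1))))

        pred = (p >= 0.5).astype(int)
        assert (compute_metrics(*counts(pred, y))
                == compute_metrics(*counts(pred[order], y[order])))


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def _tiny_training_data(n=40, length=32, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, length))
    X[y == 1] += 2.0  # trivially separable offset
    return X, y


class TestTrainModel:
    CFG = dict(input_length=32, conv_stack=((4, 3, 1),) * 2 + ((8, 3, 1),) * 2,
               pre_rnn_dense=16, rnn_reshape=(2, 8), bilstm_units=(4, 4),
               head_dense=(8, 8, 4), batch_size=16)

    def test_one_epoch_returns_one_curve_point(self):
        X, y = _tiny_training_data()
        config = ModelConfig(epochs=1, **self.CFG)
        model = build_model(config, "proposed")
        curves = train_model(model, X, y, config, seed=0)
        assert list(curves.columns) == ["epoch", "train_acc", "train_loss"]
        assert len(curves) == 1

    def test_loss_decreases_on_separable_data(self):
        X, y = _tiny_training_data()
        config = ModelConfig(epochs=20, dropout_rate=0.1, **self.CFG)
        model = build_model(config, "proposed")
        curves = train_model(model, X, y, config, seed=0)
        assert curves["train_loss"].iloc[-1] < curves["train_loss"].iloc[0]

    def test_same_seed_gives_identical_final_loss(self):
        X, y = _tiny_training_data()
        config = ModelConfig(epochs=3, **self.CFG)
        losses = []
        for _ in range(2):
            model = build_model(config, "proposed")
            curves = train_model(model, X, y, config, seed=5)
            losses.append(curves["train_loss"].iloc[-1])
        assert losses[0] == losses[1]

    def test_single_class_training_rejected(self):
        X, _ = _tiny_training_data()
        config = ModelConfig(epochs=1, **self.CFG)
        model = build_model(config, "proposed")
        with pytest.raises(ValueError, match="both classes"):
            train_model(model, X, np.ones(len(X)), config)


class TestEvaluate:
    def _model_and_data(self):
        X, y = _tiny_training_data()
        config = ModelConfig(epochs=1, **TestTrainModel.CFG)
        model = build_model(config, "proposed")
        return model, X, y.astype(int)

    def test_threshold_zero_marks_everything_positive(self):
        model, X, y = self._model_and_data()
        report = evaluate(model, X, y, threshold=0.0)
        assert report.recall == 1.0
        assert report.tn == report.fn == 0

    def test_threshold_above_one_marks_everything_negative(self):
        model, X, y = self._model_and_data()
        report = evaluate(model, X, y, threshold=1.0 + 1e-9)
        assert report.recall == 0.0
        assert report.tp == report.fp == 0

    def test_counts_sum_to_test_set_size(self):
        model, X, y = self._model_and_data()
        report = evaluate(model, X, y)
        assert report.n_samples == len(X)


# ---------------------------------------------------------------------------
# Pipeline / comparison
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_channels_mode_sample_bookkeeping(self, small_dataset):
        X, y, trial_idx = dataset_to_samples(small_dataset, "channels")
        n_c = len(small_dataset.channel_names)
        assert X.shape == (len(small_dataset) * n_c,
                           small_dataset.trials[0].n_samples)
        np.testing.assert_array_equal(y, np.repeat(small_dataset.labels, n_c))

    def test_multichannel_mode_keeps_trials(self, small_dataset):
        X, y, _ = dataset_to_samples(small_dataset, "multichannel")
        assert X.shape == (len(small_dataset),
                           small_dataset.trials[0].n_samples,
                           len(small_dataset.channel_names))

    def test_feature_pipeline_output_length_contract(self, small_dataset):
        X, _, _ = dataset_to_samples(small_dataset, "channels")
        fp = FeaturePipeline(wavelet="haar", level=2, padding="periodic")
        fp.fit(X)
        Z = fp.transform(X)
        assert Z.shape[1] == fp.output_length(X.shape[1]) == X.shape[1] // 4

    def test_run_pipeline_end_to_end_smoke(self, separable_dataset):
        config = ModelConfig(epochs=2, batch_size=32, **{
            k: v for k, v in TestTrainModel.CFG.items()
            if k not in ("input_length", "batch_size")})
        result = run_pipeline(separable_dataset, "proposed", config=config, seed=0)
        assert 0.0 <= result.report.accuracy <= 1.0
        assert len(result.report.curves) == 2

    def test_comparison_table_bookkeeping(self, separable_dataset):
        config = ModelConfig(epochs=1, batch_size=32, **{
            k: v for k, v in TestTrainModel.CFG.items()
            if k not in ("input_length", "batch_size")})
        table = run_comparison(separable_dataset, ["proposed", "cnn"],
                               config=config, seeds=[0, 1, 2])
        runs = table[table["kind"] == "run"]
        aggs = table[table["kind"] == "aggregate"]
        assert len(runs) == 6
        assert len(aggs) == 2
        assert set(aggs["architecture"]) == {"proposed", "cnn"}
        for metric in ("accuracy", "precision", "recall", "f1"):
            sub = runs[runs["architecture"] == "proposed"][metric]
            row = aggs[aggs["architecture"] == "proposed"].iloc[0]
            assert row[metric] == pytest.approx(sub.mean())

    def test_unknown_architecture_rejected(self, separable_dataset):
        with pytest.raises(ValueError, match="unknown architecture"):
            run_comparison(separable_dataset, ["mlp"], seeds=[0])

    def test_format_comparison_lists_architectures(self, separable_dataset):
        config = ModelConfig(epochs=1, batch_size=32, **{
            k: v for k, v in TestTrainModel.CFG.items()
            if k not in ("input_length", "batch_size")})
        table = run_comparison(separable_dataset, ["cnn"], config=config, seeds=[0])
        text = experiment.format_comparison(table)
        assert "cnn" in text and "Accuracy" in text
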