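"""Training protocol, metrics closed forms, and evaluation invariances."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokeformer.head import ModelConfig, SmokeClassifier
from smokeformer.synthetic_data import generate_base_frame
from smokeformer.train_eval import (ConfusionCounts, MetricsReport,
                                    TrainConfig, evaluate, evaluate_arrays,
                                    exponential_lr, load_checkpoint,
                                    load_split, measure_throughput,
                                    preprocess, save_checkpoint,
                                    stratified_folds, train)


class TestPreprocess:
    def test_resizes_to_square_input(self):
        img = generate_base_frame(0, 192, 384)
        out = preprocess(img, 224)
        assert out.shape == (3, 224, 224)
        assert out.dtype == np.float32
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_no_flip_is_deterministic(self):
        img = generate_base_frame(1, 64, 64)
        a = preprocess(img, 64, train_mode=True, flip_prob=0.0)
        b = preprocess(img, 64, train_mode=True, flip_prob=0.0)
        np.testing.assert_array_equal(a, b)

    def test_forced_flip_is_involution(self):
        img = generate_base_frame(2, 64, 64)
        rng_always = np.random.default_rng(0)
        once = preprocess(img, 64, train_mode=True, flip_prob=1.0, rng=rng_always)
        np.testing.assert_array_equal(once[:, :, ::-1][:, :, ::-1], once)
        base = preprocess(img, 64)
        np.testing.assert_array_equal(once[:, :, ::-1], base)


class TestLearningRate:
    def test_initial_epoch(self):
        assert exponential_lr(0, 1e-3, 0.9) == 1e-3

    def test_factor_one_constant(self):
        assert exponential_lr(30, 1e-3, 1.0) == 1e-3

    def test_decay_arithmetic(self):
        assert abs(exponential_lr(2, 1e-3, 0.9) - 0.00081) < 1e-12

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            exponential_lr(-1, 1e-3, 0.9)


class TestMetrics:
    def test_closed_form_example(self):
        counts = ConfusionCounts(tp=3, tn=5, fp=1, fn=1)
        report = MetricsReport.from_counts(counts)
        assert report.accuracy == pytest.approx(0.8)
        assert report.sensitivity == pytest.approx(0.75)

    def test_perfect_classifier_on_960_240(self):
        report = MetricsReport.from_counts(ConfusionCounts(tp=240, tn=960))
        assert report.accuracy == 1.0 and report.sensitivity == 1.0

    def test_all_negative_classifier(self):
        report = MetricsReport.from_counts(ConfusionCounts(tn=960, fn=240))
        assert report.accuracy == pytest.approx(0.8)
        assert report.sensitivity == 0.0

    def test_sensitivity_nan_without_positives(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            report = MetricsReport.from_counts(ConfusionCounts(tn=10, fp=2))
        assert np.isnan(report.sensitivity)

    def test_counts_sum_to_total(self):
        y = np.array([0, 1, 1, 0, 1, 0])
        p = np.array([0, 1, 0, 1, 1, 0])
        counts = ConfusionCounts.from_predictions(y, p)
        assert counts.total == len(y)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(1, 50))
    def test_metrics_match_recomputation(self, tn, fp, fn, tp):
        counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        report = MetricsReport.from_counts(counts)
        assert report.accuracy == (tp + tn) / (tp + fn + fp + tn)
        assert report.sensitivity == tp / (tp + fn)
        d = report.to_dict()
        assert d["tp"] + d["fp"] + d["fn"] + d["tn"] == counts.total


class TestFolds:
    def test_two_folds_on_40_stratified(self):
        y = np.array([1] * 8 + [0] * 32)  # 4:1 smoke-free:smoke
        folds = stratified_folds(y, 2, seed=0)
        for tr, va in folds:
            assert len(va) == 20
            assert (y[va] == 1).sum() == 4  # each fold keeps the 4:1 ratio

    def test_same_seed_identical_assignment(self):
        y = np.array([1] * 10 + [0] * 40)
        a = stratified_folds(y, 5, seed=3)
        b = stratified_folds(y, 5, seed=3)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)


@pytest.fixture(scope="module")
def short_run(tiny_dataset):
    _, manifest = tiny_dataset
    cfg = TrainConfig(input_size=64, epochs=3, batch_size=8, seed=5,
                      model=ModelConfig(input_size=64, embed_dim=16,
                                        depth=1, seed=5))
    return cfg, manifest, train(cfg, manifest, run_cv=False)


class TestTraining:
    def test_loss_decreases(self, short_run):
        _, _, result = short_run
        epochs = result["log"][-1]["epochs"]
        assert epochs[-1]["loss"] < epochs[0]["loss"]

    def test_evaluation_invariances(self, short_run, rng):
        """Metrics identical for shuffled test order and any batch size."""
        cfg, manifest, result = short_run
        model = result["model"]
        x, y = load_split(manifest, "test", cfg.input_size)
        base = evaluate_arrays(model, x, y, batch_size=4)
        perm = rng.permutation(len(y))
        shuffled = evaluate_arrays(model, x[perm], y[perm], batch_size=7)
        assert base.counts == shuffled.counts
        assert base.accuracy == shuffled.accuracy

    def test_fused_evaluation_identical_counts(self, short_run):
        cfg, manifest, result = short_run
        from smokeformer.reparam import deploy_model
        model = result["model"]
        deployed = deploy_model(model)
        a = evaluate(model, manifest, split="test")
        b = evaluate(deployed, manifest, split="test")
        assert a.counts == b.counts

    def test_checkpoint_round_trip(self, short_run, tmp_path, rng):
        cfg, _, result = short_run
        model = result["model"]
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(str(path), model, cfg)
        loaded = load_checkpoint(str(path))
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(loaded(x), model(x), atol=1e-6)

    def test_fused_checkpoint_round_trip(self, short_run, tmp_path, rng):
        cfg, _, result = short_run
        from smokeformer.reparam import deploy_model
        deployed = deploy_model(result["model"])
        path = tmp_path / "fused.ckpt.npz"
        save_checkpoint(str(path), deployed, cfg)
        loaded = load_checkpoint(str(path))
        assert loaded.topology == "fused"
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(loaded(x), deployed(x), atol=1e-6)

    def test_batch_larger_than_train_set_rejected(self, tiny_dataset):
        _, manifest = tiny_dataset
        cfg = TrainConfig(input_size=64, epochs=1, batch_size=64,
                          model=ModelConfig(input_size=64, embed_dim=8, depth=1))
        with pytest.raises(ValueError, match="batch"):
            train(cfg, manifest, run_cv=False)


class TestThroughput:
    def test_zero_images_rejected(self):
        model = SmokeClassifier(ModelConfig(input_size=32, embed_dim=8, depth=1))
        with pytest.raises(ValueError):
            measure_throughput(model, n_images=0)

    def test_reports_positive_rate(self):
        model = SmokeClassifier(ModelConfig(input_size=32, embed_dim=8, depth=1))
        rate = measure_throughput(model, n_images=4, warmup=1, repeats=2)
        assert rate > 0


class TestConfigValidation:
    def test_fold_and_epoch_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr_decay=0.0)

    def test_reference_protocol_values(self):
        cfg = TrainConfig.reference_protocol()
        assert cfg.input_size == 224
        assert cfg.initial_lr == 1e-3
        assert cfg.epochs == 50
        assert cfg.folds == 10
        assert cfg.model.depth == 10
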