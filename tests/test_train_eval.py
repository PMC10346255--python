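import numpy as np
import pytest

from semgkit.model import ModelConfig, build_irdc_net
from semgkit.train_eval import (
    SplitSpec,
    TrainConfig,
    evaluate,
    predict,
    stratified_split,
    train,
)


class TestStratifiedSplit:
    def test_seventy_thirty_with_validation(self):
        labels = np.repeat(np.arange(10), 50)
        train_idx, val_idx, test_idx = stratified_split(labels, SplitSpec(seed=0))
        assert len(test_idx) == 150 and len(train_idx) + len(val_idx) == 350
        for cls in range(10):
            assert (labels[test_idx] == cls).sum() == 15
            n_val = (labels[val_idx] == cls).sum()
            assert n_val in (10, 11)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        labels = rng.integers(0, 4, size=203)
        parts = stratified_split(labels, SplitSpec(seed=3))
        joined = np.concatenate(parts)
        assert len(joined) == 203
        assert len(np.unique(joined)) == 203

    def test_deterministic_under_seed(self, rng):
        labels = rng.integers(0, 5, size=100)
        a = stratified_split(labels, SplitSpec(seed=9))
        b = stratified_split(labels, SplitSpec(seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_class_proportions_preserved(self, rng):
        labels = np.repeat(np.arange(5), [30, 60, 90, 120, 100])
        train_idx, val_idx, test_idx = stratified_split(labels, SplitSpec(seed=1))
        total = np.bincount(labels) / labels.size
        for idx in (train_idx, test_idx):
            frac = np.bincount(labels[idx], minlength=5) / idx.size
            assert np.abs(frac - total).max() <= 1.5 / idx.size * 5

    def test_tiny_class_rejected(self):
        labels = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="1"):
            stratified_split(labels, SplitSpec())


class TestEvaluate:
    def test_oracle_predictions_are_perfect(self, rng):
        y = rng.integers(0, 4, 80)
        report = evaluate(y, y)
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(report.f1, 1.0)
        assert np.all(report.confusion == np.diag(np.bincount(y)))

    def test_constant_predictor_on_balanced_classes(self):
        y = np.repeat(np.arange(10), 20)
        pred = np.zeros_like(y)
        report = evaluate(pred, y, n_classes=10)
        assert report.accuracy == pytest.approx(0.10)
        assert report.macro_recall == pytest.approx(0.10)

    def test_hand_computed_two_class_contingency(self):
        # confusion [[8, 2], [4, 6]] (rows = true)
        y_true = np.r_[np.zeros(10, int), np.ones(10, int)]
        y_pred = np.r_[np.zeros(8, int), np.ones(2, int), np.zeros(4, int), np.ones(6, int)]
        report = evaluate(y_pred, y_true)
        np.testing.assert_array_equal(report.confusion, [[8, 2], [4, 6]])
        assert report.precision[0] == pytest.approx(8 / 12, abs=1e-9)
        assert report.recall[0] == pytest.approx(0.8, abs=1e-9)
        assert report.f1[0] == pytest.approx(0.727, abs=1e-3)

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        perm = rng.permutation(60)
        a = evaluate(pred, y)
        b = evaluate(pred[perm], y[perm])
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_macro_f1_matches_confusion_derivation(self, rng):
        y = rng.integers(0, 4, 120)
        pred = rng.integers(0, 4, 120)
        report = evaluate(pred, y)
        conf = report.confusion.astype(float)
        f1s = []
        for c in range(4):
            tp = conf[c, c]
            prec = tp / conf[:, c].sum() if conf[:, c].sum() else 0.0
            rec = tp / conf[c].sum() if conf[c].sum() else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert report.macro_f1 == pytest.approx(np.mean(f1s), abs=1e-12)

    def test_row_sums_equal_true_counts(self, rng):
        y = rng.integers(0, 5, 90)
        pred = rng.integers(0, 5, 90)
        report = evaluate(pred, y)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), np.bincount(y, minlength=5))
        assert report.accuracy == pytest.approx(np.trace(report.confusion) / 90)

    def test_empty_test_set_rejected(self, rng):
        net = build_irdc_net(ModelConfig(input_length=64))
        with pytest.raises(ValueError, match="empty"):
            evaluate(net, np.empty((0, 1, 64)), np.empty(0, int))

    def test_out_of_range_labels_rejected(self, rng):
        net = build_irdc_net(ModelConfig(n_classes=3, input_length=64))
        x = rng.standard_normal((4, 1, 64)).astype(np.float32)
        with pytest.raises(ValueError, match="class set"):
            evaluate(net, x, np.array([0, 1, 2, 3]))


def _toy_problem(rng, n_classes=3, n_per=12, length=64):
    """Linearly separable single-channel signals: one tone per class."""
    xs, ys = [], []
    for c in range(n_classes):
        t = np.arange(length)
        for _ in range(n_per):
            tone = np.sin(2 * np.pi * (c + 1) * 4 * t / length)
            xs.append(tone + 0.05 * rng.standard_normal(length))
            ys.append(c)
    x = np.asarray(xs, dtype=np.float32)[:, None, :]
    return x, np.asarray(ys)


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        x, y = _toy_problem(rng)
        net = build_irdc_net(ModelConfig(n_classes=3, input_length=64, dropout_rate=0.0))
        before = [p.value.copy() for p in net.parameters()]
        history = train(net, {"train": (x, y)}, TrainConfig(epochs=2, learning_rate=0.0, seed=0))
        for p, old in zip(net.parameters(), before):
            np.testing.assert_array_equal(p.value, old)
        assert history["train_loss"][0] == pytest.approx(history["train_loss"][-1], rel=1e-6)

    def test_single_class_dataset_is_trivially_learned(self, rng):
        x, _ = _toy_problem(rng, n_classes=1, n_per=10)
        y = np.zeros(10, int)
        net = build_irdc_net(ModelConfig(n_classes=1, input_length=64))
        history = train(net, {"train": (x, y), "val": (x, y)}, TrainConfig(epochs=1, seed=0))
        assert history["val_acc"][-1] == 1.0

    def test_loss_decreases_on_separable_toy_problem(self, rng):
        x, y = _toy_problem(rng)
        net = build_irdc_net(
            ModelConfig(n_classes=3, input_length=64, n_blocks_A=1, n_blocks_B=0,
                        dropout_rate=0.2)
        )
        history = train(net, {"train": (x, y), "val": (x, y)}, TrainConfig(epochs=8, seed=0))
        assert history["train_loss"][-1] < history["train_loss"][0]
        assert history["val_acc"][-1] >= 0.9

    def test_training_is_reproducible(self, rng):
        x, y = _toy_problem(rng)

        def run():
            net = build_irdc_net(
                ModelConfig(n_classes=3, input_length=64, n_blocks_A=1, n_blocks_B=0),
                seed=3,
            )
            train(net, {"train": (x, y)}, TrainConfig(epochs=2, seed=11))
            return predict(net, x)

        np.testing.assert_array_equal(run(), run())

    def test_empty_training_split_rejected(self):
        net = build_irdc_net(ModelConfig(n_classes=2, input_length=64))
        with pytest.raises(ValueError, match="empty"):
            train(net, {"train": (np.empty((0, 1, 64)), np.empty(0, int))})
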