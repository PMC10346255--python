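"""Dataset splitting, training loop, and evaluation metrics.

The split is stratified 70/30 train/test, with 30% of the training portion
held out for validation; per-class counts use largest-remainder rounding so
totals match the global fractions exactly where divisible. Training
minimizes categorical cross-entropy with Adam; every source of randomness
(shuffling, dropout) is seeded, so identical inputs and seeds reproduce
identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import nn

__all__ = [
    "SplitSpec", "TrainConfig", "EvalReport",
    "stratified_split", "train", "evaluate",
]


@dataclass(frozen=True)
class SplitSpec:
    test_frac: float = 0.3
    val_frac_of_train: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_frac", "val_frac_of_train"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class EvalReport:
    """Accuracy, per-class precision/recall/F1, macro averages, confusion
    matrix (rows = true class, columns = predicted), optional history."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    classes: np.ndarray
    history: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            },
            index=[f"class_{c}" for c in self.classes],
        )
        frame.loc["macro_avg"] = [
            self.macro_precision, self.macro_recall, self.macro_f1,
            int(self.support.sum()),
        ]
        return frame


def _largest_remainder_counts(sizes: np.ndarray, frac: float) -> np.ndarray:
    """Per-class counts ~ frac*size, corrected so the total is round(frac*N)."""
    quotas = frac * sizes
    base = np.floor(quotas).astype(int)
    target = int(round(frac * sizes.sum()))
    short = target - base.sum()
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(quotas - base, kind="stable")
        take = order[base[order] > 0][: -short]
        base[take] -= 1
    return base


def stratified_split(
    labels: np.ndarray, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index arrays.

    Per class, ~``test_frac`` of members go to test and ~``val_frac_of_train``
    of the remainder to validation, with largest-remainder rounding across
    classes. Deterministic under ``spec.seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < 3]
    if too_small.size:
        raise ValueError(f"classes with fewer than 3 members: {too_small.tolist()}")
    if not spec.stratified:
        perm = rng.permutation(labels.size)
        n_test = int(round(spec.test_frac * labels.size))
        n_val = int(round(spec.val_frac_of_train * (labels.size - n_test)))
        return perm[n_test + n_val :], perm[n_test : n_test + n_val], perm[:n_test]

    test_counts = _largest_remainder_counts(counts, spec.test_frac)
    remain = counts - test_counts
    val_counts = _largest_remainder_counts(remain, spec.val_frac_of_train)
    train_idx, val_idx, test_idx = [], [], []
    for cls, n_test, n_val in zip(classes, test_counts, val_counts):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        test_idx.append(members[:n_test])
        val_idx.append(members[n_test : n_test + n_val])
        train_idx.append(members[n_test + n_val :])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def _accuracy(network: nn.Network, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) in inference mode."""
    losses, correct = 0.0, 0
    for i in range(0, x.shape[0], batch):
        xb, yb = x[i : i + batch], y[i : i + batch]
        logits = network.logits(xb, training=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses += loss * xb.shape[0]
        correct += int((logits.argmax(axis=1) == yb).sum())
    return losses / x.shape[0], correct / x.shape[0]


def train(
    network: nn.Network,
    splits: dict[str, tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
) -> dict[str, list[float]]:
    """Train in place; returns per-epoch history.

    ``splits`` maps "train" and (optionally) "val" to (X, y) pairs with X of
    shape (n, channels, length) and integer labels y.
    """
    x_train, y_train = splits["train"]
    if x_train.shape[0] == 0:
        raise ValueError("empty training split")
    x_train = np.ascontiguousarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=int)
    val = splits.get("val")
    if val is not None:
        x_val = np.ascontiguousarray(val[0], dtype=np.float32)
        y_val = np.asarray(val[1], dtype=int)

    rng = np.random.default_rng(config.seed)
    network.reseed_dropout(config.seed + 1)
    optimizer = nn.Adam(network.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    n = x_train.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            network.zero_grad()
            logits = network.logits(xb, training=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {_epoch}, batch {i // config.batch_size}"
                )
            network.backward(grad)
            optimizer.step()
            epoch_loss += loss * xb.shape[0]
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(epoch_correct / n)
        if val is not None:
            vloss, vacc = _accuracy(network, x_val, y_val)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
    return history


def predict(network: nn.Network, x: np.ndarray, batch: int = 256) -> np.ndarray:
    x = np.ascontiguousarray(x, dtype=np.float32)
    out = []
    for i in range(0, x.shape[0], batch):
        out.append(network.logits(x[i : i + batch], training=False).argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def evaluate(
    network_or_pred, x_or_true: np.ndarray, y_true: np.ndarray | None = None,
    n_classes: int | None = None, history: dict | None = None,
) -> EvalReport:
    """Evaluate a network on a test set, or score given predictions.

    Call as ``evaluate(network, X, y)`` or ``evaluate(y_pred, y_true)``.
    Undefined precision/recall (empty denominator) is reported as 0.
    """
    if y_true is None:
        y_pred = np.asarray(network_or_pred, dtype=int)
        y_true_arr = np.asarray(x_or_true, dtype=int)
    else:
        y_true_arr = np.asarray(y_true, dtype=int)
        if y_true_arr.size == 0:
            raise ValueError("empty test set")
        n_classes = n_classes or network_or_pred.config.n_classes
        if y_true_arr.min() < 0 or y_true_arr.max() >= n_classes:
            raise ValueError(
                f"labels outside the model's class set [0, {n_classes})"
            )
        y_pred = predict(network_or_pred, x_or_true)
    if n_classes is None:
        n_classes = int(max(y_true_arr.max(), y_pred.max())) + 1
    classes = np.arange(n_classes)
    conf = confusion_matrix(y_true_arr, y_pred, labels=classes)
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true_arr, y_pred, labels=classes, zero_division=0
    )
    return EvalReport(
        accuracy=float((y_pred == y_true_arr).mean()),
        precision=precision, recall=recall, f1=f1, support=support,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        confusion=conf, classes=classes,
        history=history or {},
    )
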