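"""Training loop with binary validation-accuracy model selection, confusion
matrix and minority-positive metrics, and the six-configuration experiment
harness (baseline / weighted augmentation / weighted loss, each with and
without majority clustering).

Two classifier implementations satisfy the same contract: a deep
transfer-learning head (optional; needs torch) and a lightweight multinomial
linear model trained by minibatch SGD on extracted features, which mirrors
the published hyperparameter schedule (momentum, weight decay, step-decayed
learning rate) at desk scale and is what the tests and the synthetic
pipeline exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import LabeledImageSet, SplitSpec, stratified_split
from .features import FeatureExtractor, extract_features
from .transform import LabelMap, binary_truth, fold_to_binary, partition_majority
from .weighting import (
    AugmentSpec,
    WeightedAugmentSampler,
    class_weights,
    loss_weights_for_training,
    weighted_augment_sampler,
)

logger = logging.getLogger("mciic")

SUITE_CONFIGURATIONS: list[tuple[str, bool, str]] = [
    ("baseline", False, "none"),
    ("weighted-aug", False, "weighted_aug"),
    ("weighted-clf", False, "weighted_clf"),
    ("mciic", True, "none"),
    ("weighted-aug + mciic", True, "weighted_aug"),
    ("weighted-clf + mciic", True, "weighted_clf"),
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: SGD with momentum, weight decay, and a step
    learning-rate decay of ×0.1 every 12 epochs."""

    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 0.005
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 12
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.lr_decay_every) < 1:
            raise ValueError("epochs, batch_size and lr_decay_every must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        return self.learning_rate * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the minority class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    configuration: str = ""
    zero_division_flags: tuple[str, ...] = ()


def confusion_from_binary(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics_from_confusion(cm: ConfusionMatrix, configuration: str = "") -> MetricsReport:
    """Accuracy, minority precision/recall and their harmonic mean (F1).

    A zero denominator yields 0 with a flag recorded rather than NaN.
    """
    flags: list[str] = []
    accuracy = (cm.tp + cm.tn) / cm.total if cm.total else 0.0
    if cm.tp + cm.fp:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, flags = 0.0, flags + ["precision_zero_division"]
    if cm.tp + cm.fn:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, flags = 0.0, flags + ["recall_zero_division"]
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, flags = 0.0, flags + ["f1_zero_division"]
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, configuration=configuration,
                         zero_division_flags=tuple(flags))


def evaluate_binary(
    y_true_binary: np.ndarray,
    y_pred_multiclass: np.ndarray,
    label_map: LabelMap,
    configuration: str = "",
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Fold multiclass predictions to binary and score against binary truth."""
    y_pred = fold_to_binary(y_pred_multiclass, label_map)
    cm = confusion_from_binary(y_true_binary, y_pred)
    return cm, metrics_from_confusion(cm, configuration)


class SoftmaxClassifier:
    """Multinomial linear model on extracted features, trained by minibatch
    SGD with momentum and L2 weight decay.  Deterministic given the seed."""

    def __init__(self, extractor: FeatureExtractor, seed: int = 0):
        self.extractor = extractor
        self.seed = seed
        self.W: np.ndarray | None = None  # (d+1) × C, last row is the bias
        self._velocity: np.ndarray | None = None
        self._rng = np.random.default_rng(seed)

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, n_classes: int) -> None:
        self.W = self._rng.normal(0.0, 0.01, size=(n_features + 1, n_classes))
        self._velocity = np.zeros_like(self.W)

    @staticmethod
    def _design(X: np.ndarray) -> np.ndarray:
        return np.hstack([X, np.ones((X.shape[0], 1))])

    def _probabilities(self, X: np.ndarray) -> np.ndarray:
        logits = self._design(X) @ self.W
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)

    def train_epoch(self, X: np.ndarray, y: np.ndarray, epoch: int,
                    cfg: TrainConfig,
                    sample_weights: np.ndarray | None = None) -> float:
        """One pass of minibatch SGD; returns the mean (weighted) loss."""
        assert self.W is not None and self._velocity is not None
        n = X.shape[0]
        lr = cfg.lr_at(epoch)
        order = self._rng.permutation(n)
        losses: list[float] = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb = self._design(X[idx])
            yb = y[idx]
            wb = sample_weights[idx] if sample_weights is not None else np.ones(len(idx))
            logits = Xb @ self.W
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            probs = expl / expl.sum(axis=1, keepdims=True)
            losses.append(float(
                -(wb * np.log(probs[np.arange(len(idx)), yb] + 1e-12)).mean()
            ))
            grad_logits = probs
            grad_logits[np.arange(len(idx)), yb] -= 1.0
            grad_logits *= wb[:, None]
            grad = Xb.T @ grad_logits / len(idx) + cfg.weight_decay * self.W
            self._velocity = cfg.momentum * self._velocity - lr * grad
            self.W = self.W + self._velocity
        return float(np.mean(losses))

    # -- contract ----------------------------------------------------------

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        if self.W is None:
            raise RuntimeError("classifier is not fitted")
        return np.argmax(self._probabilities(X), axis=1)

    def predict(self, ds: LabeledImageSet) -> np.ndarray:
        X = extract_features(ds, self.extractor).values
        return self.predict_features(X)

    def get_weights(self) -> np.ndarray:
        assert self.W is not None
        return self.W.copy()

    def set_weights(self, W: np.ndarray) -> None:
        self.W = W.copy()


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_binary_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.epoch_loss)),
            "loss": self.epoch_loss,
            "val_binary_accuracy": self.val_binary_accuracy,
        })


def best_epoch(val_accuracies: list[float]) -> int:
    """Index of the highest validation accuracy; ties go to the earliest."""
    if not val_accuracies:
        raise ValueError("empty history")
    return int(np.argmax(val_accuracies))


def train(
    ds_train: LabeledImageSet,
    ds_val: LabeledImageSet,
    clf: SoftmaxClassifier,
    cfg: TrainConfig,
    label_map: LabelMap,
    per_class_loss_weights: np.ndarray | None = None,
    sampler: WeightedAugmentSampler | None = None,
) -> tuple[SoftmaxClassifier, TrainHistory]:
    """Fit with per-epoch binary validation model selection.

    After every epoch the validation predictions are folded to binary through
    ``label_map`` and binary accuracy recorded; the weights returned are from
    the epoch with the highest binary validation accuracy (earliest on ties).
    With a ``sampler``, each epoch's training images are drawn from the
    weighted-augmentation stream and re-featurized.
    """
    if len(ds_train) == 0 or len(ds_val) == 0:
        raise ValueError("empty train or validation split")

    X_train = extract_features(ds_train, clf.extractor).values
    y_train = ds_train.labels
    X_val = extract_features(ds_val, clf.extractor).values
    y_val_binary = binary_truth(ds_val)

    sample_w = None
    if per_class_loss_weights is not None:
        sample_w = np.asarray(per_class_loss_weights, dtype=np.float64)[y_train]

    clf._init_params(X_train.shape[1], label_map.n_classes)
    history = TrainHistory()
    best_acc, best_W = -1.0, clf.get_weights()
    for epoch in range(cfg.epochs):
        if sampler is not None:
            stream = list(sampler.epoch(epoch))
            X_ep = np.stack([clf.extractor(px) for _, px, _ in stream])
            y_ep = np.array([lab for _, _, lab in stream], dtype=np.intp)
            w_ep = (np.asarray(per_class_loss_weights)[y_ep]
                    if per_class_loss_weights is not None else None)
        else:
            X_ep, y_ep, w_ep = X_train, y_train, sample_w
        loss = clf.train_epoch(X_ep, y_ep, epoch, cfg, w_ep)
        val_pred = clf.predict_features(X_val)
        _, report = evaluate_binary(y_val_binary, val_pred, label_map)
        history.epoch_loss.append(loss)
        history.val_binary_accuracy.append(report.accuracy)
        if report.accuracy > best_acc:
            best_acc = report.accuracy
            best_W = clf.get_weights()
    history.best_epoch = best_epoch(history.val_binary_accuracy)
    clf.set_weights(best_W)
    return clf, history


def _identity_label_map(ds: LabeledImageSet) -> LabelMap:
    minority = ds.minority_label()
    return LabelMap(
        n_majority_clusters=1,
        original_majority_name=ds.label_names[1 - minority],
        original_minority_name=ds.label_names[minority],
    )


def run_experiment_suite(
    ds: LabeledImageSet,
    extractor: FeatureExtractor,
    cfg: TrainConfig,
    cluster_n: int = 10,
    split: SplitSpec | None = None,
    augment_spec: AugmentSpec | None = None,
) -> tuple[pd.DataFrame, dict[str, ConfusionMatrix]]:
    """Run the six configurations on a shared split and seed.

    Rows: baseline, weighted augmentation, weighted loss, and each again with
    majority clustering.  Returns a metrics table (accuracy + minority
    precision/recall/F1 per row) and per-row confusion matrices.
    """
    if not ds.is_binary:
        raise ValueError("the experiment suite requires a binary dataset")
    split = split or SplitSpec(seed=cfg.seed)
    augment_spec = augment_spec or AugmentSpec()
    ds_train, ds_val, ds_test = stratified_split(ds, split)
    y_test_binary = binary_truth(ds_test)

    # majority clustering of the training split, shared by the three
    # mciic rows (clustering is deterministic given features and seed)
    feats_train = extract_features(ds_train, extractor)
    ds_train_mc, label_map_mc, _ = partition_majority(
        ds_train, feats_train, cluster_n=cluster_n, seed=cfg.seed
    )
    label_map_id = _identity_label_map(ds_train)
    # binary training set relabeled so that minority = label 1
    ds_train_bin = ds_train.with_labels(
        binary_truth(ds_train),
        label_names=[label_map_id.original_majority_name,
                     label_map_id.original_minority_name],
    )

    rows: list[dict] = []
    matrices: dict[str, ConfusionMatrix] = {}
    for name, use_mciic, weighting in SUITE_CONFIGURATIONS:
        train_set = ds_train_mc if use_mciic else ds_train_bin
        label_map = label_map_mc if use_mciic else label_map_id
        counts = np.bincount(train_set.labels, minlength=label_map.n_classes)
        table = class_weights(counts)
        loss_w = loss_weights_for_training(table) if weighting == "weighted_clf" else None
        sampler = (weighted_augment_sampler(train_set, table, augment_spec, cfg.seed)
                   if weighting == "weighted_aug" else None)

        clf = SoftmaxClassifier(extractor, seed=cfg.seed)
        clf, history = train(train_set, ds_val, clf, cfg, label_map,
                             per_class_loss_weights=loss_w, sampler=sampler)
        test_pred = clf.predict(ds_test)
        cm, report = evaluate_binary(y_test_binary, test_pred, label_map, name)
        matrices[name] = cm
        rows.append({
            "configuration": name,
            "accuracy": report.accuracy,
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
        })
        logger.info("suite row %-22s acc=%.3f P=%.3f R=%.3f F1=%.3f (best epoch %d)",
                    name, report.accuracy, report.precision, report.recall,
                    report.f1, history.best_epoch)
    return pd.DataFrame(rows).set_index("configuration"), matrices


def plot_confusion_matrix(cm: ConfusionMatrix, path, title: str = "") -> None:
    """Write a 2×2 heatmap (rows: true negative/positive, cols: predicted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = cm.as_array()
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.imshow(arr, cmap="Blues")
    for (i, j), v in np.ndenumerate(arr):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > arr.max() / 2 else "black")
    ax.set_xticks([0, 1], ["majority", "minority"])
    ax.set_yticks([0, 1], ["majority", "minority"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
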