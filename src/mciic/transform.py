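"""The core relabeling: split the majority class of a binary dataset into Nc
k-means clusters, producing an (Nc+1)-class dataset, and fold multiclass
predictions back to binary for evaluation.

No sample is discarded: the "under-sampling" effect is purely the reduction
of the per-label count as the majority class spreads over Nc new labels.
Majority clusters get labels 0..Nc-1 and the minority class becomes label Nc,
so a prediction < Nc folds to majority (negative) and a prediction of Nc
folds to minority (positive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np

from .cluster import ElbowCurve, elbow_scan, kmeans
from .dataio import LabeledImageSet
from .features import FeatureMatrix

logger = logging.getLogger("mciic")


@dataclass(frozen=True)
class LabelMap:
    """Bookkeeping between the original binary labels and the expanded
    multiclass labels: majority clusters are 0..Nc-1, minority is Nc."""

    n_majority_clusters: int
    original_majority_name: str
    original_minority_name: str

    def __post_init__(self) -> None:
        if self.n_majority_clusters < 1:
            raise ValueError("need at least one majority cluster")

    @property
    def minority_label(self) -> int:
        return self.n_majority_clusters

    @property
    def majority_labels(self) -> list[int]:
        return list(range(self.n_majority_clusters))

    @property
    def n_classes(self) -> int:
        return self.n_majority_clusters + 1

    def label_names(self) -> list[str]:
        return [f"cluster_{i}" for i in self.majority_labels] + ["minority"]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "LabelMap":
        return cls(**json.loads(Path(path).read_text()))


def partition_majority(
    ds: LabeledImageSet,
    features: FeatureMatrix,
    cluster_n: int,
    seed: int,
    forced_k: int | None = None,
) -> tuple[LabeledImageSet, LabelMap, ElbowCurve]:
    """Relabel a binary imbalanced dataset into Nc majority clusters + minority.

    The elbow scan runs on the majority rows of ``features`` only and selects
    Nc; majority samples are then relabeled by their cluster index and all
    minority samples get label Nc.  ``forced_k`` bypasses the elbow choice
    (the scan still runs so the curve can be reported).  Total sample count
    and the multiset of image ids are unchanged.
    """
    if not ds.is_binary:
        raise ValueError("partition_majority requires a binary dataset")
    counts = ds.class_counts()
    if counts[0] == counts[1]:
        raise ValueError(
            "classes are exactly balanced; skip majority clustering and train "
            "the plain binary classifier instead"
        )
    minority = ds.minority_label()
    majority = 1 - minority

    labels = ds.labels
    maj_idx = np.flatnonzero(labels == majority)
    maj_rows = features.rows_for([ds.items[i].image_id for i in maj_idx])

    scan_n = min(cluster_n, len(maj_idx))
    curve = elbow_scan(maj_rows, cluster_n=scan_n, seed=seed)
    nc = int(forced_k) if forced_k is not None else curve.chosen_k
    if forced_k is not None:
        curve.chosen_k = nc

    model = kmeans(maj_rows, k=nc, seed=seed)
    label_map = LabelMap(
        n_majority_clusters=nc,
        original_majority_name=ds.label_names[majority],
        original_minority_name=ds.label_names[minority],
    )

    new_labels = np.full(len(ds), label_map.minority_label, dtype=np.intp)
    new_labels[maj_idx] = model.assignments
    cluster_sizes = np.bincount(model.assignments, minlength=nc)
    min_size = max(2, int(0.005 * len(maj_idx)))
    for j, size in enumerate(cluster_sizes):
        if size < min_size:
            logger.warning(
                "majority cluster %d has only %d samples (< %d); kept anyway",
                j, size, min_size,
            )
    out = ds.with_labels(
        new_labels,
        label_names=label_map.label_names(),
        provenance=f"{ds.provenance} | majority split into {nc} clusters",
    )
    return out, label_map, curve


def fold_to_binary(pred_labels: np.ndarray, label_map: LabelMap) -> np.ndarray:
    """Collapse multiclass predictions: < Nc -> 0 (majority/negative),
    == Nc -> 1 (minority/positive)."""
    pred = np.asarray(pred_labels, dtype=np.intp)
    if pred.size and (pred.min() < 0 or pred.max() > label_map.minority_label):
        raise ValueError(
            f"prediction outside [0, {label_map.minority_label}]"
        )
    return (pred == label_map.minority_label).astype(np.intp)


def binary_truth(ds: LabeledImageSet) -> np.ndarray:
    """Ground-truth binary labels of a binary set, minority coded as 1."""
    minority = ds.minority_label()
    return (ds.labels == minority).astype(np.intp)


def imbalance_ratio(majority_count: int, minority_count: int) -> float:
    """100 × minority/majority, rounded half-up to one decimal place."""
    if majority_count < 1 or minority_count < 1:
        raise ValueError("both class counts must be >= 1")
    if minority_count > majority_count:
        raise ValueError("minority count exceeds majority count; swap the roles")
    ratio = Decimal(100 * minority_count) / Decimal(majority_count)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
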