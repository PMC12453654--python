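"""Class-weight computation and stochastic image augmentation.

One inverse-frequency formula serves both weighted-loss training and
weighted augmentation:

    w_i = total_samples / (n_i * num_classes)

which satisfies sum_i n_i * w_i = total_samples identically.  Augmentation
probabilities are these weights normalized by their maximum, p_i = w_i /
max_j w_j = n_min / n_i, so the rarest class is always augmented and a class
with twice its count is augmented half the time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from skimage.transform import rotate as _rotate

from .dataio import ImageItem, LabeledImageSet


@dataclass
class ClassWeightTable:
    """Per-class counts, loss weights and augmentation probabilities."""

    counts: np.ndarray
    weights: np.ndarray
    probabilities: np.ndarray

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "count", "weight", "probability"])
            for i, (n, wt, p) in enumerate(
                zip(self.counts, self.weights, self.probabilities)
            ):
                w.writerow([i, int(n), wt, p])


@dataclass(frozen=True)
class AugmentSpec:
    """Stochastic augmentation operator ranges; all draws uniform."""

    brightness_range: tuple[float, float] = (0.75, 1.25)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    flip_probability: float = 0.5


def class_weights(counts: Sequence[int]) -> ClassWeightTable:
    """Inverse-frequency class weights and max-normalized probabilities."""
    counts_arr = np.asarray(counts, dtype=np.int64)
    if counts_arr.ndim != 1 or len(counts_arr) < 1:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(counts_arr < 1):
        raise ValueError("every class count must be >= 1")
    total = counts_arr.sum()
    weights = total / (counts_arr * len(counts_arr))
    return ClassWeightTable(
        counts=counts_arr,
        weights=weights,
        probabilities=weights / weights.max(),
    )


def loss_weights_for_training(table: ClassWeightTable) -> np.ndarray:
    """Per-class multipliers for the cross-entropy objective (the w_i as-is)."""
    return table.weights.copy()


def augment(image: np.ndarray, spec: AugmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Brightness scale, rotation about the centre, then horizontal flip.

    Brightness is clipped to the valid pixel range; rotation fills exposed
    edges with the nearest border value.  Output shape and dtype equal the
    input's.
    """
    arr = np.asarray(image)
    out = arr.astype(np.float64)

    factor = rng.uniform(*spec.brightness_range)
    out = np.clip(out * factor, 0, 255)

    angle = rng.uniform(*spec.rotation_range_deg)
    if angle != 0.0:
        out = _rotate(out / 255.0, angle, mode="edge", preserve_range=True)
        out = np.clip(out * 255.0, 0, 255)

    if rng.uniform() < spec.flip_probability:
        out = out[:, ::-1] if out.ndim == 2 else out[:, ::-1, :]

    return out.astype(arr.dtype)


def sample_augment_mask(labels: np.ndarray, probabilities: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """For each sample of class i, True with probability p_i."""
    labels = np.asarray(labels, dtype=np.intp)
    draws = rng.uniform(size=labels.shape[0])
    # p == 1 must always augment, so compare with strict less-than
    return draws < np.asarray(probabilities)[labels]


@dataclass
class WeightedAugmentSampler:
    """Per-epoch training stream with class-probability-weighted augmentation.

    Each epoch, a sample of class i is replaced (not duplicated) by its
    augmented version with probability p_i, so the epoch size stays fixed
    while rarer classes see more transformed variants.  Deterministic given
    the seed; consecutive epochs consume the stream in order.
    """

    ds: LabeledImageSet
    table: ClassWeightTable
    spec: AugmentSpec
    seed: int
    n_augmented: int = 0

    def epoch(self, epoch_index: int) -> Iterator[tuple[str, np.ndarray, int]]:
        rng = np.random.default_rng((self.seed, epoch_index))
        mask = sample_augment_mask(self.ds.labels, self.table.probabilities, rng)
        for item, do_aug in zip(self.ds, mask):
            pixels = item.pixels()
            if do_aug:
                pixels = augment(pixels, self.spec, rng)
                self.n_augmented += 1
            yield item.image_id, pixels, item.label


def weighted_augment_sampler(ds: LabeledImageSet, table: ClassWeightTable,
                             spec: AugmentSpec, seed: int) -> WeightedAugmentSampler:
    if table.probabilities is None or len(table.probabilities) == 0:
        raise ValueError("weight table has no probabilities")
    return WeightedAugmentSampler(ds=ds, table=table, spec=spec, seed=seed)
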