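"""Dataset containers, image-folder loading and stratified splitting.

The pipeline's currency is :class:`LabeledImageSet`: an ordered collection of
(image_id, pixels-or-path, label) triples plus a label vocabulary.  Images are
held lazily as file paths when loaded from disk; any consumer that needs pixel
data triggers the decode, so decode failures surface at first use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger("mciic")

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ImageItem:
    """One labeled image: decoded pixels, or a path decoded on demand."""

    image_id: str
    source: np.ndarray | Path
    label: int

    def pixels(self) -> np.ndarray:
        """Return the image as an H×W or H×W×3 uint8 array (decoding if lazy)."""
        if isinstance(self.source, np.ndarray):
            return self.source
        with Image.open(self.source) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if len(im.getbands()) >= 3 else "L")
            return np.asarray(im, dtype=np.uint8)


@dataclass
class LabeledImageSet:
    """Ordered labeled images with a label vocabulary.

    Invariants: labels lie in ``[0, len(label_names))`` and image ids are
    unique.  For a binary set the minority class is the one with the smaller
    sample count, never identified by name.
    """

    items: list[ImageItem]
    label_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if not (0 <= it.label < len(self.label_names)):
                raise ValueError(
                    f"label {it.label} of {it.image_id!r} outside "
                    f"[0, {len(self.label_names)})"
                )
            if it.image_id in seen:
                raise ValueError(f"duplicate image_id {it.image_id!r}")
            seen.add(it.image_id)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ImageItem]:
        return iter(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=np.intp)

    @property
    def image_ids(self) -> list[str]:
        return [it.image_id for it in self.items]

    def class_counts(self) -> np.ndarray:
        """Per-label sample counts, indexed by label value."""
        return np.bincount(self.labels, minlength=len(self.label_names))

    @property
    def is_binary(self) -> bool:
        return len(self.label_names) == 2

    def minority_label(self) -> int:
        """Label value with the fewest samples (binary sets; ties forbidden)."""
        if not self.is_binary:
            raise ValueError("minority_label is defined for binary sets only")
        counts = self.class_counts()
        if counts[0] == counts[1]:
            raise ValueError("classes are exactly balanced; no minority class")
        return int(np.argmin(counts))

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "LabeledImageSet":
        return LabeledImageSet(
            items=[self.items[i] for i in indices],
            label_names=list(self.label_names),
            provenance=provenance if provenance is not None else self.provenance,
        )

    def with_labels(self, new_labels: Sequence[int], label_names: list[str],
                    provenance: str | None = None) -> "LabeledImageSet":
        """Same images, new label assignment and vocabulary."""
        if len(new_labels) != len(self.items):
            raise ValueError("label vector length mismatch")
        return LabeledImageSet(
            items=[replace(it, label=int(l)) for it, l in zip(self.items, new_labels)],
            label_names=label_names,
            provenance=provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions; defaults follow the 80-10-10 split."""

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")
        if not math.isclose(self.train_frac + self.val_frac + self.test_frac, 1.0,
                            abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    data_path: str = ""
    output_path: str = "runs"
    cluster_n: int = 10
    backbone: str = "fallback:16"
    weighting: str = "none"  # none | weighted_aug | weighted_clf
    seed: int = 0
    train: "object | None" = None  # TrainConfig; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        if self.cluster_n < 1:
            raise ValueError("cluster_n must be >= 1")
        if self.weighting not in ("none", "weighted_aug", "weighted_clf"):
            raise ValueError(
                f"weighting must be none|weighted_aug|weighted_clf, got {self.weighting!r}"
            )


def load_image_folder(root_path: str | Path) -> LabeledImageSet:
    """Read an image-folder tree: one subdirectory per class, PNG/JPEG files.

    Label names are the subdirectory names in lexicographic order; items are
    ordered by (class, filename) so loading is deterministic.  Undecodable
    files are skipped with a warning; a class left empty is an error.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"image folder {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{root} must contain at least 2 class subdirectories")

    items: list[ImageItem] = []
    label_names = [d.name for d in class_dirs]
    for label, d in enumerate(class_dirs):
        n_before = len(items)
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in _IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError):
                logger.warning("skipping undecodable image %s", f)
                continue
            items.append(ImageItem(image_id=f"{d.name}/{f.name}", source=f, label=label))
        if len(items) == n_before:
            raise ValueError(f"class directory {d} contains no decodable images")
    return LabeledImageSet(items=items, label_names=label_names, provenance=str(root))


def _largest_remainder_counts(n: int, fracs: Sequence[float]) -> list[int]:
    """Split n into integer parts ~ proportional to fracs; leftover -> first."""
    raw = [n * f for f in fracs]
    base = [int(math.floor(r)) for r in raw]
    leftover = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    ds: LabeledImageSet, spec: SplitSpec
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Partition into train/val/test with per-class largest-remainder counts.

    Deterministic given ``spec.seed``; the three parts are pairwise disjoint
    and their union is the input.
    """
    rng = np.random.default_rng(spec.seed)
    labels = ds.labels
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    fracs = (spec.train_frac, spec.val_frac, spec.test_frac)
    for label in range(len(ds.label_names)):
        idx = np.flatnonzero(labels == label)
        if spec.stratified and len(idx) < 3:
            raise ValueError(
                f"class {ds.label_names[label]!r} has {len(idx)} samples; "
                "need >= 3 for a stratified 3-way split"
            )
        idx = rng.permutation(idx)
        n_train, n_val, n_test = _largest_remainder_counts(len(idx), fracs)
        parts[0].extend(idx[:n_train].tolist())
        parts[1].extend(idx[n_train:n_train + n_val].tolist())
        parts[2].extend(idx[n_train + n_val:].tolist())
    return tuple(  # type: ignore[return-value]
        ds.subset(sorted(p), provenance=f"{ds.provenance}[{name}]")
        for p, name in zip(parts, ("train", "val", "test"))
    )
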