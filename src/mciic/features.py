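"""Image -> fixed-length feature vectors through a pluggable extractor.

Two extractor contracts exist.  The default deep contract is the penultimate
embedding of an ImageNet-pretrained 18-layer residual network (512 features,
the final classification layer removed); it needs torch/torchvision plus a
weight download and is therefore optional at runtime.  The fallback extractor
(resize to a small square, grayscale, flatten, per-image standardize) is a
pure deterministic function of the pixels and is what the test suite and the
synthetic pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .dataio import LabeledImageSet

DEEP_OUTPUT_DIM = 512
# ImageNet channel statistics used by the deep preprocessing path.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class FeatureMatrix:
    """n×d feature matrix with row-aligned image ids."""

    values: np.ndarray
    ids: list[str]
    extractor_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows_for(self, image_ids: list[str]) -> np.ndarray:
        """Rows re-ordered to match ``image_ids``."""
        index = {i: r for r, i in enumerate(self.ids)}
        return self.values[[index[i] for i in image_ids]]

    def save(self, ids_path: str | Path, matrix_path: str | Path) -> None:
        Path(ids_path).write_text("\n".join(self.ids) + "\n")
        np.savetxt(matrix_path, self.values)

    @classmethod
    def load(cls, ids_path: str | Path, matrix_path: str | Path,
             extractor_tag: str = "loaded") -> "FeatureMatrix":
        ids = Path(ids_path).read_text().splitlines()
        values = np.atleast_2d(np.loadtxt(matrix_path))
        return cls(values=values, ids=ids, extractor_tag=extractor_tag)


@dataclass(frozen=True)
class FeatureExtractor:
    """Deterministic image -> vector map with a fixed output dimension."""

    name: str
    output_dim: int
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        vec = np.asarray(self.fn(pixels), dtype=np.float64)
        if vec.shape != (self.output_dim,):
            raise ValueError(
                f"extractor {self.name!r} produced shape {vec.shape}, "
                f"expected ({self.output_dim},)"
            )
        return vec


def _to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse to single-channel float; 3-channel uses the luma weights."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unsupported image shape {arr.shape}")


def _resize_bilinear(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize of a 2-D array to side×side (align-corners sampling)."""
    h, w = img.shape
    if (h, w) == (side, side):
        return img
    ys = np.linspace(0, h - 1, side)
    xs = np.linspace(0, w - 1, side)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    top = img[np.ix_(y0, x0)] * (1 - wx) + img[np.ix_(y0, x1)] * wx
    bot = img[np.ix_(y1, x0)] * (1 - wx) + img[np.ix_(y1, x1)] * wx
    return top * (1 - wy) + bot * wy


def make_fallback_extractor(side: int = 16) -> FeatureExtractor:
    """Resize to side×side grayscale, flatten, standardize per image.

    A zero-variance (constant) image standardizes to the zero vector: the
    variance in the denominator is guarded to 1 to avoid division by zero.
    """
    if side < 2:
        raise ValueError("side must be >= 2")

    def fn(pixels: np.ndarray) -> np.ndarray:
        gray = _resize_bilinear(_to_grayscale(pixels), side)
        flat = gray.ravel()
        sd = flat.std()
        return (flat - flat.mean()) / (sd if sd > 0 else 1.0)

    return FeatureExtractor(name=f"fallback:{side}", output_dim=side * side, fn=fn)


def make_deep_extractor() -> FeatureExtractor:
    """Penultimate-layer embedding of a pretrained 18-layer residual network.

    Eval-time preprocessing: resize to 256, center-crop 224, scale to [0,1],
    normalize with the ImageNet channel mean/std.  Requires torch and
    torchvision with downloadable pretrained weights; raises a clear error
    when they are absent so download-free installs keep working.
    """
    try:
        import torch
        from torchvision import models, transforms
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "the deep backbone needs torch and torchvision; install them or "
            "use the fallback extractor (backbone='fallback:<side>')"
        ) from exc

    model = models.resnet18(weights=models.ResNet18_Weights.IMAGENET1K_V1)
    model.fc = torch.nn.Identity()
    model.eval()
    pre = transforms.Compose([
        transforms.ToPILImage(),
        transforms.Resize(256),
        transforms.CenterCrop(224),
        transforms.ToTensor(),
        transforms.Normalize(IMAGENET_MEAN, IMAGENET_STD),
    ])

    def fn(pixels: np.ndarray) -> np.ndarray:  # pragma: no cover - optional
        arr = np.asarray(pixels, dtype=np.uint8)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        with torch.no_grad():
            out = model(pre(arr).unsqueeze(0))
        return out.squeeze(0).numpy().astype(np.float64)

    return FeatureExtractor(name="deep18", output_dim=DEEP_OUTPUT_DIM, fn=fn)


def make_extractor(backbone: str) -> FeatureExtractor:
    """Resolve a config backbone string: ``deep18`` or ``fallback:<side>``."""
    if backbone == "deep18":
        return make_deep_extractor()
    if backbone.startswith("fallback:"):
        return make_fallback_extractor(int(backbone.split(":", 1)[1]))
    raise ValueError(f"unknown backbone {backbone!r}")


def extract_features(ds: LabeledImageSet, ex: FeatureExtractor) -> FeatureMatrix:
    """Apply the extractor to every image; row i corresponds to item i.

    Grayscale/3-channel mismatches are handled inside the extractors (channel
    replication or luma collapse); a decode failure is re-raised naming the
    offending image id.
    """
    rows = np.empty((len(ds), ex.output_dim), dtype=np.float64)
    for i, item in enumerate(ds):
        try:
            rows[i] = ex(item.pixels())
        except (OSError, ValueError) as exc:
            raise ValueError(f"feature extraction failed for {item.image_id!r}: {exc}") from exc
    return FeatureMatrix(values=rows, ids=ds.image_ids, extractor_tag=ex.name)
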