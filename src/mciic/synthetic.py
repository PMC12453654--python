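"""Synthetic imbalanced image sets with planted majority-mode structure.

Majority images are drawn round-robin from ``n_modes`` distinct parametric
patterns — Gaussian intensity blobs at well-separated positions — plus
additive pixel noise, so the majority class is multi-modal in exactly the
way majority clustering exploits.  Minority images use a held-out pattern
(oriented stripes) that no majority mode resembles, so minority-vs-majority
difficulty is governed by the imbalance alone.  Default sizes mirror a rare
minority regime (around 5% imbalance, three majority modes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .dataio import ImageItem, LabeledImageSet

MAJORITY_CLASS_NAME = "majority"
MINORITY_CLASS_NAME = "minority"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the implied imbalance ratio is
    100 * n_minority / n_majority percent."""

    n_majority: int = 200
    n_minority: int = 10
    n_modes: int = 3
    side: int = 32
    noise_sigma: float = 8.0  # pixel-intensity s.d. on the 0-255 scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minority < 1 or self.n_majority <= self.n_minority:
            raise ValueError("need n_majority > n_minority >= 1")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.side < 8:
            raise ValueError("side must be >= 8 to render the patterns")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _blob_pattern(side: int, mode: int, n_modes: int) -> np.ndarray:
    """Gaussian blob centred at a mode-specific position on a ring."""
    angle = 2.0 * np.pi * mode / max(n_modes, 1)
    r = side / 3.5
    cy = side / 2 + r * np.sin(angle)
    cx = side / 2 + r * np.cos(angle)
    yy, xx = np.mgrid[0:side, 0:side]
    sigma = side / 8.0
    return 220.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


def _stripe_pattern(side: int) -> np.ndarray:
    """Diagonal sinusoidal stripes — the held-out minority pattern."""
    yy, xx = np.mgrid[0:side, 0:side]
    phase = 2.0 * np.pi * (yy + xx) / (side / 2.0)
    return 110.0 + 100.0 * np.sin(phase)


def generate(spec: SyntheticSpec) -> tuple[LabeledImageSet, np.ndarray]:
    """Render the image set; returns it with per-majority-image mode labels.

    Majority images cycle round-robin through the planted modes; the
    returned mode array has one entry per majority item (-1 for minority
    rows is never needed because the set lists majority first).  Everything
    is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    patterns = [_blob_pattern(spec.side, m, spec.n_modes) for m in range(spec.n_modes)]
    minority_pattern = _stripe_pattern(spec.side)

    items: list[ImageItem] = []
    modes = np.empty(spec.n_majority, dtype=np.intp)
    for i in range(spec.n_majority):
        mode = i % spec.n_modes
        modes[i] = mode
        img = patterns[mode] + rng.normal(0.0, spec.noise_sigma, (spec.side, spec.side))
        items.append(ImageItem(
            image_id=f"{MAJORITY_CLASS_NAME}/maj_{i:05d}.png",
            source=np.clip(img, 0, 255).astype(np.uint8),
            label=0,
        ))
    for i in range(spec.n_minority):
        img = minority_pattern + rng.normal(0.0, spec.noise_sigma, (spec.side, spec.side))
        items.append(ImageItem(
            image_id=f"{MINORITY_CLASS_NAME}/min_{i:05d}.png",
            source=np.clip(img, 0, 255).astype(np.uint8),
            label=1,
        ))
    ds = LabeledImageSet(
        items=items,
        label_names=[MAJORITY_CLASS_NAME, MINORITY_CLASS_NAME],
        provenance=f"synthetic(seed={spec.seed}, modes={spec.n_modes})",
    )
    return ds, modes


def write_image_folder(ds: LabeledImageSet, root: str | Path,
                       manifest: dict | None = None) -> Path:
    """Write the set as PNGs under class-named subdirectories.

    ``load_image_folder`` on the result round-trips counts, labels and pixel
    content exactly.  A manifest JSON (with per-file checksums) is written
    beside the tree.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for item in ds:
        class_dir = root / ds.label_names[item.label]
        class_dir.mkdir(exist_ok=True)
        name = item.image_id.split("/")[-1]
        path = class_dir / name
        Image.fromarray(item.pixels()).save(path, format="PNG")
        checksums[f"{class_dir.name}/{name}"] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()
    payload = {"checksums": checksums, **(manifest or {})}
    (root / "manifest.json").write_text(json.dumps(payload, indent=2) + "\n")
    return root


def generate_to_folder(spec: SyntheticSpec, root: str | Path) -> Path:
    ds, modes = generate(spec)
    return write_image_folder(
        ds, root, manifest={"spec": asdict(spec), "majority_modes": modes.tolist()}
    )
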