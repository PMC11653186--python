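"""Class-per-directory image datasets: loading, splitting, augmentation.

The on-disk layout is the public chest-radiograph convention::

    root/{train,test,val}/{NORMAL,PNEUMONIA}/*.png|jpg|jpeg

Images are decoded to single-channel float arrays in [0, 1] at a common
target size.  Augmentation follows the usual radiograph recipe: random
rotation up to 20 degrees, center-anchored zoom in [0.9, 1.1], shifts up to
10% of each dimension, and horizontal flips — applied to the training split
only.  Out-of-frame pixels are filled with the edge value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.transform import AffineTransform, warp

__all__ = [
    "LabeledImageSet",
    "AugmentSpec",
    "DataError",
    "CLASS_DIRS",
    "SPLITS",
    "load_dataset",
    "stratified_split",
    "augment",
]

logger = logging.getLogger(__name__)

CLASS_DIRS = ("NORMAL", "PNEUMONIA")  # label 0, label 1
SPLITS = ("train", "test", "val")
_EXTENSIONS = (".png", ".jpg", ".jpeg")


class DataError(ValueError):
    """Dataset layout or content problem."""


@dataclass
class LabeledImageSet:
    """Images plus binary labels (0 = normal, 1 = pneumonia-like)."""

    images: list[np.ndarray]
    labels: np.ndarray
    split: str = "train"
    source: str = "loaded"  # loaded | synthetic

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise DataError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def stack(self) -> np.ndarray:
        """(N, H, W) array; requires all images the same shape."""
        return np.stack(self.images) if self.images else np.empty((0, 0, 0))


@dataclass(frozen=True)
class AugmentSpec:
    """Transform ranges; each copy samples uniformly within them."""

    rotation_deg: float = 20.0
    zoom_frac: float = 0.1
    shift_frac: float = 0.1
    hflip_prob: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "AugmentSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.pop("multiplier", None)
        return cls(**payload)


def _load_image(path: Path, target_size: tuple[int, int]) -> np.ndarray:
    with Image.open(path) as img:
        gray = img.convert("L")
        # PIL size is (width, height)
        resized = gray.resize((target_size[1], target_size[0]), Image.BILINEAR)
        return np.asarray(resized, dtype=np.float64) / 255.0


def load_dataset(
    root_dir, target_size: tuple[int, int] = (64, 64)
) -> dict[str, LabeledImageSet]:
    """Load every split under ``root_dir`` into memory.

    Raises :class:`DataError` for a missing or empty class directory;
    unreadable files are skipped with a warning and counted in the log.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise DataError(f"dataset root {root} is not a directory")
    out: dict[str, LabeledImageSet] = {}
    for split in SPLITS:
        split_dir = root / split
        if not split_dir.is_dir():
            continue
        images: list[np.ndarray] = []
        labels: list[int] = []
        for label, cls in enumerate(CLASS_DIRS):
            cls_dir = split_dir / cls
            if not cls_dir.is_dir():
                raise DataError(f"missing class directory {cls_dir}")
            files = sorted(
                p for p in cls_dir.iterdir() if p.suffix.lower() in _EXTENSIONS
            )
            if not files:
                raise DataError(f"empty class directory {cls_dir}")
            skipped = 0
            for path in files:
                try:
                    images.append(_load_image(path, target_size))
                except Exception as exc:  # noqa: BLE001 - skip-and-count contract
                    skipped += 1
                    warnings.warn(f"skipping unreadable image {path}: {exc}")
            n_ok = len(files) - skipped
            labels.extend([label] * n_ok)
            logger.info(
                "%s/%s: %d images loaded, %d skipped", split, cls, n_ok, skipped
            )
        out[split] = LabeledImageSet(images, np.array(labels), split=split)
    if not out:
        raise DataError(f"no split directories found under {root}")
    return out


def stratified_split(
    pool: LabeledImageSet,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Split into (train, test, val) preserving per-class proportions
    within one image, via a seeded shuffle and largest-remainder counts."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for label in np.unique(pool.labels):
        idx = np.flatnonzero(pool.labels == label)
        if len(idx) < len(fractions):
            raise DataError(
                f"class {label} has {len(idx)} images, fewer than {len(fractions)} splits"
            )
        rng.shuffle(idx)
        raw = [f * len(idx) for f in fractions]
        counts = [int(np.floor(r)) for r in raw]
        remainders = [r - c for r, c in zip(raw, counts)]
        for j in np.argsort(remainders)[::-1][: len(idx) - sum(counts)]:
            counts[j] += 1
        start = 0
        for part, n in zip(parts, counts):
            part.extend(idx[start : start + n].tolist())
            start += n
    sets = []
    for split_name, part in zip(SPLITS, parts):
        sets.append(
            LabeledImageSet(
                images=[pool.images[i] for i in part],
                labels=pool.labels[np.array(part, dtype=int)]
                if part
                else np.array([], dtype=int),
                split=split_name,
                source=pool.source,
            )
        )
    return tuple(sets)


def _random_transform(
    image: np.ndarray, spec: AugmentSpec, rng: np.random.Generator
) -> np.ndarray:
    """One augmented copy: hflip, then a center-anchored rotate+zoom+shift
    affine warp with edge fill."""
    h, w = image.shape[:2]
    out = image
    if rng.random() < spec.hflip_prob:
        out = out[:, ::-1]

    angle = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    scale = 1.0 + rng.uniform(-spec.zoom_frac, spec.zoom_frac)
    dy = rng.uniform(-spec.shift_frac, spec.shift_frac) * h
    dx = rng.uniform(-spec.shift_frac, spec.shift_frac) * w

    if angle == 0.0 and scale == 1.0 and dx == 0.0 and dy == 0.0:
        return out.copy()

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # rotate and zoom about the image center, then translate
    tform = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, scale=(scale, scale))
        + AffineTransform(translation=center + np.array([dx, dy]))
    )
    warped = warp(out, tform.inverse, mode="edge", order=1, preserve_range=True)
    return np.clip(warped, 0.0, 1.0)


def augment(
    dataset: LabeledImageSet,
    spec: AugmentSpec,
    multiplier: int,
    rng: np.random.Generator,
) -> LabeledImageSet:
    """Originals plus ``multiplier`` transformed copies of each image;
    labels inherited, intensities kept in [0, 1]."""
    if multiplier < 0 or int(multiplier) != multiplier:
        raise DataError(f"multiplier must be a nonnegative integer, got {multiplier}")
    images = list(dataset.images)
    labels = list(dataset.labels)
    for _ in range(int(multiplier)):
        for img, lab in zip(dataset.images, dataset.labels):
            images.append(_random_transform(img, spec, rng))
            labels.append(int(lab))
    return LabeledImageSet(
        images=images,
        labels=np.array(labels, dtype=int),
        split=dataset.split,
        source=dataset.source,
    )
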