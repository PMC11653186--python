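"""Two-class synthetic grayscale images with tunable separability.

Both classes share a smooth low-frequency background plus pixel noise; the
positive class additionally carries a small number of soft, localized
bright blobs — the statistical signature of opacities/consolidations in a
diseased radiograph.  Raising the blob intensity lift makes the task
easier; lift 0 makes the classes distributionally identical.  No anatomical
realism is attempted: the generator exists to give the search loop a task
whose difficulty is known and certifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import CLASS_DIRS, DataError, LabeledImageSet

__all__ = [
    "SynthSpec",
    "generate",
    "write_dataset_tree",
    "threshold_oracle_accuracy",
]


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    ``lesion_radius`` is a (lo, hi) range as a fraction of image width;
    ``intensity_lift`` is the blob peak brightness added on top of the
    background, in [0, 1].
    """

    n_per_class: int = 200
    image_size: tuple[int, int] = (32, 32)
    background_smoothness: float = 4.0  # gaussian sigma in pixels
    background_level: tuple[float, float] = (0.25, 0.55)
    lesion_count: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (0.08, 0.2)
    intensity_lift: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        h, w = self.image_size
        if h < 2 or w < 2:
            raise ValueError(f"image_size too small: {self.image_size}")
        if not 0.0 <= self.intensity_lift <= 1.0:
            raise ValueError("intensity_lift must be in [0, 1]")
        if self.lesion_count[0] < 1 or self.lesion_count[0] > self.lesion_count[1]:
            raise ValueError(f"bad lesion_count range {self.lesion_count}")
        lo, hi = self.lesion_radius
        if not 0 < lo <= hi:
            raise ValueError(f"bad lesion_radius range {self.lesion_radius}")
        if hi >= 1.0:
            raise ValueError("lesion radius must be smaller than the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SynthSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload = payload.get("synth", payload)
        for key in ("image_size", "background_level", "lesion_count", "lesion_radius"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _background(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field with a fixed per-image mean.

    The field is standardized (zero mean, unit variance per image) so the
    class-0 image mean is pinned at the middle of ``background_level``;
    separability between the classes is then carried entirely by the
    lesions' bright-pixel mass rather than by exposure drift.
    """
    h, w = spec.image_size
    field = gaussian_filter(rng.standard_normal((h, w)), spec.background_smoothness)
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    lo, hi = spec.background_level
    # ~99.7% of pixels inside [lo, hi]
    return (lo + hi) / 2.0 + (hi - lo) / 6.0 * field


def _add_lesions(img: np.ndarray, spec: SynthSpec, rng: np.random.Generator) -> None:
    h, w = img.shape
    n = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    for _ in range(n):
        radius = rng.uniform(*spec.lesion_radius) * w
        # keep centers inside the frame with a small margin
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        yy, xx = np.mgrid[0:h, 0:w]
        # mildly elliptical, radially decaying profile
        ay = rng.uniform(0.7, 1.3)
        ax = 1.0 / ay
        r2 = (ay * (yy - cy)) ** 2 + (ax * (xx - cx)) ** 2
        img += spec.intensity_lift * np.exp(-r2 / (2.0 * radius**2))


def generate(spec: SynthSpec) -> LabeledImageSet:
    """Balanced two-class image set, seeded and byte-reproducible.

    Class 0 = background + noise; class 1 = the same plus bright blobs.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for label in (0, 1):
        for _ in range(spec.n_per_class):
            img = _background(spec, rng)
            if label == 1:
                _add_lesions(img, spec, rng)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(label)
    return LabeledImageSet(
        images=images, labels=np.array(labels, dtype=int), split="train",
        source="synthetic",
    )


def write_dataset_tree(dataset: LabeledImageSet, root_dir) -> Path:
    """Write 8-bit PNGs in the ``{split}/{NORMAL,PNEUMONIA}`` layout that
    :func:`evocnn.data.load_dataset` consumes."""
    root = Path(root_dir)
    split_dir = root / dataset.split
    for cls in CLASS_DIRS:
        (split_dir / cls).mkdir(parents=True, exist_ok=True)
    counters = [0, 0]
    for img, label in zip(dataset.images, dataset.labels):
        cls = CLASS_DIRS[int(label)]
        name = f"{cls.lower()}_{counters[int(label)]:05d}.png"
        counters[int(label)] += 1
        arr = np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(split_dir / cls / name)
    return root


def threshold_oracle_accuracy(
    train: LabeledImageSet, test: LabeledImageSet
) -> float:
    """Test accuracy of the best mean-intensity threshold rule.

    The threshold is chosen by brute-force sweep on the training split
    (midpoints between consecutive sorted image means, both polarities);
    this certifies separability independently of any trained network.
    """
    if len(train) == 0 or len(test) == 0:
        raise DataError("threshold oracle needs non-empty train and test sets")
    m_train = np.array([img.mean() for img in train.images])
    m_test = np.array([img.mean() for img in test.images])
    order = np.argsort(m_train)
    sorted_means = m_train[order]
    cuts = np.concatenate(
        [[sorted_means[0] - 1.0], (sorted_means[1:] + sorted_means[:-1]) / 2.0,
         [sorted_means[-1] + 1.0]]
    )
    best_acc, best_cut, best_sign = -1.0, 0.0, 1
    y = train.labels
    for cut in cuts:
        for sign in (1, -1):
            pred = (sign * m_train > sign * cut).astype(int)
            acc = float(np.mean(pred == y))
            if acc > best_acc:
                best_acc, best_cut, best_sign = acc, float(cut), sign
    pred_test = (best_sign * m_test > best_sign * best_cut).astype(int)
    return float(np.mean(pred_test == test.labels))
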