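"""Dataset loading, stratified splitting, and augmentation."""

import numpy as np
import pytest
from PIL import Image

from evocnn import (
    AugmentSpec,
    LabeledImageSet,
    augment,
    load_dataset,
    stratified_split,
)
from evocnn.data import DataError


def _write_tree(root, per_class=2, size=(12, 10), value=128, splits=("train",)):
    """Tiny PNG tree in the {split}/{NORMAL,PNEUMONIA} layout."""
    rng = np.random.default_rng(0)
    for split in splits:
        for cls in ("NORMAL", "PNEUMONIA"):
            d = root / split / cls
            d.mkdir(parents=True, exist_ok=True)
            for i in range(per_class):
                arr = (
                    np.full(size, value, dtype=np.uint8)
                    if value is not None
                    else rng.integers(0, 256, size=size, dtype=np.uint8)
                )
                Image.fromarray(arr, mode="L").save(d / f"img_{i}.png")


class TestLoadDataset:
    def test_counts_by_construction(self, tmp_path):
        _write_tree(tmp_path, per_class=2)
        data = load_dataset(tmp_path, target_size=(8, 8))
        assert set(data) == {"train"}
        assert len(data["train"]) == 4
        assert data["train"].class_counts() == (2, 2)

    def test_all_white_image_scales_to_one(self, tmp_path):
        _write_tree(tmp_path, per_class=1, value=255)
        data = load_dataset(tmp_path, target_size=(8, 8))
        for img in data["train"].images:
            assert np.all(img == 1.0)

    def test_images_resized_and_in_unit_range(self, tmp_path):
        _write_tree(tmp_path, per_class=2, value=None, size=(20, 30))
        data = load_dataset(tmp_path, target_size=(8, 8))
        for img in data["train"].images:
            assert img.shape == (8, 8)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_empty_class_dir_is_an_error(self, tmp_path):
        _write_tree(tmp_path, per_class=1)
        for f in (tmp_path / "train" / "PNEUMONIA").iterdir():
            f.unlink()
        with pytest.raises(DataError, match="PNEUMONIA"):
            load_dataset(tmp_path, target_size=(8, 8))

    def test_unreadable_file_skipped_with_warning(self, tmp_path):
        _write_tree(tmp_path, per_class=2)
        (tmp_path / "train" / "NORMAL" / "junk.png").write_bytes(b"not a png")
        with pytest.warns(UserWarning, match="junk.png"):
            data = load_dataset(tmp_path, target_size=(8, 8))
        assert len(data["train"]) == 4

    def test_missing_root_is_an_error(self, tmp_path):
        with pytest.raises(DataError):
            load_dataset(tmp_path / "nope", target_size=(8, 8))


class TestStratifiedSplit:
    def _pool(self, n, seed=0):
        rng = np.random.default_rng(seed)
        images = [rng.random((4, 4)) for _ in range(n)]
        labels = np.array([i % 2 for i in range(n)])
        return LabeledImageSet(images, labels)

    def test_reference_corpus_fractions_are_exact(self):
        """5,856 images at the historical fractions give exactly
        (4192, 624, 1040)."""
        pool = self._pool(5856)
        fr = (4192 / 5856, 624 / 5856, 1040 / 5856)
        train, test, val = stratified_split(pool, fr, seed=0)
        assert (len(train), len(test), len(val)) == (4192, 624, 1040)

    def test_everything_in_train(self):
        pool = self._pool(10)
        train, test, val = stratified_split(pool, (1.0, 0.0, 0.0), seed=0)
        assert (len(train), len(test), len(val)) == (10, 0, 0)

    def test_balanced_within_one_image(self):
        pool = self._pool(1000)
        train, test, val = stratified_split(pool, (0.8, 0.1, 0.1), seed=1)
        for part in (train, test, val):
            n0, n1 = part.class_counts()
            assert abs(n0 - n1) <= 1

    def test_disjoint_and_exhaustive(self):
        pool = self._pool(100, seed=3)
        # tag each image with a unique value to track identity
        for i, img in enumerate(pool.images):
            img[0, 0] = i
        parts = stratified_split(pool, (0.6, 0.2, 0.2), seed=5)
        seen = [int(img[0, 0]) for part in parts for img in part.images]
        assert sorted(seen) == list(range(100))

    def test_bad_fractions_rejected(self):
        with pytest.raises(DataError, match="sum to 1"):
            stratified_split(self._pool(10), (0.5, 0.2, 0.2), seed=0)

    def test_class_smaller_than_split_count_rejected(self):
        images = [np.zeros((4, 4))] * 3
        pool = LabeledImageSet(images, np.array([0, 0, 1]))
        with pytest.raises(DataError, match="fewer"):
            stratified_split(pool, (0.4, 0.3, 0.3), seed=0)

    def test_seeded_shuffle_reproducible(self):
        pool = self._pool(50, seed=2)
        a = stratified_split(pool, (0.6, 0.2, 0.2), seed=9)
        b = stratified_split(pool, (0.6, 0.2, 0.2), seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.labels, pb.labels)
            for ia, ib in zip(pa.images, pb.images):
                assert np.array_equal(ia, ib)


class TestAugment:
    def _set(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        images = [rng.random((16, 16)) for _ in range(n)]
        labels = np.array([i % 2 for i in range(n)])
        return LabeledImageSet(images, labels, split="train")

    def test_multiplier_zero_is_identity(self, rng):
        ds = self._set()
        out = augment(ds, AugmentSpec(), 0, rng)
        assert len(out) == len(ds)
        for a, b in zip(out.images, ds.images):
            assert np.array_equal(a, b)

    def test_multiplier_one_doubles_and_keeps_originals_first(self, rng):
        ds = self._set()
        out = augment(ds, AugmentSpec(), 1, rng)
        assert len(out) == 2 * len(ds)
        for a, b in zip(out.images[: len(ds)], ds.images):
            assert np.array_equal(a, b)
        assert np.array_equal(out.labels[len(ds) :], ds.labels)

    def test_identity_transform_reproduces_originals(self, rng):
        """All ranges zero and flip probability zero: the transformed
        copies must equal the originals pixel for pixel."""
        ds = self._set()
        spec = AugmentSpec(rotation_deg=0.0, zoom_frac=0.0, shift_frac=0.0, hflip_prob=0.0)
        out = augment(ds, spec, 1, rng)
        for orig, copy in zip(ds.images, out.images[len(ds) :]):
            assert np.array_equal(orig, copy)

    def test_labels_and_range_preserved(self, rng):
        ds = self._set()
        out = augment(ds, AugmentSpec(), 2, rng)
        assert np.array_equal(out.labels[: len(ds)], ds.labels)
        for img in out.images:
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_flip_only_is_exact_mirror(self):
        ds = self._set(n=1)
        spec = AugmentSpec(rotation_deg=0.0, zoom_frac=0.0, shift_frac=0.0, hflip_prob=1.0)
        out = augment(ds, spec, 1, np.random.default_rng(0))
        assert np.array_equal(out.images[1], ds.images[0][:, ::-1])

    def test_seeded_reproducibility(self):
        ds = self._set()
        a = augment(ds, AugmentSpec(), 1, np.random.default_rng(7))
        b = augment(ds, AugmentSpec(), 1, np.random.default_rng(7))
        for ia, ib in zip(a.images, b.images):
            assert np.array_equal(ia, ib)

    def test_negative_multiplier_rejected(self, rng):
        with pytest.raises(DataError):
            augment(self._set(), AugmentSpec(), -1, rng)
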