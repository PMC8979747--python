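"""Phantom generation, oversampling accounting, and augmentation geometry."""

import numpy as np
import pytest
from skimage import transform as sktransform

from dyndet.data_synth import (
    PhantomConfig,
    augment,
    generate_dataset,
    geometric_transform,
    oversample,
    oversampled_counts,
    random_augmentation,
    split_dataset,
)
from dyndet.exceptions import ConfigError, InvalidParameterError
from dyndet.scheduler import BoundingBox, iou


class TestGeneration:
    def test_manifest_matches_requested_counts(self, small_phantoms):
        m = small_phantoms.manifest
        assert m.original_counts == (4, 3, 3)
        assert m.total == 10 == len(small_phantoms)
        counts = [small_phantoms.image_classes.count(c) for c in range(3)]
        assert tuple(counts) == (4, 3, 3)

    def test_seeded_generation_is_byte_identical(self):
        cfg = PhantomConfig(image_size=64, class_counts=(2, 1, 1), seed=5)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for ia, ib in zip(a.images, b.images):
            assert ia.tobytes() == ib.tobytes()
        assert a.boxes == b.boxes

    def test_boxes_cover_lesion_foreground(self, small_phantoms):
        """Every annotation box contains >= 90% of its lesion's pixels."""
        for boxes, masks in zip(small_phantoms.boxes, small_phantoms.masks):
            for box, mask in zip(boxes, masks):
                inside = mask[int(box.y_min):int(box.y_max),
                              int(box.x_min):int(box.x_max)]
                assert inside.sum() >= 0.9 * mask.sum()

    def test_lesion_count_in_range(self, small_phantoms):
        lo, hi = 1, 3
        for boxes in small_phantoms.boxes:
            assert lo <= len(boxes) <= hi

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            PhantomConfig(image_size=16).validate()
        with pytest.raises(ConfigError):
            PhantomConfig(oversample_factors=(0, 1, 1)).validate()


class TestOversampling:
    def test_reference_imbalance_arithmetic(self):
        """The emulated study's counts: 3x and 8x rebalancing of minorities."""
        assert oversampled_counts((2273, 845, 324), (1, 3, 8)) == (2273, 2535, 2592)
        assert sum(oversampled_counts((2273, 845, 324), (1, 1, 1))) == 3442

    def test_factor_one_is_identity(self, small_phantoms):
        out = oversample(small_phantoms, (1, 1, 1), seed=0)
        assert len(out) == len(small_phantoms)
        for ia, ib in zip(out.images, small_phantoms.images):
            assert ia.tobytes() == ib.tobytes()

    def test_copies_beyond_first_are_augmented(self, small_phantoms):
        out = oversample(small_phantoms, (1, 2, 3), seed=0)
        # 4*1 + 3*2 + 3*3 images
        assert len(out) == 19
        assert out.manifest.post_counts == (4, 6, 9)
        augmented = [r for r in out.manifest.records if r["augmented"]]
        assert len(augmented) == 3 * 1 + 3 * 2
        # augmented copies are not pixel-identical duplicates of their source
        for r in augmented:
            src = small_phantoms.images[r["source_index"]]
            assert out.images[r["index"]].tobytes() != src.tobytes()

    def test_manifest_conservation(self, small_phantoms):
        out = oversample(small_phantoms, (2, 3, 4), seed=1)
        m = out.manifest
        assert m.total == sum(m.post_counts)
        assert m.post_counts == tuple(
            c * f for c, f in zip(m.original_counts, m.oversample_factors))

    def test_invalid_factors_rejected(self, small_phantoms):
        with pytest.raises(InvalidParameterError):
            oversample(small_phantoms, (0, 1, 1))


class TestAugment:
    def test_hflip_is_involution(self, small_phantoms):
        img, boxes = small_phantoms.images[0], small_phantoms.boxes[0]
        once_img, once_boxes = augment(img, boxes, "hflip", {})
        twice_img, twice_boxes = augment(once_img, once_boxes, "hflip", {})
        assert twice_img.tobytes() == img.tobytes()
        for a, b in zip(twice_boxes, boxes):
            assert a.as_array() == pytest.approx(b.as_array())

    def test_hflip_box_mapping(self):
        img = np.zeros((100, 100), dtype=np.float32)
        box = BoundingBox(10, 20, 30, 40)
        _, out = augment(img, [box], "hflip", {})
        assert out[0].as_array() == pytest.approx([70, 20, 90, 40])

    def test_gamma_one_is_identity(self, small_phantoms):
        img, boxes = small_phantoms.images[0], small_phantoms.boxes[0]
        out_img, out_boxes = augment(img, boxes, "gamma", {"gamma": 1.0})
        np.testing.assert_allclose(out_img, img, atol=1e-6)
        assert out_boxes == list(boxes)

    def test_photometric_ops_keep_boxes(self, small_phantoms):
        img, boxes = small_phantoms.images[1], small_phantoms.boxes[1]
        for op, params in (("gamma", {"gamma": 1.3}), ("hist_eq", {})):
            _, out_boxes = augment(img, boxes, op, params)
            assert out_boxes == list(boxes)

    @pytest.mark.parametrize("op,params", [
        ("hflip", {}),
        ("vflip", {}),
        ("rotate", {"angle": 12.0}),
        ("rotate", {"angle": -15.0}),
        ("shear", {"angle": 10.0}),
        ("shear", {"angle": -8.0}),
    ])
    def test_boxes_track_warped_masks(self, small_phantoms, op, params):
        """Augmented boxes vs boxes re-derived from warped lesion masks:
        IoU >= 0.8 (interpolation tolerance)."""
        tform = geometric_transform(op, params, small_phantoms.images[0].shape)
        for img, boxes, masks in zip(small_phantoms.images[:6],
                                     small_phantoms.boxes[:6],
                                     small_phantoms.masks[:6]):
            _, out_boxes = augment(img, boxes, op, params)
            assert len(out_boxes) == len(boxes)
            for box, mask in zip(out_boxes, masks):
                warped = sktransform.warp(mask.astype(float), tform.inverse,
                                          order=0, mode="constant") > 0.5
                if not warped.any():
                    continue
                rows = np.any(warped, axis=1)
                cols = np.any(warped, axis=0)
                y0, y1 = np.where(rows)[0][[0, -1]]
                x0, x1 = np.where(cols)[0][[0, -1]]
                ref = BoundingBox(x0, y0, x1 + 1, y1 + 1)
                assert iou(box, ref) >= 0.8

    def test_boxes_stay_inside_canvas(self, small_phantoms):
        rng = np.random.default_rng(0)
        h, w = small_phantoms.images[0].shape
        for _ in range(20):
            op, params = random_augmentation(rng)
            _, boxes = augment(small_phantoms.images[0],
                               small_phantoms.boxes[0], op, params)
            for b in boxes:
                assert 0 <= b.x_min < b.x_max <= w
                assert 0 <= b.y_min < b.y_max <= h

    def test_unknown_op_rejected(self, small_phantoms):
        with pytest.raises(InvalidParameterError):
            augment(small_phantoms.images[0], [], "posterize", {})


class TestSplit:
    def test_stratified_split_partitions_dataset(self):
        ds = generate_dataset(PhantomConfig(image_size=64, class_counts=(10, 6, 4),
                                            seed=2))
        train, val, test = split_dataset(ds, (0.5, 0.25, 0.25), seed=3)
        assert len(train) + len(val) + len(test) == len(ds)
        assert train.manifest.original_counts == (5, 3, 2)
        # deterministic given the seed
        train2, _, _ = split_dataset(ds, (0.5, 0.25, 0.25), seed=3)
        assert train.manifest.records == train2.manifest.records
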