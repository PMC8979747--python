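"""Synthetic lesion phantoms: generation, class-imbalance oversampling, and
the augmentation family used to synthesize oversampled copies.

The generator emulates the *structure* of a three-class lesion-detection CT
study — grayscale images, one to a few boxed lesions per image, a heavy class
imbalance (defaults 2273 : 845 : 324) — without attempting radiological
realism. The three classes are separable by shape/texture family:

* class 0 ("round"): a single smooth bright ellipse;
* class 1 ("spiculated"): a star-shaped lesion whose radius is modulated by
  an angular cosine, giving spiky margins;
* class 2 ("clustered"): several small bright foci grouped under one box.

Every lesion gets a tight axis-aligned box derived from its binary mask.
Minority classes are balanced by oversampling with augmented copies (flips,
rotation, shear, gamma transformation, histogram equalization) rather than
pixel-identical duplicates; default factors (1, 3, 8) match the ~3x and ~8x
imbalance of the emulated study. All randomness flows from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import exposure, transform

from dyndet.exceptions import ConfigError, InvalidParameterError
from dyndet.scheduler import BoundingBox

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "DatasetManifest",
    "DetectionDataset",
    "generate_dataset",
    "oversampled_counts",
    "oversample",
    "augment",
    "random_augmentation",
    "geometric_transform",
    "split_dataset",
    "CLASS_NAMES",
]

CLASS_NAMES = ("round", "spiculated", "clustered")

AUGMENT_OPS = ("hflip", "vflip", "rotate", "shear", "gamma", "hist_eq")

#: default parameter ranges for randomly sampled augmentations
ROTATE_RANGE = (-15.0, 15.0)   # degrees
SHEAR_RANGE = (-10.0, 10.0)    # degrees
GAMMA_RANGE = (0.7, 1.5)


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for a phantom dataset.

    ``class_counts`` defaults to the emulated study's per-class image counts;
    ``oversample_factors`` to its 1x/3x/8x balancing factors. ``noise_level``
    is the standard deviation of per-pixel Gaussian noise on a [0, 1] scale.
    """

    image_size: int = 512
    class_counts: tuple = (2273, 845, 324)
    oversample_factors: tuple = (1, 3, 8)
    lesions_per_image: tuple = (1, 3)
    noise_level: float = 0.03
    seed: int = 0
    keep_masks: bool = False

    def validate(self):
        if self.image_size < 32:
            raise ConfigError(f"image_size must be >= 32, got {self.image_size}")
        if len(self.class_counts) != 3 or any(c < 0 for c in self.class_counts):
            raise ConfigError(f"class_counts must be 3 non-negative ints, got {self.class_counts}")
        if any(f < 1 for f in self.oversample_factors):
            raise ConfigError(f"oversample factors must be >= 1, got {self.oversample_factors}")
        lo, hi = self.lesions_per_image
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid lesions_per_image range {self.lesions_per_image}")
        if self.noise_level < 0:
            raise ConfigError(f"noise_level must be >= 0, got {self.noise_level}")


@dataclass
class DatasetManifest:
    """Per-class accounting of a dataset before/after oversampling."""

    original_counts: tuple
    oversample_factors: tuple | None
    post_counts: tuple
    total: int
    records: list = field(default_factory=list)

    def check(self):
        if self.total != sum(self.post_counts):
            raise ConfigError(
                f"manifest total {self.total} != sum of per-class counts {self.post_counts}"
            )


@dataclass
class DetectionDataset:
    """Images plus per-image box/class annotations and the manifest.

    ``images`` are float32 grayscale arrays in [0, 1]; ``boxes[i]`` is the
    list of class-tagged :class:`BoundingBox` for image ``i``;
    ``image_classes[i]`` is the image-level lesion class.
    """

    images: list
    boxes: list
    image_classes: list
    manifest: DatasetManifest
    masks: list | None = None

    def __len__(self):
        return len(self.images)

    def subset(self, indices) -> "DetectionDataset":
        indices = list(indices)
        counts = [0, 0, 0]
        for i in indices:
            counts[self.image_classes[i]] += 1
        manifest = DatasetManifest(
            original_counts=tuple(counts), oversample_factors=None,
            post_counts=tuple(counts), total=len(indices),
            records=[self.manifest.records[i] for i in indices],
        )
        return DetectionDataset(
            images=[self.images[i] for i in indices],
            boxes=[self.boxes[i] for i in indices],
            image_classes=[self.image_classes[i] for i in indices],
            manifest=manifest,
            masks=None if self.masks is None else [self.masks[i] for i in indices],
        )


# ---------------------------------------------------------------------------
# lesion rendering
# ---------------------------------------------------------------------------


def _coord_grids(size):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return yy, xx


def _round_mask(size, cy, cx, radius, rng):
    yy, xx = _coord_grids(size)
    ang = rng.uniform(0, np.pi)
    ratio = rng.uniform(0.7, 1.0)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / radius) ** 2 + (v / (radius * ratio)) ** 2 <= 1.0


def _spiculated_mask(size, cy, cx, radius, rng):
    yy, xx = _coord_grids(size)
    n_spikes = int(rng.integers(5, 10))
    phase = rng.uniform(0, 2 * np.pi)
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(xx - cx, yy - cy)
    # deep angular modulation: arms must stay resolvable after smoothing
    rad_theta = radius * (0.58 + 0.42 * np.cos(n_spikes * theta + phase))
    return rr <= rad_theta


def _clustered_mask(size, cy, cx, radius, rng):
    yy, xx = _coord_grids(size)
    mask = np.zeros((size, size), dtype=bool)
    n_foci = int(rng.integers(3, 6))
    for _ in range(n_foci):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, 0.6) * radius
        fy, fx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        fr = radius * rng.uniform(0.25, 0.4)
        mask |= (xx - fx) ** 2 + (yy - fy) ** 2 <= fr ** 2
    return mask


_MASK_FNS = (_round_mask, _spiculated_mask, _clustered_mask)


def _tight_box(mask, class_id) -> BoundingBox:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    y0, y1 = np.where(rows)[0][[0, -1]]
    x0, x1 = np.where(cols)[0][[0, -1]]
    return BoundingBox(float(x0), float(y0), float(x1 + 1), float(y1 + 1),
                       class_id=class_id)


def _render_image(size, class_id, n_lesions, noise_level, rng):
    """One phantom: textured background plus n same-class lesions."""
    base = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 12.0)
    base = base / max(base.std(), 1e-6)
    img = 0.30 + 0.08 * base
    boxes, masks = [], []
    margin = 0.16 * size
    for _ in range(n_lesions):
        for _attempt in range(30):
            radius = rng.uniform(0.06, 0.13) * size
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            mask = _MASK_FNS[class_id](size, cy, cx, radius, rng)
            if not mask.any():
                continue
            box = _tight_box(mask, class_id)
            if all(_box_iou(box, b) < 0.2 for b in boxes):
                break
        else:  # keep the last attempt rather than emit fewer lesions
            pass
        soft = gaussian_filter(mask.astype(float), sigma=1.0)
        intensity = rng.uniform(0.68, 0.82)
        img = img * (1 - soft) + intensity * soft
        # contract: the tight box contains >= 90% of the lesion's pixels
        inside = mask[int(box.y_min):int(box.y_max), int(box.x_min):int(box.x_max)]
        assert inside.sum() >= 0.9 * mask.sum()
        boxes.append(box)
        masks.append(mask)
    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), boxes, masks


def _box_iou(a: BoundingBox, b: BoundingBox) -> float:
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def generate_dataset(config: PhantomConfig) -> DetectionDataset:
    """Generate a seeded phantom dataset with the requested per-class counts.

    Class frequencies match ``config.class_counts`` exactly; images are
    emitted class-by-class and the manifest records one entry per image.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    images, boxes, classes, masks, records = [], [], [], [], []
    lo, hi = config.lesions_per_image
    for class_id, count in enumerate(config.class_counts):
        for _ in range(count):
            n_lesions = int(rng.integers(lo, hi + 1))
            img, bxs, msks = _render_image(
                config.image_size, class_id, n_lesions, config.noise_level, rng
            )
            records.append({
                "index": len(images), "class_id": class_id,
                "n_lesions": len(bxs), "augmented": False,
                "source_index": len(images),
            })
            images.append(img)
            boxes.append(bxs)
            classes.append(class_id)
            if config.keep_masks:
                masks.append(msks)
    manifest = DatasetManifest(
        original_counts=tuple(config.class_counts),
        oversample_factors=None,
        post_counts=tuple(config.class_counts),
        total=len(images),
        records=records,
    )
    manifest.check()
    return DetectionDataset(images=images, boxes=boxes, image_classes=classes,
                            manifest=manifest,
                            masks=masks if config.keep_masks else None)


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------


def oversampled_counts(counts, factors) -> tuple:
    """Per-class counts after oversampling: ``post_c = count_c * factor_c``."""
    if len(counts) != len(factors):
        raise InvalidParameterError("counts and factors must have equal length")
    if any(f < 1 for f in factors):
        raise InvalidParameterError(f"factors must be >= 1, got {factors}")
    return tuple(int(c) * int(f) for c, f in zip(counts, factors))


def oversample(dataset: DetectionDataset, factors, seed: int = 0) -> DetectionDataset:
    """Balance classes by replicating images, augmenting copies beyond the first.

    Each image of class ``c`` appears ``factors[c]`` times; replicas 2..f are
    passed through one randomly sampled augmentation each. For an image whose
    lesions span several classes the maximum factor applies (logged).
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise InvalidParameterError(f"factors must be >= 1, got {factors}")
    rng = np.random.default_rng(seed)
    images, boxes, classes, records = [], [], [], []
    for i, img in enumerate(dataset.images):
        lesion_classes = {b.class_id for b in dataset.boxes[i]}
        if len(lesion_classes) > 1:
            f = max(factors[c] for c in lesion_classes)
            logger.info("image %d mixes classes %s; using factor %d",
                        i, sorted(lesion_classes), f)
        else:
            f = factors[dataset.image_classes[i]]
        for copy in range(f):
            if copy == 0:
                new_img, new_boxes = img, list(dataset.boxes[i])
            else:
                op, params = random_augmentation(rng)
                new_img, new_boxes = augment(img, dataset.boxes[i], op, params)
            records.append({
                "index": len(images), "class_id": dataset.image_classes[i],
                "n_lesions": len(new_boxes), "augmented": copy > 0,
                "source_index": i,
            })
            images.append(new_img)
            boxes.append(new_boxes)
            classes.append(dataset.image_classes[i])
    post = oversampled_counts(dataset.manifest.post_counts, factors)
    manifest = DatasetManifest(
        original_counts=dataset.manifest.post_counts,
        oversample_factors=factors,
        post_counts=post,
        total=len(images),
        records=records,
    )
    manifest.check()
    return DetectionDataset(images=images, boxes=boxes, image_classes=classes,
                            manifest=manifest)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def random_augmentation(rng: np.random.Generator):
    """Sample one augmentation op and its parameters from the default ranges."""
    op = AUGMENT_OPS[int(rng.integers(len(AUGMENT_OPS)))]
    if op == "rotate":
        return op, {"angle": float(rng.uniform(*ROTATE_RANGE))}
    if op == "shear":
        return op, {"angle": float(rng.uniform(*SHEAR_RANGE))}
    if op == "gamma":
        return op, {"gamma": float(rng.uniform(*GAMMA_RANGE))}
    return op, {}


def geometric_transform(op_name: str, params: dict, image_shape):
    """Forward affine map of a geometric op (None for photometric ops).

    The map acts on (x, y) pixel coordinates about the image center and is
    shared between the image warp and the box/mask coordinate update, so the
    two can never drift apart.
    """
    h, w = image_shape[:2]
    if op_name in ("gamma", "hist_eq"):
        return None
    if op_name == "hflip":
        return transform.AffineTransform(matrix=np.array(
            [[-1.0, 0.0, float(w)], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
    if op_name == "vflip":
        return transform.AffineTransform(matrix=np.array(
            [[1.0, 0.0, 0.0], [0.0, -1.0, float(h)], [0.0, 0.0, 1.0]]))
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    to_origin = transform.AffineTransform(translation=(-cx, -cy))
    back = transform.AffineTransform(translation=(cx, cy))
    if op_name == "rotate":
        core = transform.AffineTransform(rotation=np.deg2rad(params["angle"]))
    elif op_name == "shear":
        core = transform.AffineTransform(shear=np.deg2rad(params["angle"]))
    else:
        raise InvalidParameterError(f"unknown augmentation op {op_name!r}")
    return to_origin + core + back


def _ellipse_points(box: BoundingBox, n: int = 32) -> np.ndarray:
    """Points on the inscribed ellipse of a box (plus center).

    Lesions are elliptical-ish, so mapping the inscribed ellipse through a
    rotation/shear yields a far tighter transformed box than mapping the
    corners (whose hull inflates a rotated square by ~22% at 15 degrees).
    Flips are handled by corner mapping, which is exact.
    """
    cx, cy = (box.x_min + box.x_max) / 2, (box.y_min + box.y_max) / 2
    rx, ry = (box.x_max - box.x_min) / 2, (box.y_max - box.y_min) / 2
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([cx + rx * np.cos(t), cy + ry * np.sin(t)], axis=1)
    return np.vstack([pts, [[cx, cy]]])


def _transform_boxes(boxes, tform, op_name, image_shape):
    h, w = image_shape[:2]
    out, dropped = [], 0
    for box in boxes:
        if op_name in ("hflip", "vflip"):
            pts = np.array([[box.x_min, box.y_min], [box.x_max, box.y_max],
                            [box.x_min, box.y_max], [box.x_max, box.y_min]])
        else:
            pts = _ellipse_points(box)
        mapped = tform(pts)
        x0 = float(np.clip(mapped[:, 0].min(), 0, w))
        x1 = float(np.clip(mapped[:, 0].max(), 0, w))
        y0 = float(np.clip(mapped[:, 1].min(), 0, h))
        y1 = float(np.clip(mapped[:, 1].max(), 0, h))
        if x1 - x0 < 1.0 or y1 - y0 < 1.0:
            dropped += 1
            continue
        out.append(BoundingBox(x0, y0, x1, y1, class_id=box.class_id))
    if dropped:
        logger.warning("%d annotation(s) dropped: box left the canvas", dropped)
    return out


def augment(image: np.ndarray, boxes, op_name: str, params: dict | None = None):
    """Apply one named augmentation to an image and its boxes.

    Geometric ops (hflip, vflip, rotate, shear) warp the image and update the
    boxes through the same affine map, clipping to the canvas and dropping
    boxes that leave it entirely; photometric ops (gamma, hist_eq) change
    pixel values only and return the boxes unchanged.
    """
    if op_name not in AUGMENT_OPS:
        raise InvalidParameterError(
            f"unknown augmentation op {op_name!r}; expected one of {AUGMENT_OPS}"
        )
    params = params or {}
    if op_name == "gamma":
        return exposure.adjust_gamma(image, params.get("gamma", 1.0)).astype(
            image.dtype), list(boxes)
    if op_name == "hist_eq":
        return exposure.equalize_hist(image).astype(image.dtype), list(boxes)
    tform = geometric_transform(op_name, params, image.shape)
    if op_name == "hflip":
        warped = image[:, ::-1].copy()
    elif op_name == "vflip":
        warped = image[::-1, :].copy()
    else:
        warped = transform.warp(image, tform.inverse, mode="edge",
                                preserve_range=True).astype(image.dtype)
    return warped, _transform_boxes(boxes, tform, op_name, image.shape)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_dataset(dataset: DetectionDataset, ratios=(0.7, 0.15, 0.15),
                  seed: int = 0):
    """Stratified train/val/test-dev split by image class (seeded).

    Oversampling, when used, should be applied to the *training* split only,
    so that augmented replicas of one source image never straddle splits.
    """
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise InvalidParameterError(f"ratios must be 3 values summing to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    parts = ([], [], [])
    for c in range(3):
        idx = [i for i, cls in enumerate(dataset.image_classes) if cls == c]
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train:n_train + n_val])
        parts[2].extend(idx[n_train + n_val:])
    return tuple(dataset.subset(sorted(p)) for p in parts)
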