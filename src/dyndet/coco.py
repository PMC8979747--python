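"""COCO-style detection JSON I/O (plain json; no binary formats).

Annotations use the standard layout: ``images`` (id, file_name, width,
height), ``annotations`` (id, image_id, category_id, bbox as
``[x, y, width, height]``, area, iscrowd), ``categories``. Detections use the
COCO results layout: a list of ``{image_id, category_id, bbox, score}``.
Internally boxes are corner-format (x0, y0, x1, y1); conversion happens here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from dyndet.data_synth import CLASS_NAMES, DatasetManifest, DetectionDataset
from dyndet.scheduler import BoundingBox

__all__ = [
    "write_coco_dataset",
    "read_coco_dataset",
    "write_detections",
    "read_detections",
]


def _box_to_xywh(b: BoundingBox):
    return [b.x_min, b.y_min, b.x_max - b.x_min, b.y_max - b.y_min]


def _xywh_to_box(xywh, class_id, score=None) -> BoundingBox:
    x, y, w, h = xywh
    return BoundingBox(x, y, x + w, y + h, class_id=class_id, score=score)


def write_coco_dataset(dataset: DetectionDataset, out_dir) -> Path:
    """Write PNG images, a COCO annotations JSON and a manifest sidecar."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    for i, img in enumerate(dataset.images):
        fname = f"img_{i:06d}.png"
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(img_dir / fname)
        h, w = img.shape
        images.append({"id": i, "file_name": f"images/{fname}",
                       "width": w, "height": h})
        for b in dataset.boxes[i]:
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": b.class_id,
                "bbox": _box_to_xywh(b), "area": b.area, "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": c, "name": n} for c, n in enumerate(CLASS_NAMES)],
    }
    (out_dir / "annotations.json").write_text(json.dumps(doc))
    manifest = {
        "original_counts": list(dataset.manifest.original_counts),
        "oversample_factors": (None if dataset.manifest.oversample_factors is None
                               else list(dataset.manifest.oversample_factors)),
        "post_counts": list(dataset.manifest.post_counts),
        "total": dataset.manifest.total,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def read_coco_dataset(in_dir) -> DetectionDataset:
    """Load a dataset written by :func:`write_coco_dataset`."""
    in_dir = Path(in_dir)
    doc = json.loads((in_dir / "annotations.json").read_text())
    by_image = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        by_image[ann["image_id"]].append(
            _xywh_to_box(ann["bbox"], ann["category_id"]))
    images, boxes, classes, records = [], [], [], []
    for img in sorted(doc["images"], key=lambda d: d["id"]):
        arr = np.asarray(Image.open(in_dir / img["file_name"]), dtype=np.float32) / 255.0
        bxs = by_image[img["id"]]
        cls = bxs[0].class_id if bxs else 0
        records.append({"index": len(images), "class_id": cls,
                        "n_lesions": len(bxs), "augmented": False,
                        "source_index": len(images)})
        images.append(arr)
        boxes.append(bxs)
        classes.append(cls)
    counts = [classes.count(c) for c in range(3)]
    manifest = DatasetManifest(original_counts=tuple(counts),
                               oversample_factors=None,
                               post_counts=tuple(counts),
                               total=len(images), records=records)
    return DetectionDataset(images=images, boxes=boxes, image_classes=classes,
                            manifest=manifest)


def write_detections(detections_by_image, path) -> Path:
    """Write per-image detection lists as a COCO results JSON."""
    results = []
    for image_id, dets in enumerate(detections_by_image):
        for d in dets:
            results.append({
                "image_id": image_id, "category_id": d.class_id,
                "bbox": _box_to_xywh(d), "score": float(d.score),
            })
    path = Path(path)
    path.write_text(json.dumps(results))
    return path


def read_detections(path, num_images: int | None = None):
    """Read a COCO results JSON back into per-image detection lists."""
    results = json.loads(Path(path).read_text())
    n = num_images
    if n is None:
        n = 1 + max((r["image_id"] for r in results), default=-1)
    by_image = [[] for _ in range(n)]
    for r in results:
        by_image[r["image_id"]].append(
            _xywh_to_box(r["bbox"], r["category_id"], score=r["score"]))
    return by_image
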