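"""Average precision at fixed IoU thresholds and the study's mAP aggregate.

AP follows the standard single-class protocol: detections are ranked by
score (ties broken by input order), each detection greedily claims the
highest-IoU still-unmatched ground truth provided the IoU reaches the match
threshold, and AP is the area under the all-point interpolated
precision-recall curve. The headline mAP here is the arithmetic mean of the
six per-class AP values at IoU thresholds 0.5 and 0.75 (three lesion
classes x two thresholds) — not the COCO [.5:.95] sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from dyndet.exceptions import InvalidInputError, InvalidParameterError
from dyndet.scheduler import BoundingBox, iou_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "average_precision",
    "dataset_average_precision",
    "aggregate_map",
    "evaluate_detections",
]

DEFAULT_THRESHOLDS = (0.5, 0.75)


@dataclass(frozen=True)
class EvalResult:
    """Per-(class, IoU-threshold) AP table plus the aggregate mAP."""

    ap: dict
    map_score: float

    def as_rows(self):
        return [
            {"class_id": c, "iou_threshold": t, "ap": v}
            for (c, t), v in sorted(self.ap.items())
        ]


def _det_arrays(detections):
    boxes = np.zeros((len(detections), 4))
    scores = np.zeros(len(detections))
    for i, d in enumerate(detections):
        if isinstance(d, BoundingBox):
            if d.score is None:
                raise InvalidInputError("detections must carry scores")
            boxes[i] = d.as_array()
            scores[i] = d.score
        else:
            arr = np.asarray(d, dtype=float)
            boxes[i] = arr[:4]
            scores[i] = arr[4]
    return boxes, scores


def _gt_array(ground_truths):
    return np.stack(
        [g.as_array() if isinstance(g, BoundingBox) else np.asarray(g, dtype=float)[:4]
         for g in ground_truths]
    ) if len(ground_truths) else np.zeros((0, 4))


def _ap_from_flags(tp: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from score-ordered TP flags."""
    if n_gt == 0 or tp.size == 0:
        return 0.0
    tps = np.cumsum(tp)
    fps = np.cumsum(1 - tp)
    recall = tps / n_gt
    precision = tps / np.maximum(tps + fps, 1e-12)
    # precision envelope, then sum over recall increments
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _match_flags(det_boxes, det_scores, gt_boxes, iou_threshold):
    """Greedy matching; returns TP flags in global score order positions."""
    order = np.argsort(-det_scores, kind="stable")
    tp = np.zeros(len(det_boxes))
    if len(gt_boxes) == 0:
        return tp, order
    ious = iou_matrix(det_boxes, gt_boxes)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    for rank, i in enumerate(order):
        row = ious[i].copy()
        row[taken] = -1.0
        j = int(np.argmax(row))
        if row[j] >= iou_threshold:
            taken[j] = True
            tp[rank] = 1.0
    return tp, order


def average_precision(detections, ground_truths, iou_threshold: float) -> float:
    """Single-image (or pooled single-class) AP at one IoU threshold.

    ``detections`` are scored boxes (:class:`BoundingBox` with score, or
    5-sequences ``(x0, y0, x1, y1, score)``); ``ground_truths`` are boxes.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise InvalidParameterError(f"iou_threshold must be in (0,1), got {iou_threshold}")
    det_boxes, det_scores = _det_arrays(detections)
    gt_boxes = _gt_array(ground_truths)
    if len(gt_boxes) == 0:
        if len(det_boxes):
            logger.warning("no ground truths: AP defined as 0 for %d detections",
                           len(det_boxes))
        return 0.0
    if len(det_boxes) == 0:
        return 0.0
    tp, _ = _match_flags(det_boxes, det_scores, gt_boxes, iou_threshold)
    return _ap_from_flags(tp, len(gt_boxes))


def dataset_average_precision(detections_by_image, gts_by_image,
                              iou_threshold: float) -> float:
    """AP over a dataset: matching is per image, ranking is global.

    Both arguments are sequences indexed by image; matching never crosses
    image boundaries, while the precision-recall curve ranks all detections
    of all images together by score.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise InvalidParameterError(f"iou_threshold must be in (0,1), got {iou_threshold}")
    all_scores, all_tp = [], []
    n_gt = 0
    for dets, gts in zip(detections_by_image, gts_by_image):
        det_boxes, det_scores = _det_arrays(dets)
        gt_boxes = _gt_array(gts)
        n_gt += len(gt_boxes)
        if len(det_boxes) == 0:
            continue
        tp, order = _match_flags(det_boxes, det_scores, gt_boxes, iou_threshold)
        all_scores.append(det_scores[order])
        all_tp.append(tp)
    if n_gt == 0 or not all_scores:
        return 0.0
    scores = np.concatenate(all_scores)
    tp = np.concatenate(all_tp)
    order = np.argsort(-scores, kind="stable")
    return _ap_from_flags(tp[order], n_gt)


def evaluate_detections(detections_by_image, gts_by_image, num_classes: int = 3,
                        thresholds=DEFAULT_THRESHOLDS) -> EvalResult:
    """Per-class AP at each threshold plus the aggregate mAP.

    Detections and ground truths are per-image lists of class-tagged
    :class:`BoundingBox` objects; detections additionally carry scores.
    """
    ap = {}
    for c in range(num_classes):
        dets_c = [[d for d in dets if d.class_id == c] for dets in detections_by_image]
        gts_c = [[g for g in img_gts if g.class_id == c] for img_gts in gts_by_image]
        for t in thresholds:
            ap[(c, t)] = dataset_average_precision(dets_c, gts_c, t)
    return EvalResult(ap=ap, map_score=aggregate_map(ap))


def aggregate_map(ap_table) -> float:
    """Arithmetic mean of the per-(class, threshold) AP cells.

    ``ap_table`` is a mapping from (class, threshold) to AP, or a flat
    sequence of AP values; all cells must be present and non-None.
    """
    if isinstance(ap_table, dict):
        values = list(ap_table.values())
    else:
        values = list(ap_table)
    if not values or any(v is None for v in values):
        raise InvalidInputError("AP table has missing cells")
    return float(np.mean([float(v) for v in values]))
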