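"""Dynamic label assignment: IoU, the binary assignment rule, and the
order-statistic schedule that raises the IoU threshold during training.

Early in training most proposals overlap the ground truth poorly, so a low
positive/negative threshold is needed to harvest enough positives; as the
proposal distribution improves, a fixed low threshold floods the second stage
with mediocre positives. The scheduler therefore tracks the K_I-th largest
proposal-to-ground-truth IoU per iteration and periodically resets the
threshold ``T_now`` to the mean of the recorded statistics, so the bar rises
together with proposal quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from dyndet.exceptions import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: set once the short-sample fallback has been reported at WARNING level
_FALLBACK_WARNED: set = set()

__all__ = [
    "BoundingBox",
    "AssignmentState",
    "iou",
    "iou_matrix",
    "assign_labels",
    "match_proposals",
    "update_threshold",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous, 0-based pixel coordinates.

    Corners are ``(x_min, y_min)`` inclusive-top-left to ``(x_max, y_max)``;
    area is the real-valued product of side lengths and must be positive.
    ``class_id`` is the integer category; ``score`` is set on detections only.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int = 0
    score: float | None = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidInputError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


def _to_xyxy(box) -> np.ndarray:
    if isinstance(box, BoundingBox):
        return box.as_array()
    arr = np.asarray(box, dtype=float)
    if arr.shape != (4,):
        raise InvalidInputError(f"box must have 4 coordinates, got shape {arr.shape}")
    if not (arr[2] > arr[0] and arr[3] > arr[1]):
        raise InvalidInputError(f"degenerate box {arr.tolist()}")
    return arr


def iou(a, b) -> float:
    """Intersection-over-union of two boxes (corner format).

    Symmetric, 1 iff the extents coincide, 0 iff the boxes are disjoint.
    Boxes may be :class:`BoundingBox` or 4-sequences ``(x0, y0, x1, y1)``.
    """
    a = _to_xyxy(a)
    b = _to_xyxy(b)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N, 4) / (M, 4) corner-format arrays."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0.0, None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0.0, None,
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def match_proposals(proposals, ground_truths, t_now: float):
    """Max-IoU matching of proposals against ground truths.

    Returns ``(labels, max_ious, matched_idx)``: binary foreground labels
    (1 iff max IoU >= t_now, boundary inclusive), the per-proposal maximum
    IoU, and the index of the argmax ground truth (-1 where there is none).
    """
    if not (0.0 < t_now < 1.0):
        raise InvalidParameterError(f"T_now must lie in (0, 1), got {t_now}")
    n = len(proposals)
    if len(ground_truths) == 0:
        logger.warning("no ground truths: all %d proposals labelled background", n)
        return np.zeros(n, dtype=int), np.zeros(n), np.full(n, -1, dtype=int)
    p = np.stack([_to_xyxy(b) for b in proposals]) if n else np.zeros((0, 4))
    g = np.stack([_to_xyxy(b) for b in ground_truths])
    ious = iou_matrix(p, g)
    max_ious = ious.max(axis=1) if n else np.zeros(0)
    matched = ious.argmax(axis=1) if n else np.zeros(0, dtype=int)
    labels = (max_ious >= t_now).astype(int)
    matched = np.where(labels == 1, matched, -1)
    return labels, max_ious, matched


def assign_labels(proposals, ground_truths, t_now: float) -> list:
    """Binary foreground/background labels at the current IoU threshold.

    ``label_i = 1`` iff the maximum IoU of proposal ``i`` over all ground
    truths is at least ``t_now``; the boundary is inclusive.
    """
    labels, _, _ = match_proposals(proposals, ground_truths, t_now)
    return labels.tolist()


@dataclass
class AssignmentState:
    """Dynamic IoU threshold plus the statistics buffer that drives it.

    ``T_now`` is refreshed to the mean of the buffered per-iteration
    statistics (the K_I-th largest proposal IoU) every ``cadence`` recorded
    iterations, clamped to ``clamp``. The first window doubles as warm-up.
    """

    T_now: float = 0.5
    K_I: int = 75
    iou_buffer: list = field(default_factory=list)
    clamp: tuple = (0.4, 0.9)
    cadence: int = 100

    @classmethod
    def create(
        cls,
        t_init: float = 0.5,
        k_i: int = 75,
        cadence: int = 100,
        clamp: tuple = (0.4, 0.9),
    ) -> "AssignmentState":
        if k_i < 1:
            raise InvalidParameterError(f"K_I must be >= 1, got {k_i}")
        if cadence < 1:
            raise InvalidParameterError(f"cadence must be >= 1, got {cadence}")
        if not (0 < clamp[0] <= clamp[1] < 1):
            raise InvalidParameterError(f"invalid threshold clamp {clamp}")
        t = float(min(max(t_init, clamp[0]), clamp[1]))
        return cls(T_now=t, K_I=int(k_i), clamp=(float(clamp[0]), float(clamp[1])),
                   cadence=int(cadence))


def update_threshold(state: AssignmentState, ious_I) -> AssignmentState:
    """Record an IoU statistic and, at cadence, refresh ``T_now``.

    Appends the ``K_I``-th *largest* value of ``ious_I`` to the buffer; when
    ``cadence`` statistics have accumulated, sets ``T_now`` to
    ``max(T_now, mean(buffer))`` (clamped) and clears the buffer — the bar
    only ever rises, tracking the one-way improvement of proposal quality. If fewer than ``K_I`` IoUs are supplied,
    the smallest available value is used, with a logged warning.

    The state is updated in place and returned.
    """
    vals = np.asarray(ious_I, dtype=float).ravel()
    if vals.size == 0:
        raise InvalidParameterError("ious_I must be non-empty")
    k = state.K_I
    if k > vals.size:
        level = logging.DEBUG if _FALLBACK_WARNED else logging.WARNING
        logger.log(level, "K_I=%d exceeds sample size %d; using the smallest value",
                   k, vals.size)
        _FALLBACK_WARNED.add("k_i")
        k = vals.size
    stat = float(np.partition(vals, vals.size - k)[vals.size - k])
    state.iou_buffer.append(stat)
    if len(state.iou_buffer) >= state.cadence:
        t = max(state.T_now, float(np.mean(state.iou_buffer)))
        state.T_now = min(max(t, state.clamp[0]), state.clamp[1])
        state.iou_buffer.clear()
    return state
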