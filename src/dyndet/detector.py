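"""A CPU-scale two-stage detector wiring the dynamic training components.

Architecture (the "small-conv" backbone): four 3x3 convolution stages with
strides 2/2/2/1 (total stride 8), a region proposal network (RPN) on the
final feature map, and a Box_Head that classifies RoI-aligned proposal
features with a softmax cross-entropy loss and regresses class-agnostic box
deltas with a selectable regression loss (dynamic balanced Smooth L1 by
default). During training the second-stage positive/negative IoU threshold
``T_now`` and the regression-loss shape factor ``alpha_now`` are refreshed
from running proposal statistics (see :mod:`dyndet.scheduler` and
:mod:`dyndet.losses`); a self-calibrated convolution block can replace the
plain convolution in the RPN head and/or the last backbone stage.

Everything runs through the numpy autodiff engine in :mod:`dyndet.nn`, so a
fixed seed plus fixed data gives bit-identical training trajectories on CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from dyndet import nn
from dyndet.exceptions import ConfigError, InvalidInputError
from dyndet.losses import DynamicLossState, update_alpha
from dyndet.scheduler import AssignmentState, BoundingBox, iou_matrix, update_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "TrainingState",
    "Detector",
    "build_detector",
    "train_detector",
    "softmax_classification_loss",
]

BACKBONE_STRIDE = 8
_BACKBONE_CHANNELS = (16, 32, 64, 64)
_BACKBONE_STRIDES = (2, 2, 2, 1)
_SCCONV_SITES = ("rpn", "backbone")


@dataclass(frozen=True)
class DetectorConfig:
    """Detector, optimizer and dynamic-schedule settings.

    Training defaults follow the emulated study (input 512x512, 12 epochs,
    SGD with lr 0.01, momentum 0.9, weight decay 1e-4); structural settings
    the paper leaves open (anchors, NMS, sampling) follow common two-stage
    detector practice and are all configurable here.
    """

    input_size: int = 512
    backbone: str = "small-conv"
    num_classes: int = 3
    use_scconv: bool = True
    scconv_placement: tuple = ("rpn",)
    scconv_pooling_rate: int = 4
    epochs: int = 12
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0001
    grad_clip: float = 35.0
    seed: int = 0
    # anchors / proposals
    anchor_scales: tuple = (2.0, 4.0, 8.0)      # in units of the stride
    anchor_ratios: tuple = (0.5, 1.0, 2.0)
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 64
    rpn_nms_iou: float = 0.7
    pre_nms_top: int = 600
    post_nms_top_train: int = 100
    post_nms_top_test: int = 100
    # second stage
    roi_batch: int = 64
    roi_pos_fraction: float = 0.25
    roi_size: int = 6
    score_threshold: float = 0.05
    nms_iou: float = 0.5
    max_detections: int = 50
    # regression loss: dbs_l1 | ds_l1 | smooth_l1
    loss: str = "dbs_l1"
    smooth_l1_beta: float = 1.0
    k_alpha: int = 10
    alpha_init: float = 1.0
    alpha_clamp: tuple = (0.05, 1.0)
    # dynamic assignment
    t_init: float = 0.4
    k_i: int = 75
    t_clamp: tuple = (0.4, 0.9)
    cadence: int = 100

    def validate(self):
        if self.backbone != "small-conv":
            raise ConfigError(
                f"unknown backbone {self.backbone!r}: this toolkit ships the "
                "CPU-scale 'small-conv' backbone only"
            )
        if self.input_size % BACKBONE_STRIDE != 0 or self.input_size < 4 * BACKBONE_STRIDE:
            raise ConfigError(
                f"input_size must be a multiple of the total stride "
                f"{BACKBONE_STRIDE} (and >= {4 * BACKBONE_STRIDE}), got {self.input_size}"
            )
        for rate in (self.learning_rate, self.momentum, self.weight_decay):
            if rate < 0:
                raise ConfigError(f"optimizer rates must be non-negative, got {rate}")
        if self.use_scconv:
            bad = set(self.scconv_placement) - set(_SCCONV_SITES)
            if bad or not self.scconv_placement:
                raise ConfigError(
                    f"scconv_placement must be a non-empty subset of {_SCCONV_SITES}, "
                    f"got {self.scconv_placement}"
                )
        if self.loss not in ("dbs_l1", "ds_l1", "smooth_l1"):
            raise ConfigError(f"unknown regression loss {self.loss!r}")


@dataclass
class TrainingState:
    """Iteration counter plus the two dynamic schedules and the loss log."""

    iteration: int = 0
    loss_state: DynamicLossState = field(default_factory=DynamicLossState)
    assign_state: AssignmentState = field(default_factory=AssignmentState)
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _param(rng, shape, fan_in) -> nn.Tensor:
    std = np.sqrt(2.0 / fan_in)
    return nn.Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                     requires_grad=True)


class ConvLayer:
    def __init__(self, rng, c_in, c_out, k=3, stride=1):
        self.stride = stride
        self.pad = k // 2
        self.w = _param(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = nn.Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return nn.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]

    def n_params(self):
        return self.w.data.size + self.b.data.size


class LinearLayer:
    def __init__(self, rng, n_in, n_out):
        self.w = _param(rng, (n_out, n_in), n_in)
        self.b = nn.Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return nn.linear(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def n_params(self):
        return self.w.data.size + self.b.data.size


class SCConvBlock:
    """Trainable self-calibrated convolution (channel-preserving, bias-free).

    Evaluates exactly the functional pipeline of :mod:`dyndet.scconv` through
    the autodiff engine: split channels, gate the K3 response of the first
    half with sigmoid(X1 + up(K2 * avgpool_r(X1))), refine with K4,
    convolve the second half with K1, concatenate.
    """

    def __init__(self, rng, channels, k=3, r=4):
        if channels % 2:
            raise ConfigError(f"self-calibrated block needs even channels, got {channels}")
        c2 = channels // 2
        self.r = r
        self.pad = k // 2
        self.kernels = [_param(rng, (c2, c2, k, k), c2 * k * k) for _ in range(4)]

    def __call__(self, x):
        c = x.shape[1]
        h, w = x.shape[2], x.shape[3]
        k1, k2, k3, k4 = self.kernels
        x1 = nn.narrow(x, 1, 0, c // 2)
        x2 = nn.narrow(x, 1, c // 2, c // 2)
        r = min(self.r, h, w)
        t1 = nn.avgpool2d(x1, r)
        x1p = nn.upsample_bilinear(nn.conv2d(t1, k2, pad=self.pad), h, w)
        gate = nn.sigmoid_t(nn.add(x1, x1p))
        y1p = nn.mul(nn.conv2d(x1, k3, pad=self.pad), gate)
        y1 = nn.conv2d(y1p, k4, pad=self.pad)
        y2 = nn.conv2d(x2, k1, pad=self.pad)
        return nn.concat([y1, y2], axis=1)

    def params(self):
        return list(self.kernels)

    def n_params(self):
        return sum(k.data.size for k in self.kernels)


# ---------------------------------------------------------------------------
# box arithmetic (plain numpy)
# ---------------------------------------------------------------------------

RPN_STDS = np.array([1.0, 1.0, 1.0, 1.0])
HEAD_STDS = np.array([0.1, 0.1, 0.2, 0.2])


def encode_deltas(anchors: np.ndarray, gts: np.ndarray, stds: np.ndarray) -> np.ndarray:
    """(dx, dy, dw, dh) targets with log-space sizes, divided by stds."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + 0.5 * aw
    acy = anchors[:, 1] + 0.5 * ah
    gw = gts[:, 2] - gts[:, 0]
    gh = gts[:, 3] - gts[:, 1]
    gcx = gts[:, 0] + 0.5 * gw
    gcy = gts[:, 1] + 0.5 * gh
    d = np.stack([(gcx - acx) / aw, (gcy - acy) / ah,
                  np.log(gw / aw), np.log(gh / ah)], axis=1)
    return d / stds


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray, stds: np.ndarray,
                  size: int) -> np.ndarray:
    d = deltas * stds
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + 0.5 * aw
    acy = anchors[:, 1] + 0.5 * ah
    cx = acx + d[:, 0] * aw
    cy = acy + d[:, 1] * ah
    w = aw * np.exp(np.minimum(d[:, 2], 4.0))
    h = ah * np.exp(np.minimum(d[:, 3], 4.0))
    boxes = np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h], axis=1)
    return np.clip(boxes, 0.0, size)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-ordered."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.asarray(keep, dtype=int)


def make_anchors(size: int, stride: int, scales, ratios) -> np.ndarray:
    """Anchor grid ordered (row, col, anchor), corner format."""
    n = size // stride
    bases = []
    for s in scales:
        side = s * stride
        for r in ratios:
            w = side * np.sqrt(1.0 / r)
            h = side * np.sqrt(r)
            bases.append((w, h))
    bases = np.asarray(bases)
    centers = (np.arange(n) + 0.5) * stride
    cy, cx = np.meshgrid(centers, centers, indexing="ij")
    cx = cx[:, :, None]
    cy = cy[:, :, None]
    w = bases[None, None, :, 0]
    h = bases[None, None, :, 1]
    anchors = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)
    return anchors.reshape(-1, 4)


def softmax_classification_loss(logits, labels) -> float:
    """Mean softmax cross-entropy over proposals (background = extra index)."""
    t = nn.Tensor(np.asarray(logits, dtype=np.float64))
    return float(nn.softmax_cross_entropy(t, np.asarray(labels, dtype=int)).data)


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------


class Detector:
    """Two-stage detector exposing forward, loss and step operations."""

    def __init__(self, config: DetectorConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._sample_rng = np.random.default_rng(config.seed + 1)
        sites = set(config.scconv_placement) if config.use_scconv else set()

        self.backbone = []
        c_in = 1
        for i, (c_out, stride) in enumerate(zip(_BACKBONE_CHANNELS, _BACKBONE_STRIDES)):
            last = i == len(_BACKBONE_CHANNELS) - 1
            if last and "backbone" in sites and c_in == c_out and stride == 1:
                self.backbone.append(SCConvBlock(rng, c_out, r=config.scconv_pooling_rate))
            else:
                # 5x5 stem: a wider view of the raw pixels before the first
                # downsampling step, cheap at 1 input channel
                k = 5 if i == 0 else 3
                self.backbone.append(ConvLayer(rng, c_in, c_out, k=k, stride=stride))
            c_in = c_out
        feat_c = c_in

        if "rpn" in sites:
            self.rpn_mid = SCConvBlock(rng, feat_c, r=config.scconv_pooling_rate)
        else:
            self.rpn_mid = ConvLayer(rng, feat_c, feat_c)
        self.n_anchors = len(config.anchor_scales) * len(config.anchor_ratios)
        self.rpn_cls = ConvLayer(rng, feat_c, self.n_anchors, k=1)
        self.rpn_reg = ConvLayer(rng, feat_c, 4 * self.n_anchors, k=1)

        # the Box_Head reads hypercolumn RoI features: the stride-4 map keeps
        # the fine texture that separates the lesion classes, the stride-8
        # map carries the deeper context the RPN sees
        self._head_c = _BACKBONE_CHANNELS[1] + feat_c
        flat = self._head_c * config.roi_size * config.roi_size
        self.fc1 = LinearLayer(rng, flat, 256)
        self.fc2 = LinearLayer(rng, 256, 256)
        self.fc_cls = LinearLayer(rng, 256, config.num_classes + 1)
        self.fc_reg = LinearLayer(rng, 256, 4)
        self._feat_c = feat_c

        self.optimizer = nn.SGD(self.parameters(), lr=config.learning_rate,
                                momentum=config.momentum,
                                weight_decay=config.weight_decay)
        self.anchors = make_anchors(config.input_size, BACKBONE_STRIDE,
                                    config.anchor_scales, config.anchor_ratios)

    # -- plumbing -----------------------------------------------------------

    def _modules(self):
        return [*self.backbone, self.rpn_mid, self.rpn_cls, self.rpn_reg,
                self.fc1, self.fc2, self.fc_cls, self.fc_reg]

    def parameters(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return sum(m.n_params() for m in self._modules())

    def new_training_state(self) -> TrainingState:
        cfg = self.config
        return TrainingState(
            loss_state=DynamicLossState.create(cfg.alpha_init, cfg.k_alpha,
                                               cfg.cadence, cfg.alpha_clamp),
            assign_state=AssignmentState.create(cfg.t_init, cfg.k_i,
                                                cfg.cadence, cfg.t_clamp),
        )

    # -- forward ------------------------------------------------------------

    def _prepare_image(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 3 and img.shape[0] == 1:
            img = img[0]
        if img.ndim != 2:
            raise InvalidInputError(f"expected a grayscale image, got shape {img.shape}")
        s = self.config.input_size
        if img.shape != (s, s):
            logger.info("resizing image %s -> (%d, %d)", img.shape, s, s)
            img = nn.bilinear_resize(img[None, None], s, s)[0, 0]
        return img

    def _forward_features(self, images: np.ndarray):
        """Backbone forward; returns the stride-4 and stride-8 feature maps."""
        t = nn.Tensor(images)
        mid = None
        for i, layer in enumerate(self.backbone):
            t = nn.relu(layer(t))
            if i == 1:  # after the second stride-2 stage: stride 4
                mid = t
        return mid, t

    def _roi_features(self, feat4, feat8, idx: int, rois: np.ndarray):
        """Hypercolumn RoI extraction for one image of the batch."""
        rs = self.config.roi_size
        f4 = nn.reshape(nn.take(feat4, np.array([idx])),
                        (feat4.shape[1],) + feat4.shape[2:])
        f8 = nn.reshape(nn.take(feat8, np.array([idx])),
                        (feat8.shape[1],) + feat8.shape[2:])
        return nn.concat([nn.roi_align(f4, rois, 0.25, rs),
                          nn.roi_align(f8, rois, 1.0 / BACKBONE_STRIDE, rs)],
                         axis=1)

    def _forward_rpn(self, feat):
        mid = nn.relu(self.rpn_mid(feat))
        n = feat.shape[0]
        k = self.anchors.shape[0]
        cls = self.rpn_cls(mid)   # (N, A, Ho, Wo)
        reg = self.rpn_reg(mid)   # (N, 4A, Ho, Wo)
        cls = nn.reshape(nn.transpose(cls, (0, 2, 3, 1)), (n * k,))
        reg = nn.reshape(nn.transpose(reg, (0, 2, 3, 1)), (n * k, 4))
        return cls, reg

    def _proposals(self, cls_np: np.ndarray, reg_np: np.ndarray, n_images: int,
                   training: bool):
        """Decode, filter and NMS the RPN output (numpy, no gradient)."""
        cfg = self.config
        k = self.anchors.shape[0]
        scores_all = nn.sigmoid(cls_np.reshape(n_images, k))
        deltas_all = reg_np.reshape(n_images, k, 4)
        top = cfg.post_nms_top_train if training else cfg.post_nms_top_test
        proposals = []
        for i in range(n_images):
            boxes = decode_deltas(self.anchors, deltas_all[i], RPN_STDS, cfg.input_size)
            scores = scores_all[i]
            ok = ((boxes[:, 2] - boxes[:, 0] > 2.0) & (boxes[:, 3] - boxes[:, 1] > 2.0))
            boxes, scores = boxes[ok], scores[ok]
            order = np.argsort(-scores, kind="stable")[:cfg.pre_nms_top]
            boxes, scores = boxes[order], scores[order]
            keep = nms(boxes, scores, cfg.rpn_nms_iou)[:top]
            proposals.append(boxes[keep])
        return proposals

    # -- training -----------------------------------------------------------

    def _rpn_targets(self, gt_boxes: np.ndarray):
        """Sampled anchor indices, binary labels and encoded targets."""
        cfg = self.config
        k = self.anchors.shape[0]
        labels = np.full(k, -1, dtype=int)
        matched = np.zeros(k, dtype=int)
        if len(gt_boxes):
            ious = iou_matrix(self.anchors, gt_boxes)
            max_iou = ious.max(axis=1)
            matched = ious.argmax(axis=1)
            labels[max_iou < cfg.rpn_neg_iou] = 0
            labels[max_iou >= cfg.rpn_pos_iou] = 1
            # every gt claims its best-overlapping anchor
            best = ious.argmax(axis=0)
            labels[best] = 1
            matched[best] = np.arange(len(gt_boxes))
        else:
            labels[:] = 0
        pos = np.where(labels == 1)[0]
        neg = np.where(labels == 0)[0]
        n_pos = min(len(pos), cfg.rpn_batch // 2)
        if len(pos) > n_pos:
            pos = self._sample_rng.choice(pos, n_pos, replace=False)
        n_neg = min(len(neg), cfg.rpn_batch - n_pos)
        if len(neg) > n_neg:
            neg = self._sample_rng.choice(neg, n_neg, replace=False)
        targets = (encode_deltas(self.anchors[pos], gt_boxes[matched[pos]], RPN_STDS)
                   if len(pos) else np.zeros((0, 4)))
        return pos, neg, targets

    def _sample_rois(self, proposals: np.ndarray, gt_boxes: np.ndarray,
                     gt_classes: np.ndarray, t_now: float):
        """Dynamic second-stage assignment and 1:3 positive sampling."""
        cfg = self.config
        n_real = len(proposals)
        if len(gt_boxes):
            proposals = np.vstack([proposals, gt_boxes])
            ious = iou_matrix(proposals, gt_boxes)
            max_iou = ious.max(axis=1)
            matched = ious.argmax(axis=1)
        else:
            max_iou = np.zeros(len(proposals))
            matched = np.full(len(proposals), -1, dtype=int)
        # schedule statistics come from genuine RPN proposals only; the
        # appended ground-truth boxes (IoU 1, zero regression error) would
        # otherwise bias T_now up and alpha_now down artificially
        stat_iou = max_iou[:n_real]
        if len(gt_boxes):
            fg_real = np.where(max_iou[:n_real] >= t_now)[0]
            stat_err = (np.abs(encode_deltas(proposals[fg_real],
                                             gt_boxes[matched[fg_real]], HEAD_STDS)).ravel()
                        if len(fg_real) else np.zeros(0))
        else:
            stat_err = np.zeros(0)
        fg = np.where(max_iou >= t_now)[0]
        bg = np.where(max_iou < t_now)[0]
        n_pos = min(len(fg), int(cfg.roi_batch * cfg.roi_pos_fraction))
        if len(fg) > n_pos:
            fg = self._sample_rng.choice(fg, n_pos, replace=False)
        n_neg = min(len(bg), cfg.roi_batch - n_pos)
        if len(bg) > n_neg:
            bg = self._sample_rng.choice(bg, n_neg, replace=False)
        sel = np.concatenate([fg, bg]).astype(int)
        rois = proposals[sel]
        labels = np.full(len(sel), cfg.num_classes, dtype=int)  # background
        labels[:len(fg)] = gt_classes[matched[fg]] if len(fg) else []
        targets = (encode_deltas(rois[:len(fg)], gt_boxes[matched[fg]], HEAD_STDS)
                   if len(fg) else np.zeros((0, 4)))
        return rois, labels, len(fg), targets, stat_iou, stat_err

    def _reg_loss_fns(self, state: TrainingState):
        cfg = self.config
        if cfg.loss == "smooth_l1":
            beta = cfg.smooth_l1_beta
            return (lambda x: np.where(x < beta, 0.5 * x * x / beta, x - 0.5 * beta),
                    lambda x: np.where(x < beta, x / beta, 1.0))
        if cfg.loss == "ds_l1":
            a = state.loss_state.alpha_now
            return (lambda x: np.where(x < a, 0.5 * x * x / a, x - 0.5 * a),
                    lambda x: np.where(x < a, x / a, 1.0))
        st = state.loss_state
        a, b, c = st.alpha_now, st.b, st.C
        return (lambda x: np.where(x < a, (a / b) * (b * x + 1) * np.log(b * x + 1) - a * x,
                                   x + c),
                lambda x: np.where(x < a, a * np.log(b * x + 1), 1.0))

    def training_step(self, batch, state: TrainingState):
        """One SGD step on a batch of ``(image, [BoundingBox, ...])`` pairs.

        Computes RPN objectness/regression losses, the Box_Head softmax
        classification loss on dynamically assigned labels and the selected
        regression loss; records the IoU and regression-error statistics that
        drive ``T_now`` and ``alpha_now``; applies one optimizer step.
        """
        cfg = self.config
        images, gt_list = [], []
        for image, boxes in batch:
            images.append(self._prepare_image(image))
            gt_list.append(boxes)
        x = np.stack(images)[:, None]
        n = len(images)
        k = self.anchors.shape[0]

        feat4, feat8 = self._forward_features(x)
        rpn_cls, rpn_reg = self._forward_rpn(feat8)

        # --- RPN losses
        sel_idx, sel_lab, pos_idx, pos_targets = [], [], [], []
        for i, boxes in enumerate(gt_list):
            gt = np.stack([b.as_array() for b in boxes]) if boxes else np.zeros((0, 4))
            pos, neg, targets = self._rpn_targets(gt)
            sel_idx.append(i * k + np.concatenate([pos, neg]))
            sel_lab.append(np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]))
            pos_idx.append(i * k + pos)
            pos_targets.append(targets)
        sel_idx = np.concatenate(sel_idx)
        sel_lab = np.concatenate(sel_lab)
        pos_idx = np.concatenate(pos_idx)
        pos_targets = np.vstack(pos_targets)
        n_sampled = max(len(sel_idx), 1)
        loss_rpn_cls = nn.bce_with_logits(nn.take(rpn_cls, sel_idx), sel_lab)
        if len(pos_idx):
            loss_rpn_reg = nn.regression_loss(
                nn.take(rpn_reg, pos_idx), pos_targets,
                lambda e: np.where(e < 1.0, 0.5 * e * e, e - 0.5),
                lambda e: np.minimum(e, 1.0),
                divisor=float(n_sampled),
            )
        else:
            loss_rpn_reg = nn.Tensor(np.float32(0.0))

        # --- proposals and dynamic second-stage assignment
        proposals = self._proposals(rpn_cls.data, rpn_reg.data, n, training=True)
        roi_feats, roi_labels, roi_targets = [], [], []
        n_fg_total, iou_stats, err_stats = 0, [], []
        for i, boxes in enumerate(gt_list):
            gt = np.stack([b.as_array() for b in boxes]) if boxes else np.zeros((0, 4))
            cls_ids = np.array([b.class_id for b in boxes], dtype=int)
            rois, labels, n_fg, targets, stat_iou, stat_err = self._sample_rois(
                proposals[i], gt, cls_ids, state.assign_state.T_now)
            iou_stats.append(stat_iou)
            if len(stat_err):
                err_stats.append(stat_err)
            roi_feats.append(self._roi_features(feat4, feat8, i, rois))
            roi_labels.append(labels)
            roi_targets.append(targets)
            n_fg_total += n_fg

        rf = nn.concat(roi_feats, axis=0)
        r_total = rf.shape[0]
        h = nn.relu(self.fc2(nn.relu(self.fc1(nn.reshape(rf, (r_total, -1))))))
        logits = self.fc_cls(h)
        reg = self.fc_reg(h)
        labels_all = np.concatenate(roi_labels)
        loss_cls = nn.softmax_cross_entropy(logits, labels_all)

        # positives sit first within each image's roi block
        offsets = np.cumsum([0] + [len(l) for l in roi_labels[:-1]])
        fg_rows = np.concatenate(
            [off + np.arange(len(t)) for off, t in zip(offsets, roi_targets)]
        ).astype(int)
        if len(fg_rows):
            value_fn, grad_fn = self._reg_loss_fns(state)
            loss_reg = nn.regression_loss(nn.take(reg, fg_rows),
                                          np.vstack(roi_targets),
                                          value_fn, grad_fn,
                                          divisor=float(max(r_total, 1)))
        else:
            loss_reg = nn.Tensor(np.float32(0.0))

        total = nn.add(nn.add(loss_rpn_cls, loss_rpn_reg), nn.add(loss_cls, loss_reg))
        self.optimizer.zero_grad()
        total.backward()
        self._clip_gradients()
        self.optimizer.step()

        # --- dynamic schedule bookkeeping (shared cadence, shared warm-up);
        # with no foreground proposals this iteration, the current alpha is
        # recorded as a neutral statistic so both buffers stay in lockstep
        update_threshold(state.assign_state, np.concatenate(iou_stats))
        update_alpha(state.loss_state,
                     np.concatenate(err_stats) if err_stats
                     else np.array([state.loss_state.alpha_now]))
        state.iteration += 1
        losses = {
            "rpn_cls": float(loss_rpn_cls.data), "rpn_reg": float(loss_rpn_reg.data),
            "cls": float(loss_cls.data), "reg": float(loss_reg.data),
            "total": float(total.data),
        }
        state.history.append({
            "iteration": state.iteration, **losses,
            "T_now": state.assign_state.T_now,
            "alpha_now": state.loss_state.alpha_now,
            "n_fg": n_fg_total,
        })
        return losses, state

    def _clip_gradients(self):
        if not self.config.grad_clip:
            return
        sq = 0.0
        for p in self.parameters():
            if p.grad is not None:
                sq += float((p.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(sq)
        if norm > self.config.grad_clip:
            s = self.config.grad_clip / (norm + 1e-6)
            for p in self.parameters():
                if p.grad is not None:
                    p.grad *= s

    # -- inference ----------------------------------------------------------

    def predict(self, image) -> list:
        """Post-NMS, score-sorted detections for one image."""
        cfg = self.config
        orig = np.asarray(image, dtype=np.float32)
        orig_shape = orig.shape[-2:]
        img = self._prepare_image(image)
        sx = orig_shape[1] / cfg.input_size
        sy = orig_shape[0] / cfg.input_size
        feat4, feat8 = self._forward_features(img[None, None])
        rpn_cls, rpn_reg = self._forward_rpn(feat8)
        proposals = self._proposals(rpn_cls.data, rpn_reg.data, 1, training=False)[0]
        if len(proposals) == 0:
            return []
        rf = self._roi_features(feat4, feat8, 0, proposals)
        h = nn.relu(self.fc2(nn.relu(self.fc1(nn.reshape(rf, (len(proposals), -1))))))
        logits = self.fc_cls(h).data.astype(np.float64)
        reg = self.fc_reg(h).data.astype(np.float64)
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        boxes = decode_deltas(proposals, reg, HEAD_STDS, cfg.input_size)
        detections = []
        for c in range(cfg.num_classes):
            sc = probs[:, c]
            ok = sc > cfg.score_threshold
            if not ok.any():
                continue
            keep = nms(boxes[ok], sc[ok], cfg.nms_iou)
            for b, s in zip(boxes[ok][keep], sc[ok][keep]):
                x0, y0, x1, y1 = b
                if x1 - x0 < 1.0 or y1 - y0 < 1.0:
                    continue
                detections.append(BoundingBox(
                    x0 * sx, y0 * sy, x1 * sx, y1 * sy,
                    class_id=c, score=float(s)))
        detections.sort(key=lambda d: -d.score)
        return detections[:cfg.max_detections]

    # -- persistence --------------------------------------------------------

    def save(self, path, state: TrainingState | None = None):
        """Checkpoint parameters, config and (optionally) the full training
        state — iteration counter, both dynamic schedules with their buffers,
        and the loss history — so training can resume exactly."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        if state is not None:
            blob = {
                "iteration": state.iteration,
                "loss_state": asdict(state.loss_state),
                "assign_state": asdict(state.assign_state),
                "history": state.history,
            }
            arrays["state_json"] = np.frombuffer(json.dumps(blob).encode(),
                                                 dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        """Restore a checkpoint; returns ``(detector, state_or_None)``."""
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
            for key in ("scconv_placement", "anchor_scales", "anchor_ratios",
                        "alpha_clamp", "t_clamp"):
                cfg_dict[key] = tuple(cfg_dict[key])
            det = cls(DetectorConfig(**cfg_dict))
            for i, p in enumerate(det.parameters()):
                p.data = data[f"p{i}"].copy()
            state = None
            if "state_json" in data:
                blob = json.loads(bytes(data["state_json"].tobytes()).decode())
                ls = blob["loss_state"]
                ls["clamp"] = tuple(ls["clamp"])
                ass = blob["assign_state"]
                ass["clamp"] = tuple(ass["clamp"])
                state = TrainingState(
                    iteration=blob["iteration"],
                    loss_state=DynamicLossState(**ls),
                    assign_state=AssignmentState(**ass),
                    history=blob["history"],
                )
        return det, state


def build_detector(config: DetectorConfig) -> Detector:
    """Construct a detector with deterministic, seeded initialization."""
    return Detector(config)


def train_detector(detector: Detector, dataset, epochs: int | None = None,
                   batch_size: int = 4, state: TrainingState | None = None,
                   log_every: int = 50) -> TrainingState:
    """Full training loop over a phantom dataset (seeded shuffling)."""
    cfg = detector.config
    epochs = cfg.epochs if epochs is None else epochs
    state = state or detector.new_training_state()
    rng = np.random.default_rng(cfg.seed + 1000)
    n = len(dataset)
    # standard step schedule: decay the learning rate 10x at 3/4 and 11/12
    # of the run (the classic "1x" milestones for a 12-epoch schedule)
    milestones = {int(epochs * 3 / 4), int(epochs * 11 / 12)} if epochs >= 4 else set()
    for epoch in range(epochs):
        if epoch in milestones:
            detector.optimizer.lr *= 0.1
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = [(dataset.images[i], dataset.boxes[i]) for i in idx]
            losses, state = detector.training_step(batch, state)
            if state.iteration % log_every == 0:
                logger.info(
                    "iter %d epoch %d total %.4f (T_now %.3f alpha %.3f)",
                    state.iteration, epoch, losses["total"],
                    state.assign_state.T_now, state.loss_state.alpha_now)
    return state
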