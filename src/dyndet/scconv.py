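"""Self-calibrated convolution: a drop-in replacement for a plain KxK conv.

A standard convolution with a (C, C, k_h, k_w) filter bank is split into four
equal groups K1..K4 of shape (C/2, C/2, k_h, k_w), and the input X into
channel halves X1, X2. The first half is *self-calibrated*: a context signal
is computed in a downsampled space (average pooling with rate r, convolution
with K2, bilinear upsampling back to (H, W)), added to X1 and squashed by a
sigmoid to form a spatial gate that multiplies the K3 response of X1; a final
K4 convolution produces Y1. The second half goes through a plain K1
convolution to Y2, and the output is the channel concatenation [Y1, Y2]. The
gate lets each location modulate its response with context from a larger
effective receptive field at no extra kernel size.

All operations here are functional, on single feature maps of shape
(C, H, W), with 'same' zero padding so spatial dimensions are preserved (the
calibration sum X1 + up(...) requires it). The trainable block used inside
the detector (:class:`dyndet.detector.SCConvBlock`) evaluates exactly this
pipeline through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyndet import nn
from dyndet.exceptions import InvalidParameterError, ShapeError

__all__ = [
    "SCConvFilters",
    "split_channels",
    "downsample_avg",
    "calibrate",
    "scconv_forward",
]


@dataclass(frozen=True)
class SCConvFilters:
    """The four filter groups and pooling rate of one self-calibrated block.

    Each of K1..K4 has shape (C/2, C/2, k_h, k_w) with odd k_h = k_w (odd so
    that 'same' zero padding is symmetric); ``r >= 1`` is the average-pooling
    rate of the calibration branch.
    """

    K1: np.ndarray
    K2: np.ndarray
    K3: np.ndarray
    K4: np.ndarray
    r: int = 4

    def __post_init__(self):
        shapes = {np.asarray(k).shape for k in (self.K1, self.K2, self.K3, self.K4)}
        if len(shapes) != 1:
            raise ShapeError(f"filter groups must share one shape, got {shapes}")
        (co, ci, kh, kw) = next(iter(shapes))
        if co != ci:
            raise ShapeError(f"filters must be square in channels, got ({co}, {ci})")
        if kh != kw or kh % 2 == 0:
            raise ShapeError(f"kernel must be odd and square, got ({kh}, {kw})")
        if self.r < 1:
            raise InvalidParameterError(f"pooling rate must be >= 1, got {self.r}")

    @property
    def half_channels(self) -> int:
        return self.K1.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.K1.shape[2]

    @classmethod
    def random(cls, channels: int, kernel_size: int = 3, r: int = 4,
               rng: np.random.Generator | None = None) -> "SCConvFilters":
        """He-scaled random filters for a C-channel block (C even)."""
        if channels % 2:
            raise ShapeError(f"channel count must be even, got {channels}")
        rng = rng or np.random.default_rng()
        c2 = channels // 2
        std = np.sqrt(2.0 / (c2 * kernel_size * kernel_size))
        ks = [rng.normal(0.0, std, size=(c2, c2, kernel_size, kernel_size))
              for _ in range(4)]
        return cls(*ks, r=r)


def _check_map(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ShapeError(f"feature map must be (C, H, W), got shape {x.shape}")
    return x


def split_channels(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split (C, H, W) into contiguous channel halves (X1 first, X2 second)."""
    x = _check_map(x)
    c = x.shape[0]
    if c % 2:
        raise ShapeError(f"channel count must be even to split, got {c}")
    return x[: c // 2], x[c // 2:]


def downsample_avg(x1: np.ndarray, r: int) -> np.ndarray:
    """Average pooling with kernel and stride r (floor output size)."""
    x1 = _check_map(x1)
    return nn.avgpool2d_forward(x1[None], r)[0]


def _conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    pad = k.shape[2] // 2
    out, _ = nn.conv2d_forward(x[None], k, stride=1, pad=pad)
    return out[0]


def calibrate(x1: np.ndarray, filters: SCConvFilters) -> np.ndarray:
    """Gated response Y1' = (X1 * K3) ⊙ sigmoid(X1 + up(avgpool_r(X1) * K2)).

    The upsampling always targets X1's own (H, W), so the output shape equals
    the input shape regardless of divisibility by r.
    """
    x1 = _check_map(x1)
    if x1.shape[0] != filters.half_channels:
        raise ShapeError(
            f"X1 has {x1.shape[0]} channels, filters expect {filters.half_channels}"
        )
    h, w = x1.shape[1:]
    t1 = downsample_avg(x1, filters.r)
    x1p = nn.bilinear_resize(_conv_same(t1, filters.K2), h, w)
    if x1p.shape != x1.shape:  # pragma: no cover - upsample targets (H, W)
        raise ShapeError(f"calibration shape mismatch: {x1p.shape} vs {x1.shape}")
    gate = nn.sigmoid(x1 + x1p)
    return _conv_same(x1, filters.K3) * gate


def scconv_forward(x: np.ndarray, filters: SCConvFilters) -> np.ndarray:
    """Full block: Y = concat[ calibrate(X1) * K4 , X2 * K1 ], shape-preserving."""
    x1, x2 = split_channels(_check_map(x))
    y1 = _conv_same(calibrate(x1, filters), filters.K4)
    y2 = _conv_same(x2, filters.K1)
    return np.concatenate([y1, y2], axis=0)
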