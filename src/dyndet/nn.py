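"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector needs exact gradients through convolutions, pooling, bilinear
resizing, RoI feature extraction and the piecewise regression losses. This
module provides a small tape-based autodiff engine (a :class:`Tensor` holding
a numpy array plus a backward closure) and the handful of differentiable
operations the detector uses, together with the dtype-preserving low-level
numpy kernels (im2col convolution, average pooling, bilinear interpolation
matrices) that the self-calibrated convolution module reuses directly.

Convolutions are evaluated as im2col + matmul so that both the forward and
the backward pass reduce to BLAS calls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dyndet.exceptions import InvalidInputError, InvalidParameterError

# ---------------------------------------------------------------------------
# low-level numpy kernels (no autodiff; dtype-preserving)
# ---------------------------------------------------------------------------


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Unfold (N, C, H, W) into (N*Ho*Wo, C*kh*kw) patch rows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(col), ho, wo


def col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter patch-row gradients back."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcol.dtype)
    d6 = dcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += d6[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad:hp - pad, pad:wp - pad]
    return dxp


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                   stride: int = 1, pad: int = 0):
    """Plain 2D convolution (cross-correlation) on (N, C, H, W).

    Returns ``(out, col)``; ``col`` is the im2col cache reused by backward.
    """
    o, ci, kh, kw = w.shape
    if x.shape[1] != ci:
        raise InvalidInputError(f"channel mismatch: input {x.shape[1]}, filter {ci}")
    col, ho, wo = im2col(x, kh, kw, stride, pad)
    out = col @ w.reshape(o, -1).T
    if b is not None:
        out += b
    n = x.shape[0]
    return out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2), col


def avgpool2d_forward(x: np.ndarray, r: int) -> np.ndarray:
    """Average pooling with kernel r, stride r; trailing rows/cols beyond a
    full window are dropped (floor semantics)."""
    if r < 1:
        raise InvalidParameterError(f"pooling rate must be >= 1, got {r}")
    n, c, h, w = x.shape
    if r > h or r > w:
        raise InvalidParameterError(f"pooling rate {r} exceeds spatial dims ({h}, {w})")
    if r == 1:
        return x.copy()
    ho, wo = h // r, w // r
    return x[:, :, :ho * r, :wo * r].reshape(n, c, ho, r, wo, r).mean(axis=(3, 5))


def bilinear_matrix(in_size: int, out_size: int, dtype=np.float64) -> np.ndarray:
    """Row-interpolation matrix A (out, in) for bilinear resizing with the
    half-pixel (align_corners=False) convention."""
    a = np.zeros((out_size, in_size), dtype=dtype)
    if in_size == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0.0, in_size - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    a[np.arange(out_size), lo] += 1.0 - frac
    a[np.arange(out_size), hi] += frac
    return a


def bilinear_resize(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of (..., H, W) to (..., out_h, out_w)."""
    h, w = x.shape[-2:]
    a = bilinear_matrix(h, out_h, dtype=x.dtype)
    b = bilinear_matrix(w, out_w, dtype=x.dtype)
    return np.matmul(a, np.matmul(x, b.T))


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype, copy=False)


# ---------------------------------------------------------------------------
# autodiff tape
# ---------------------------------------------------------------------------


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise InvalidInputError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # light operator sugar used by the detector
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _node(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient g to the given (broadcast-source) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# -- arithmetic --------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s)

    return _node(a.data * s, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _node(a.data @ b.data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(gp)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis with zero-padded backward."""
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        if a.requires_grad:
            da = np.zeros_like(a.data)
            da[sl] = g
            a.accumulate(da)

    return _node(a.data[sl].copy(), (a,), backward)


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather along axis 0 with scatter-add backward."""
    idx = np.asarray(idx)

    def backward(g):
        if a.requires_grad:
            da = np.zeros_like(a.data)
            np.add.at(da, idx, g)
            a.accumulate(da)

    return _node(a.data[idx], (a,), backward)


# -- nonlinearities ----------------------------------------------------------


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def sigmoid_t(a: Tensor) -> Tensor:
    s = sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


# -- structured layers -------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    out_np, col = conv2d_forward(x.data, w.data, None if b is None else b.data,
                                 stride=stride, pad=pad)
    o, ci, kh, kw = w.shape
    n, _, ho, wo = out_np.shape
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gcol = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if b is not None and b.requires_grad:
            b.accumulate(gcol.sum(axis=0))
        if w.requires_grad:
            w.accumulate((gcol.T @ col).reshape(w.shape))
        if x.requires_grad:
            dcol = gcol @ w.data.reshape(o, -1)
            x.accumulate(col2im(dcol, x.shape, kh, kw, stride, pad))

    return _node(out_np, parents, backward)


def avgpool2d(x: Tensor, r: int) -> Tensor:
    out_np = avgpool2d_forward(x.data, r)
    if r == 1:
        def backward1(g):
            if x.requires_grad:
                x.accumulate(g)
        return _node(out_np, (x,), backward1)
    n, c, ho, wo = out_np.shape

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            expanded = np.repeat(np.repeat(g, r, axis=2), r, axis=3) / (r * r)
            dx[:, :, :ho * r, :wo * r] = expanded
            x.accumulate(dx)

    return _node(out_np, (x,), backward)


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    h, w = x.shape[-2:]
    a = bilinear_matrix(h, out_h, dtype=x.data.dtype)
    bmat = bilinear_matrix(w, out_w, dtype=x.data.dtype)
    out_np = np.matmul(a, np.matmul(x.data, bmat.T))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.matmul(a.T, np.matmul(g, bmat)))

    return _node(out_np, (x,), backward)


def roi_align_weights(rois: np.ndarray, feat_h: int, feat_w: int,
                      spatial_scale: float, out_size: int,
                      dtype=np.float32, sampling: int = 2) -> np.ndarray:
    """Bilinear sampling matrix (R*out*out, H*W).

    Each output bin averages ``sampling x sampling`` bilinear samples placed
    on a regular sub-grid of the bin; pixel centers sit at half-integer
    continuous coordinates and samples are clamped inside the feature map.
    """
    rois = np.asarray(rois, dtype=np.float64).reshape(-1, 4) * spatial_scale
    n_rois = rois.shape[0]
    wm = np.zeros((n_rois * out_size * out_size, feat_h * feat_w), dtype=dtype)
    if n_rois == 0:
        return wm
    frac = 1.0 / (sampling * sampling)
    x1, y1, x2, y2 = rois.T
    bw = np.maximum(x2 - x1, 1e-3) / out_size
    bh = np.maximum(y2 - y1, 1e-3) / out_size
    bins = np.arange(out_size)
    rows = ((np.arange(n_rois)[:, None, None] * out_size + bins[None, :, None])
            * out_size + bins[None, None, :]).ravel()
    for si in range(sampling):
        py = y1[:, None] + (bins[None, :] + (si + 0.5) / sampling) * bh[:, None] - 0.5
        py = np.clip(py, 0.0, feat_h - 1.0)
        y0 = np.floor(py).astype(int)
        y1i = np.minimum(y0 + 1, feat_h - 1)
        fy = py - y0
        for sj in range(sampling):
            px = x1[:, None] + (bins[None, :] + (sj + 0.5) / sampling) * bw[:, None] - 0.5
            px = np.clip(px, 0.0, feat_w - 1.0)
            x0 = np.floor(px).astype(int)
            x1i = np.minimum(x0 + 1, feat_w - 1)
            fx = px - x0
            for yy, wy in ((y0, 1 - fy), (y1i, fy)):
                for xx, wx in ((x0, 1 - fx), (x1i, fx)):
                    cols = (yy[:, :, None] * feat_w + xx[:, None, :]).ravel()
                    vals = (wy[:, :, None] * wx[:, None, :]).ravel() * frac
                    np.add.at(wm, (rows, cols), vals.astype(dtype))
    return wm


def roi_align(feat: Tensor, rois: np.ndarray, spatial_scale: float,
              out_size: int) -> Tensor:
    """Extract (R, C, out, out) RoI features from a single-image (C, H, W) map."""
    c, h, w = feat.shape
    n_rois = np.asarray(rois).reshape(-1, 4).shape[0]
    wm = roi_align_weights(rois, h, w, spatial_scale, out_size, dtype=feat.data.dtype)
    flat = feat.data.reshape(c, h * w)
    out = (wm @ flat.T).reshape(n_rois, out_size, out_size, c).transpose(0, 3, 1, 2)

    def backward(g):
        if feat.requires_grad:
            grows = g.transpose(0, 2, 3, 1).reshape(-1, c)
            feat.accumulate((wm.T @ grows).T.reshape(c, h, w))

    return _node(np.ascontiguousarray(out), (feat,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map y = x @ W^T + b for (N, in) inputs."""
    return add(matmul(x, transpose(w, (1, 0))), b)


# -- losses ------------------------------------------------------------------


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    labels = np.asarray(labels, dtype=int)
    n, c = logits.shape
    if labels.size and (labels.min() < 0 or labels.max() >= c):
        raise InvalidInputError(
            f"labels must lie in [0, {c - 1}], got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits.accumulate(g * p / n)

    return _node(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (stable formulation)."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    n = z.size

    def backward(g):
        if logits.requires_grad:
            logits.accumulate(g * (sigmoid(z) - t) / n)

    return _node(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def regression_loss(pred: Tensor, target: np.ndarray, value_fn, grad_fn,
                    divisor: float) -> Tensor:
    """Sum of an elementwise loss of |pred - target|, divided by ``divisor``.

    ``value_fn``/``grad_fn`` map the non-negative error array to the loss
    value / dL/d|x| arrays; they carry the piecewise regression-loss shape
    (Smooth L1 or the dynamic balanced variant) supplied by the caller.
    """
    t = np.asarray(target, dtype=pred.data.dtype)
    d = pred.data - t
    x = np.abs(d)
    loss = value_fn(x).sum() / divisor

    def backward(g):
        if pred.requires_grad:
            pred.accumulate(g * np.sign(d) * grad_fn(x) / divisor)

    return _node(np.asarray(loss, dtype=pred.data.dtype), (pred,), backward)


# -- optimizer ---------------------------------------------------------------


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay
    (decay added to the raw gradient, as in standard detector training)."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
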