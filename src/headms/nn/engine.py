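"""Minimal reverse-mode autodiff over NumPy arrays for 2-D segmentation networks.

All activations are float32 NHWC.  Convolutions are lowered to BLAS matrix
products via im2col; the gradient with respect to the input is itself computed
as a same-padded convolution with the channel-transposed, spatially flipped
kernel, so no scatter-add (col2im) is ever needed.  Transposed convolutions
are implemented as zero-dilation followed by an ordinary convolution, with the
kernel stored directly in correlation form.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode); saves activation caches."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = data
        self.grad = None
        self.parents = parents if _grad_enabled else ()
        self.bwd = bwd if _grad_enabled else None

    @property
    def shape(self):
        return self.data.shape


class Param(Tensor):
    """A trainable leaf tensor (weights / biases / norm affine terms)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32))
        # leaves always take part in the tape, even when created under no_grad
        self.parents = ()
        self.bwd = None


def backward(out: Tensor, grad_out: np.ndarray) -> None:
    """Run reverse-mode accumulation from ``out`` seeded with ``grad_out``."""
    topo, seen = [], set()
    stack = [(out, False)]
    while stack:  # iterative DFS; network depth can exceed recursion limit
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    out.grad = grad_out.astype(np.float32, copy=False)
    for node in reversed(topo):
        if node.bwd is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.bwd(node.grad)):
            if g is None:
                continue
            parent.grad = g if parent.grad is None else parent.grad + g
        node.grad = None  # free intermediate gradients eagerly
        node.bwd = None


# ---------------------------------------------------------------------------
# convolution primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded k x k patches of NHWC ``x`` as an (N*H*W, k*k*C) matrix."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(-1, k * k * x.shape[3])


def _conv_raw(x, wmat, b, k):
    n, h, w, _ = x.shape
    cols = _im2col(x, k)
    y = cols @ wmat
    y += b
    cout = wmat.shape[1]
    return y.reshape(n, h, w, cout), cols


def _flip_transpose(wmat, k, cin, cout):
    """Kernel for the input-gradient convolution: spatial flip + channel swap."""
    w4 = wmat.reshape(k, k, cin, cout)
    return np.ascontiguousarray(
        w4[::-1, ::-1].transpose(0, 1, 3, 2)
    ).reshape(k * k * cout, cin)


def conv2d(x: Tensor, w: Param, b: Param, k: int = 3) -> Tensor:
    """Same-padded stride-1 convolution.  ``w.data`` has shape (k*k*Cin, Cout)."""
    cin = x.data.shape[3]
    y, cols = _conv_raw(x.data, w.data, b.data, k)
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        gy_flat = gy.reshape(-1, gy.shape[3])
        dw = cols.T @ gy_flat
        db = gy_flat.sum(axis=0)
        wb = _flip_transpose(w.data, k, cin, gy.shape[3])
        dx, _ = _conv_raw(gy, wb, np.float32(0.0), k)
        return dx, dw, db

    return Tensor(y, (x, w, b), bwd)


def conv1x1(x: Tensor, w: Param, b: Param, stride: int = 1) -> Tensor:
    """Pointwise convolution; ``w.data`` has shape (Cin, Cout)."""
    xs = x.data[:, ::stride, ::stride, :] if stride > 1 else x.data
    y = xs @ w.data + b.data
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        gflat = gy.reshape(-1, gy.shape[3])
        dw = xs.reshape(-1, xs.shape[3]).T @ gflat
        db = gflat.sum(axis=0)
        dxs = gy @ w.data.T
        if stride > 1:
            dx = np.zeros_like(x.data)
            dx[:, ::stride, ::stride, :] = dxs
        else:
            dx = dxs
        return dx, dw, db

    return Tensor(y, (x, w, b), bwd)


def conv_transpose2x(x: Tensor, w: Param, b: Param) -> Tensor:
    """3x3 stride-2 transposed convolution doubling the spatial size.

    Equivalent to zero-dilating the input onto the even grid of a 2H x 2W
    canvas and applying a same-padded 3x3 convolution.
    """
    n, h, ww, c = x.data.shape
    z = np.zeros((n, 2 * h, 2 * ww, c), dtype=np.float32)
    z[:, ::2, ::2, :] = x.data
    y, cols = _conv_raw(z, w.data, b.data, 3)
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        gy_flat = gy.reshape(-1, gy.shape[3])
        dw = cols.T @ gy_flat
        db = gy_flat.sum(axis=0)
        wb = _flip_transpose(w.data, 3, c, gy.shape[3])
        dz, _ = _conv_raw(gy, wb, np.float32(0.0), 3)
        return dz[:, ::2, ::2, :], dw, db

    return Tensor(y, (x, w, b), bwd)


# ---------------------------------------------------------------------------
# pooling / resampling


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    v = np.ascontiguousarray(
        x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    ).reshape(n, h // 2, w // 2, c, 4)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        dv = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dv, idx[..., None], gy[..., None], axis=-1)
        dx = dv.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return (dx.reshape(n, h, w, c),)

    return Tensor(y, (x,), bwd)


def avgpool3x3(x: Tensor) -> Tensor:
    """3x3 stride-1 zero-padded mean filter (self-adjoint, so bwd = fwd op)."""

    def _filt(a):
        return ndimage.uniform_filter(a, size=(1, 3, 3, 1), mode="constant")

    y = _filt(x.data)
    if not _grad_enabled:
        return Tensor(y)
    return Tensor(y, (x,), lambda gy: (_filt(gy),))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour spatial doubling."""
    y = x.data.repeat(2, axis=1).repeat(2, axis=2)
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        n, h2, w2, c = gy.shape
        return (gy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)),)

    return Tensor(y, (x,), bwd)


# ---------------------------------------------------------------------------
# elementwise / shape ops


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    if not _grad_enabled:
        return Tensor(y)
    return Tensor(y, (x,), lambda gy: (np.where(x.data > 0, gy, 0.0),))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    if not _grad_enabled:
        return Tensor(y)
    return Tensor(y, (x,), lambda gy: (gy * (y * (1.0 - y)),))


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data
    if not _grad_enabled:
        return Tensor(y)
    return Tensor(y, (a, b), lambda gy: (gy, gy))


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product; supports a single-channel ``b`` broadcast over ``a``."""
    y = a.data * b.data
    if not _grad_enabled:
        return Tensor(y)

    def bwd(gy):
        ga = gy * b.data
        gb = gy * a.data
        if b.data.shape[3] == 1 and a.data.shape[3] > 1:
            gb = gb.sum(axis=3, keepdims=True)
        return ga, gb

    return Tensor(y, (a, b), bwd)


def concat(tensors) -> Tensor:
    """Channel concatenation (NHWC axis 3)."""
    y = np.concatenate([t.data for t in tensors], axis=3)
    if not _grad_enabled:
        return Tensor(y)
    sizes = [t.data.shape[3] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(gy):
        return tuple(np.ascontiguousarray(g) for g in np.split(gy, splits, axis=3))

    return Tensor(y, tuple(tensors), bwd)


def batchnorm(x: Tensor, gamma: Param, beta: Param, running_mean, running_var,
              training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization with running statistics."""
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gamma.data * xhat + beta.data
    if not _grad_enabled:
        return Tensor(y)

    m = float(x.data.shape[0] * x.data.shape[1] * x.data.shape[2])

    def bwd(gy):
        dgamma = (gy * xhat).sum(axis=(0, 1, 2))
        dbeta = gy.sum(axis=(0, 1, 2))
        if training:
            dx = (gamma.data * inv / m) * (
                m * gy - dbeta - xhat * dgamma
            )
        else:
            dx = gy * (gamma.data * inv)
        return dx.astype(np.float32, copy=False), dgamma, dbeta

    return Tensor(y, (x, gamma, beta), bwd)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last (class) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
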