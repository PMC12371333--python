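"""A minimal reverse-mode automatic-differentiation engine over NumPy arrays.

Define-by-run: every operation records its parents and a backward closure;
:meth:`Tensor.backward` runs a topological sort and accumulates gradients.
The op set is exactly what the affinity models need: broadcast arithmetic,
matmul, pointwise nonlinearities, reshape/transpose/concat/slice, reductions,
and a 3-D convolution implemented as im2col + GEMM.

Gradients are validated against central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from itertools import product as _iproduct

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import GridbindError

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# -- arithmetic ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out, (a, b), bwd)


# -- nonlinearities ------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = x.data * mask

    def bwd(g):
        x._accumulate(g * mask)

    return _make(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * out * (1.0 - out))

    return _make(out, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.tanh(x.data)

    def bwd(g):
        x._accumulate(g * (1.0 - out * out))

    return _make(out, (x,), bwd)


# -- shape ops -----------------------------------------------------------

def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    out = x.data.reshape(shape)

    def bwd(g):
        x._accumulate(g.reshape(x.shape))

    return _make(out, (x,), bwd)


def transpose(x: Tensor, axes) -> Tensor:
    x = _as_tensor(x)
    out = np.transpose(x.data, axes)
    inv = np.argsort(axes)

    def bwd(g):
        x._accumulate(np.transpose(g, inv))

    return _make(out, (x,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out, tuple(tensors), bwd)


def getitem(x: Tensor, key) -> Tensor:
    x = _as_tensor(x)
    out = x.data[key]

    def bwd(g):
        full = np.zeros_like(x.data)
        np.add.at(full, key, g)
        x._accumulate(full)

    return _make(out, (x,), bwd)


# -- reductions ----------------------------------------------------------

def tsum(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = _as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        x._accumulate(np.broadcast_to(g, x.shape).copy())

    return _make(out, (x,), bwd)


def tmean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = _as_tensor(x)
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.shape[a] for a in axes]))
    return mul(tsum(x, axis, keepdims), 1.0 / n)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=pred.dtype))
    return tmean(mul(diff, diff))


# -- convolution ---------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3-D cross-correlation: x (N,C,D,H,W), w (O,C,k,k,k) -> (N,O,D',H',W')."""
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, D, H, W = x.shape
    O, Cw, k, _, _ = w.shape
    if Cw != C:
        raise GridbindError(f"conv3d expected {Cw} input channels, got {C}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    # win: (N, C, Do, Ho, Wo, k, k, k)
    _, _, Do, Ho, Wo, _, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(N * Do * Ho * Wo, C * k ** 3)
    wm = w.data.reshape(O, C * k ** 3)
    out = (cols @ wm.T).reshape(N, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1, 1)

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(N * Do * Ho * Wo, O)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if w.requires_grad:
            w._accumulate((gm.T @ cols).reshape(w.shape))
        if x.requires_grad:
            gcols = (gm @ wm).reshape(N, Do, Ho, Wo, C, k, k, k)
            gxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=x.dtype)
            for a, bb, c in _iproduct(range(k), range(k), range(k)):
                gxp[:, :, a:a + s * Do:s, bb:bb + s * Ho:s, c:c + s * Wo:s] += \
                    gcols[:, :, :, :, :, a, bb, c].transpose(0, 4, 1, 2, 3)
            if p:
                gxp = gxp[:, :, p:-p, p:-p, p:-p]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bwd)


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling; trailing voxels beyond a multiple of
    ``factor`` are cropped."""
    N, C, D, H, W = x.shape
    f = factor
    d, h, w = D // f, H // f, W // f
    if d < 1 or h < 1 or w < 1:
        raise GridbindError(f"cannot pool spatial shape {(D, H, W)} by {f}")
    cropped = x[:, :, :d * f, :h * f, :w * f]
    r = reshape(cropped, (N, C, d, f, h, f, w, f))
    return tmean(r, axis=(3, 5, 7))


def global_mean_pool(x: Tensor) -> Tensor:
    """Mean over all spatial axes: (N, C, D, H, W) -> (N, C)."""
    return tmean(x, axis=(2, 3, 4))
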