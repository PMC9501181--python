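"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation builds a :class:`Tensor` holding
the forward value and a closure that scatters the output gradient back to
its parents.  ``Tensor.backward()`` runs the closures in reverse topological
order.  Only the operations the segmentation network needs are implemented
(dense/batched matmul, 2-D convolution and its transpose, softmax, the usual
pointwise nonlinearities, reductions and layout ops); all of them preserve
the dtype of their inputs so the same graph can be gradient-checked in
float64 and trained in float32.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "matmul",
    "softmax",
    "sigmoid",
    "relu",
    "relu6",
    "gelu",
    "index_select",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._make(self.data ** e, (self,), bw)

    # -- transcendental -------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(self.dtype))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        arg = self.data == out_data  # all maxima share the gradient

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            counts = arg.sum(axis=axis, keepdims=True)
            self._accumulate(np.where(arg, gg / counts, 0).astype(self.dtype))

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(data, (self,), bw)

    # -- layout ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)

        return Tensor._make(self.data[key], (self,), bw)

    def pad(self, pad_width):
        """Zero-pad; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple(tuple(p) for p in pad_width)

        def bw(g):
            sl = tuple(slice(b, g.shape[i] - a) for i, (b, a) in enumerate(pw))
            self._accumulate(g[sl])

        return Tensor._make(np.pad(self.data, pw), (self,), bw)

    def roll(self, shifts, axes):
        def bw(g):
            neg = tuple(-s for s in (shifts if isinstance(shifts, tuple) else (shifts,)))
            self._accumulate(np.roll(g, neg, axis=axes))

        return Tensor._make(np.roll(self.data, shifts, axis=axes), (self,), bw)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; leading batch dims of a and b must match."""

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return Tensor._make(a.data @ b.data, (a, b), bw)


def concat(tensors, axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def index_select(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of ``table`` (first axis) at integer ``idx``."""
    idx = np.asarray(idx)

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, *table.shape[1:]))
        table._accumulate(full)

    return Tensor._make(table.data[idx], (table,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate((y * (g - dot)).astype(x.dtype))

    return Tensor._make(y, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * y * (1.0 - y))

    return Tensor._make(y, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0), (x,), bw)


def relu6(x: Tensor) -> Tensor:
    mask = (x.data > 0) & (x.data < 6)

    def bw(g):
        x._accumulate(g * mask)

    return Tensor._make(np.clip(x.data, 0, 6), (x,), bw)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))

    def bw(g):
        pdf = np.exp(-0.5 * x.data * x.data) * _INV_SQRT2PI
        x._accumulate(g * (cdf + x.data * pdf))

    return Tensor._make(x.data * cdf, (x,), bw)


# ----------------------------------------------------------------------
# 2-D convolution primitives (NCHW layout, im2col based)
# ----------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, d: int, oh: int, ow: int):
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh * kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = xp[
                :, :, i * d : i * d + s * (oh - 1) + 1 : s,
                j * d : j * d + s * (ow - 1) + 1 : s,
            ]
    return cols


def _col2im(cols, xp_shape, kh, kw, s, d, oh, ow):
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[
                :, :, i * d : i * d + s * (oh - 1) + 1 : s,
                j * d : j * d + s * (ow - 1) + 1 : s,
            ] += cols[:, :, i * kw + j]
    return xp


def _conv_fwd(x, w, s, p, d, g):
    n, c, h, wd = x.shape
    co, cig, kh, kw = w.shape
    oh, ow = _out_size(h, kh, s, p, d), _out_size(wd, kw, s, p, d)
    cols = _im2col(_pad_hw(x, p), kh, kw, s, d, oh, ow)
    colsr = cols.reshape(n, g, cig * kh * kw, oh * ow)
    wr = w.reshape(g, co // g, cig * kh * kw)
    y = wr[None] @ colsr
    return y.reshape(n, co, oh, ow)


def _conv_dw(dy, x, w_shape, s, p, d, g):
    n, c, h, wd = x.shape
    co, cig, kh, kw = w_shape
    oh, ow = dy.shape[2], dy.shape[3]
    cols = _im2col(_pad_hw(x, p), kh, kw, s, d, oh, ow)
    colsr = cols.reshape(n, g, cig * kh * kw, oh * ow)
    dyr = dy.reshape(n, g, co // g, oh * ow)
    dw = (dyr @ np.swapaxes(colsr, -1, -2)).sum(axis=0)
    return dw.reshape(w_shape)


def _conv_dx(dy, w, x_shape, s, p, d, g):
    n, c, h, wd = x_shape
    co, cig, kh, kw = w.shape
    oh, ow = dy.shape[2], dy.shape[3]
    wr = w.reshape(g, co // g, cig * kh * kw)
    dyr = dy.reshape(n, g, co // g, oh * ow)
    dcols = np.swapaxes(wr, -1, -2)[None] @ dyr
    dcols = dcols.reshape(n, c, kh * kw, oh, ow)
    xp = _col2im(dcols, (n, c, h + 2 * p, wd + 2 * p), kh, kw, s, d, oh, ow)
    if p:
        xp = xp[:, :, p:-p, p:-p]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weight (I per group)."""
    s, p, d, g = stride, padding, dilation, groups
    y = _conv_fwd(x.data, w.data, s, p, d, g)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(grad):
        if x.requires_grad:
            x._accumulate(_conv_dx(grad, w.data, x.shape, s, p, d, g))
        if w.requires_grad:
            w._accumulate(_conv_dw(grad, x.data, w.shape, s, p, d, g))
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed 2-D convolution (the adjoint of :func:`conv2d`).

    Weight layout is (in_channels, out_channels, kh, kw).  With the default
    kernel 3 / stride 2 / padding 1 / output padding 1 the spatial size is
    exactly doubled.
    """
    s, p, op = stride, padding, output_padding
    ci, co, kh, kw = w.shape
    n, _, h, wd = x.shape
    oh = (h - 1) * s - 2 * p + (kh - 1) + op + 1
    ow = (wd - 1) * s - 2 * p + (kw - 1) + op + 1
    # forward = gradient-wrt-input of a conv with weight viewed as (ci, co, ...)
    y = _conv_dx(x.data, w.data, (n, co, oh, ow), s, p, 1, 1)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(grad):
        if x.requires_grad:
            x._accumulate(_conv_fwd(grad, w.data, s, p, 1, 1))
        if w.requires_grad:
            w._accumulate(_conv_dw(x.data, grad, w.shape, s, p, 1, 1))
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, bw)
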