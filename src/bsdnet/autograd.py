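"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations a convolutional detector needs:
elementwise arithmetic with broadcasting, reductions, shape manipulation,
2-d (grouped/depthwise) convolution via im2col, same-stride max pooling,
nearest-neighbour upsampling, and the SiLU/GELU/sigmoid nonlinearities.
All data is float32.  Gradients are accumulated by walking the tape in
reverse topological order.

A process-wide switch (`no_grad`) disables tape construction for inference,
and a lightweight FLOP recorder can be attached to count the multiply-
accumulate work actually executed by conv/linear ops (1 MAC = 2 FLOPs).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_grad_enabled = True
_flop_recorder: list | None = None


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextlib.contextmanager
def record_flops(counter: list):
    """Record executed conv/linear FLOPs (MAC = 2) into ``counter[0]``."""
    global _flop_recorder
    prev = _flop_recorder
    _flop_recorder = counter
    try:
        yield
    finally:
        _flop_recorder = prev


def _tally(macs: int) -> None:
    if _flop_recorder is not None:
        _flop_recorder[0] += 2 * macs


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents: tuple = ()

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

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

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * out_data / b.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1))

    return Tensor._make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return Tensor._make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return Tensor._make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / out_data)

    return Tensor._make(out_data, (a,), backward)


def absolute(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.abs(a.data)

    def backward(g):
        a._accum(g * np.sign(a.data))

    return Tensor._make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.maximum(a.data, b.data)

    def backward(g):
        # ties route gradient to the first argument
        mask = a.data >= b.data
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.minimum(a.data, b.data)

    def backward(g):
        mask = a.data <= b.data
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    return minimum(maximum(a, lo), hi)


def atan(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        a._accum(g / (1.0 + a.data * a.data))

    return Tensor._make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x)."""
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return Tensor._make(out_data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact (erf-based) GELU: x * Phi(x)."""
    a = _as_tensor(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32)))
    out_data = x * phi

    def backward(g):
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        a._accum(g * (phi + x * pdf).astype(np.float32))

    return Tensor._make(out_data, (a,), backward)


# -- reductions / shape ---------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            grad = np.broadcast_to(g, a.data.shape)
        a._accum(grad)

    return Tensor._make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return Tensor._make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return Tensor._make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        grad = np.zeros_like(a.data)
        np.add.at(grad, idx, g)
        a._accum(grad)

    return Tensor._make(out_data, (a,), backward)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softmax(a, axis: int) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return Tensor._make(out_data, (a,), backward)


# -- spatial ops ----------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-d cross-correlation.  x: (N,C,H,W), w: (O,C,kh,kw), b: (O,) or None."""
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out_data = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    _tally(cols.shape[0] * cols.shape[1] * o)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise conv: one k x k filter per channel.  w: (C,1,kh,kw)."""
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    ker = w.data[:, 0]
    out_data = np.einsum("nchwij,cij->nchw", win, ker, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, c, 1, 1)
    _tally(n * c * ho * wo * kh * kw)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
            w._accum(gw[:, None])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        g * ker[:, i, j][None, :, None, None]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def maxpool2d(x, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Max pooling; gradient flows to every tied maximum inside a window."""
    x = _as_tensor(x)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    out_data = win.max(axis=(4, 5))

    def backward(g):
        gxp = np.zeros_like(xp)
        for i in range(kernel):
            for j in range(kernel):
                mask = win[:, :, :, :, i, j] == out_data
                gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += g * mask
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accum(gxp)

    return Tensor._make(out_data, (x,), backward)


def upsample2x(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = _as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)
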