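"""Minimal reverse-mode automatic differentiation over numpy arrays.

The detector has to run on plain CPU scientific-Python installs, so instead
of depending on a deep-learning framework the package carries a small tape
based autodiff engine: a :class:`Tensor` wrapping a float32 ndarray plus the
handful of differentiable operations the model actually needs (convolution,
normalisation arithmetic, pooling, elementwise math, gather/concat).

Everything is define-by-run: each op returns a new ``Tensor`` holding a
closure that propagates gradients to its parents; ``Tensor.backward`` walks
the tape in reverse topological order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

_F32 = np.float32


def _f32(a) -> np.ndarray:
    return np.asarray(a, dtype=_F32)


class Tensor:
    """A float32 ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _f32(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure so intermediate buffers can be reclaimed
            node._backward = None
            node._prev = ()

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return take(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._saved = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._saved
        return False


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _node(out_data, (a,), backward)


def atan(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = expit(a.data)

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x) — smooth, non-monotonic activation."""
    a = as_tensor(a)
    s = expit(a.data)
    out_data = a.data * s

    def backward(g):
        a._accum(g * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), backward)


def clamp(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    def backward(g):
        a._accum(g * mask)

    return _node(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    pick_a = a.data >= b.data
    out_data = np.where(pick_a, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * pick_a, a.shape))
        b._accum(_unbroadcast(g * ~pick_a, b.shape))

    return _node(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    pick_a = a.data <= b.data
    out_data = np.where(pick_a, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * pick_a, a.shape))
        b._accum(_unbroadcast(g * ~pick_a, b.shape))

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# reductions / reshaping / indexing
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).astype(_F32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).astype(_F32))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _node(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(out_data, (a,), backward)


def take(a, key) -> Tensor:
    """Differentiable ``a[key]`` for any numpy index expression."""
    a = as_tensor(a)
    out_data = a.data[key]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, key, g)
        a._accum(ga)

    return _node(np.ascontiguousarray(out_data), (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _node(out_data, tuple(ts), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int, stride: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols


def _col2im(dcols: np.ndarray, xp_shape, oh: int, ow: int, stride: int) -> np.ndarray:
    kh, kw = dcols.shape[2], dcols.shape[3]
    dxp = np.zeros(xp_shape, dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcols[:, :, i, j]
    return dxp


def batchnorm2d(x, gamma, beta, eps: float = 1e-3) -> Tensor:
    """Fused train-mode batch normalisation over (N, H, W) per channel.

    Returns ``(out, (batch_mean, batch_var))``; the detached statistics feed
    the caller's running-average update.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.shape
    m = n * h * w
    mean = x.data.mean(axis=(0, 2, 3))
    centred = x.data - mean.reshape(1, c, 1, 1)
    var = (centred * centred).mean(axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv.reshape(1, c, 1, 1)
    out_data = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * gamma.data.reshape(1, c, 1, 1)
            mean_gh = gh.mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            mean_ghx = (gh * xhat).mean(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            x._accum(inv.reshape(1, c, 1, 1) * (gh - mean_gh - xhat * mean_ghx))

    out = _node(out_data, (x, gamma, beta), backward)
    return out, (mean, var)


def affine_channels(x, scale: np.ndarray, shift: np.ndarray) -> Tensor:
    """Per-channel y = x*scale + shift with constant coefficients (eval BN)."""
    x = as_tensor(x)
    c = x.shape[1]
    out_data = x.data * scale.reshape(1, c, 1, 1) + shift.reshape(1, c, 1, 1)

    def backward(g):
        x._accum(g * scale.reshape(1, c, 1, 1))

    return _node(out_data, (x,), backward)


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution, NCHW layout; ``groups`` must be 1 or the full channel
    count (depthwise)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    co, cpg, kh, kw = weight.shape
    if groups not in (1, c):
        raise ValueError(f"unsupported groups={groups} (need 1 or {c})")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    xp = _pad_hw(x.data, padding)
    cols = _im2col(xp, kh, kw, oh, ow, stride)
    mult = co // groups if groups > 1 else 1  # channel multiplier

    if groups == 1:
        cols2 = cols.reshape(n, c * kh * kw, oh * ow)
        wmat = weight.data.reshape(co, c * kh * kw)
        out_data = (wmat[None] @ cols2).reshape(n, co, oh, ow)
    else:  # depthwise (each input channel yields `mult` output maps)
        wgrp = weight.data.reshape(c, mult, kh, kw)
        out_data = np.einsum("ncijhw,ctij->ncthw", cols, wgrp,
                             optimize=True).astype(_F32).reshape(n, co, oh, ow)

    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data.reshape(1, co, 1, 1)
        parents.append(bias)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=_F32)
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            gmat = g.reshape(n, co, oh * ow)
            if weight.requires_grad:
                cols2b = cols.reshape(n, c * kh * kw, oh * ow)
                dw = np.matmul(gmat, cols2b.transpose(0, 2, 1)).sum(axis=0)
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                wmat = weight.data.reshape(co, c * kh * kw)
                dcols = (wmat.T[None] @ gmat).reshape(n, c, kh, kw, oh, ow)
                dxp = _col2im(dcols, xp.shape, oh, ow, stride)
                x._accum(dxp[:, :, padding:padding + h, padding:padding + w]
                         if padding else dxp)
        else:
            ggrp = g.reshape(n, c, mult, oh, ow)
            if weight.requires_grad:
                dw = np.einsum("ncijhw,ncthw->ctij", cols, ggrp, optimize=True)
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                wgrp = weight.data.reshape(c, mult, kh, kw)
                dcols = np.einsum("ctij,ncthw->ncijhw", wgrp, ggrp,
                                  optimize=True).astype(_F32)
                dxp = _col2im(dcols, xp.shape, oh, ow, stride)
                x._accum(dxp[:, :, padding:padding + h, padding:padding + w]
                         if padding else dxp)

    return _node(out_data, tuple(parents), backward)


def maxpool2d(x, kernel: int, stride: int = 1) -> Tensor:
    """Max pooling with ``kernel//2`` zero-free padding (-inf outside)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    p = kernel // 2
    oh = (h + 2 * p - kernel) // stride + 1
    ow = (w + 2 * p - kernel) // stride + 1
    xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=_F32)
    xp[:, :, p:p + h, p:p + w] = x.data
    best = np.full((n, c, oh, ow), -np.inf, dtype=_F32)
    arg = np.zeros((n, c, oh, ow), dtype=np.int16)
    idx = 0
    for i in range(kernel):
        for j in range(kernel):
            v = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            m = v > best
            best[m] = v[m]
            arg[m] = idx
            idx += 1

    def backward(g):
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
        idx2 = 0
        for i in range(kernel):
            for j in range(kernel):
                m = arg == idx2
                dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g * m
                idx2 += 1
        x._accum(dxp[:, :, p:p + h, p:p + w])

    return _node(best, (x,), backward)


def upsample_nearest2(x) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """NCHW -> NC channel descriptor (spatial mean)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).astype(_F32))

    return _node(out_data, (x,), backward)


def channel_conv1d(v, weight) -> Tensor:
    """1-D convolution across the channel axis of an (N, C) descriptor.

    A single kernel of odd width is shared by every channel (no bias), i.e.
    cross-channel interaction without dimensionality reduction.
    """
    v, weight = as_tensor(v), as_tensor(weight)
    k = weight.shape[0]
    p = k // 2
    n, c = v.shape
    vp = np.pad(v.data, ((0, 0), (p, p)))
    out_data = np.zeros((n, c), dtype=_F32)
    for t in range(k):
        out_data += weight.data[t] * vp[:, t:t + c]

    def backward(g):
        if weight.requires_grad:
            dw = np.array([(g * vp[:, t:t + c]).sum() for t in range(k)], dtype=_F32)
            weight._accum(dw)
        if v.requires_grad:
            gp = np.pad(g, ((0, 0), (p, p)))
            dv = np.zeros((n, c), dtype=_F32)
            for t in range(k):
                dv += weight.data[t] * gp[:, k - 1 - t:k - 1 - t + c]
            v._accum(dv)

    return _node(out_data, (v, weight), backward)


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise binary cross-entropy on raw logits (stable form)."""
    logits = as_tensor(logits)
    t = targets.data if isinstance(targets, Tensor) else _f32(targets)
    x = logits.data
    out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        logits._accum(g * (expit(x) - t))

    return _node(out_data, (logits,), backward)
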