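"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the cGAN translators need: broadcasting
elementwise arithmetic, matmul (batched), reductions, shape ops, channel
concatenation, 2-D convolution / transposed convolution, nearest-neighbor
upsampling and the usual nonlinearities. Gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]
_DTYPE = [np.float32]  # float32 keeps CPU training fast; tests that
                       # finite-difference gradients switch to float64


def default_dtype():
    return _DTYPE[-1]


@contextlib.contextmanager
def dtype(dt):
    _DTYPE.append(np.dtype(dt).type)
    try:
        yield
    finally:
        _DTYPE.pop()


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(),
                 _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE[-1])
        self.grad = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    nd = len(shape)
    while g.ndim > nd:
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    need = grad_enabled() and any(
        p.requires_grad or p._prev for p in parents)
    if not need:
        return Tensor(data)
    return Tensor(data, requires_grad=False, _prev=tuple(parents),
                  _backward=backward)


# -- elementwise ------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / b.data ** 2, b.shape))

    return _make(out_data, (a, b), backward)


def powc(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        _accum(a, g * np.where(mask, 1.0, slope))

    return _make(out_data, (a,), backward)


def relu(a):
    return leaky_relu(a, 0.0)


def gelu(a):
    """tanh-approximation GELU (composite; differentiated by the graph)."""
    a = as_tensor(a)
    c = float(np.sqrt(2.0 / np.pi))
    inner = mul(add(a, mul(powc(a, 3.0), 0.044715)), c)
    return mul(mul(a, add(tanh(inner), 1.0)), 0.5)


def clip(a, lo: float, hi: float):
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def absval(a):
    a = as_tensor(a)
    sign = np.sign(a.data)
    out_data = np.abs(a.data)

    def backward(g):
        _accum(a, g * sign)

    return _make(out_data, (a,), backward)


# -- reductions and shape ops ----------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            for d in sorted(a_norm_axes(ax, a.ndim)):
                gg = np.expand_dims(gg, d)
        _accum(a, np.broadcast_to(gg, a.shape).copy())

    return _make(out_data, (a,), backward)


def a_norm_axes(axes, ndim):
    return tuple(d % ndim for d in axes)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[d] for d in a_norm_axes(
            axis if isinstance(axis, tuple) else (axis,), a.ndim)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.shape))
        _accum(b, _unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def softmax(a, axis: int = -1):
    a = as_tensor(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, tsum(e, axis=axis, keepdims=True))


def dropout(a, p: float, rng: np.random.Generator, train: bool):
    if not train or p <= 0.0:
        return as_tensor(a)
    a = as_tensor(a)
    mask = (rng.random(a.shape) >= p) / (1.0 - p)
    return mul(a, Tensor(mask))


# -- convolution primitives -------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    return win[:, :, :ho, :wo]


def conv2d(x, w, b, stride: int = 1, pad: int = 0):
    """x: (N,C,H,W), w: (F,C,kh,kw), b: (F,) -> (N,F,Ho,Wo)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _im2col(xp, kh, kw, stride, ho, wo)        # (N,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    wmat = w.data.reshape(f, c * kh * kw)
    y = (cols @ wmat.T).reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    y = y + b.data[None, :, None, None]

    def backward(g):
        gy = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, f)
        gw = np.einsum("nif,nik->fk", gy, cols).reshape(w.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols = (gy @ wmat).reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + stride * ho:stride,
                    j:j + stride * wo:stride] += gcols[:, :, :, :, i, j] \
                    .transpose(0, 3, 1, 2)
        gx = gxp[:, :, pad:pad + h, pad:pad + wd] if pad else gxp
        _accum(x, gx)
        _accum(w, gw)
        _accum(b, gb)

    return _make(y, (x, w, b), backward)


def conv_transpose2d(x, w, b, stride: int = 2, pad: int = 1):
    """x: (N,C,H,W), w: (C,F,kh,kw), b: (F,) -> (N,F,(H-1)s+kh-2p, ...)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, c, h, wd = x.shape
    _, f, kh, kw = w.shape
    hp = (h - 1) * stride + kh
    wp = (wd - 1) * stride + kw
    ho, wo = hp - 2 * pad, wp - 2 * pad
    ypad = np.zeros((n, f, hp, wp), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            ypad[:, :, i:i + stride * h:stride, j:j + stride * wd:stride] += \
                np.einsum("nchw,cf->nfhw", x.data, w.data[:, :, i, j])
    y = ypad[:, :, pad:pad + ho, pad:pad + wo] + b.data[None, :, None, None]

    def backward(g):
        gpad = np.zeros((n, f, hp, wp), dtype=g.dtype)
        gpad[:, :, pad:pad + ho, pad:pad + wo] = g
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                sub = gpad[:, :, i:i + stride * h:stride,
                           j:j + stride * wd:stride]
                gx += np.einsum("nfhw,cf->nchw", sub, w.data[:, :, i, j])
                gw[:, :, i, j] = np.einsum("nchw,nfhw->cf", x.data, sub)
        _accum(x, gx)
        _accum(w, gw)
        _accum(b, g.sum(axis=(0, 2, 3)))

    return _make(y, (x, w, b), backward)


def upsample_nearest(x, factor: int = 2):
    x = as_tensor(x)
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    n, c, h, w = x.shape

    def backward(g):
        gg = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        _accum(x, gg)

    return _make(out_data, (x,), backward)
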