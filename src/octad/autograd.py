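"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the distillation networks need: elementwise
arithmetic with broadcasting, reductions, a safe square root, clamping,
leaky-ReLU, 2-D convolution (im2col), average pooling, nearest-neighbour
upsampling and channel concatenation, plus an Adam optimizer.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order. Tensors created
from plain arrays default to ``requires_grad=False`` and act as constants.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "conv2d", "avg_pool", "upsample_nearest", "concat", "leaky_relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to produce an array of `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        def bw(g):
            self._accum(g)
            other._accum(g)
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)
        def bw(g):
            self._accum(g)
            other._accum(-g)
        return self._make(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return self._wrap(other).__sub__(self)

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __mul__(self, other):
        other = self._wrap(other)
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))
        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other).__truediv__(self)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        def bw(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), bw)

    def sqrt(self, eps: float = 1e-12):
        """Square root with a clamped backward pass (finite gradient at 0)."""
        root = np.sqrt(self.data)
        def bw(g):
            self._accum(g * 0.5 / np.maximum(root, eps))
        return self._make(root, (self,), bw)

    def clamp_min(self, lo: float):
        mask = self.data > lo
        def bw(g):
            self._accum(g * mask)
        return self._make(np.maximum(self.data, lo), (self,), bw)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# --------------------------------------------------------------- activations
def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, slope * x.data)
    def bw(g):
        x._accum(g * np.where(pos, 1.0, slope))
    return Tensor._make(out_data, (x,), bw)


# --------------------------------------------------------------- convolution
def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, hp, wp = xp.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout; weight shape (OC, C, KH, KW)."""
    n, c, h, wdt = x.data.shape
    oc, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {cin}")
    if h + 2 * pad < kh or wdt + 2 * pad < kw:
        raise ValueError("input smaller than kernel after padding")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, kh, kw, stride)            # (N, C*KH*KW, L)
    w2 = w.data.reshape(oc, -1)                   # (OC, C*KH*KW)
    out = np.einsum("ok,nkl->nol", w2, cols) + b.data.reshape(1, oc, 1)
    oh = (xp.shape[2] - kh) // stride + 1
    ow = (xp.shape[3] - kw) // stride + 1
    out = out.reshape(n, oc, oh, ow)

    def bw(g):
        g2 = g.reshape(n, oc, -1)
        if w.requires_grad:
            dw = np.einsum("nol,nkl->ok", g2, cols).reshape(w.data.shape)
            w._accum(dw)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("ok,nol->nkl", w2, g2)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor._make(out, (x, w, b), bw)


def avg_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling by an integer factor."""
    if factor == 1:
        return x
    n, c, h, w = x.data.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {factor}")
    oh, ow = h // factor, w // factor
    out = x.data.reshape(n, c, oh, factor, ow, factor).mean(axis=(3, 5))

    def bw(g):
        gg = g[:, :, :, None, :, None] / (factor * factor)
        x._accum(np.broadcast_to(gg, (n, c, oh, factor, ow, factor)).reshape(n, c, h, w))

    return Tensor._make(out, (x,), bw)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def bw(g):
        x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(out, tuple(tensors), bw)


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: list, lr: float = 5e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
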