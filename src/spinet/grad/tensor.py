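"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the primitives the segmentation network needs: broadcasted
arithmetic, reductions, shape ops, 2-D convolution, depthwise 1-D
convolution, max pooling, and a separable linear map used for bilinear
resizing and adaptive average pooling.  Gradients are accumulated by a
topological-order sweep from the output scalar.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concatenate", "conv2d", "dwconv1d", "maxpool2d_3x3s2", "lin2d"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
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
                    if id(p) not in seen and p._parents:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                    seen.add(id(p))
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))

    def __rsub__(self, other):
        return _ensure(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (_unbroadcast(g * b.data, a.shape),
                                        _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (_unbroadcast(g / b.data, a.shape),
                                        _unbroadcast(-g * a.data / (b.data * b.data), b.shape)))

    def __rtruediv__(self, other):
        return _ensure(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        out = _node(np.power(self.data, p), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g * p * np.power(a.data, p - 1.0))
            out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        if out._parents:
            def bw(g, a=self, y=y):
                a._accumulate(g * y)
            out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = bw
        return out

    def relu(self):
        m = self.data > 0
        out = _node(self.data * m, (self,))
        if out._parents:
            def bw(g, a=self, m=m):
                a._accumulate(g * m)
            out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        if out._parents:
            def bw(g, a=self, y=y):
                a._accumulate(g * y * (1.0 - y))
            out._backward = bw
        return out

    # -- reductions and shape ops -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is None:
                    a._accumulate(np.broadcast_to(g, shape).copy())
                    return
                if not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    ax = tuple(i % len(shape) for i in ax)
                    g = np.expand_dims(g, ax)
                a._accumulate(np.broadcast_to(g, shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _node(self.data.transpose(axes), (self,))
        if out._parents:
            inv = tuple(np.argsort(axes))

            def bw(g, a=self, inv=inv):
                a._accumulate(g.transpose(inv))
            out._backward = bw
        return out


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents
                 if isinstance(p, Tensor) and (p.requires_grad or p._parents))
    if live:
        out._parents = live
        out.requires_grad = True
    return out


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out._parents:
        def bw(g, a=a, b=b):
            ga, gb = grads(g, a, b)
            if a.requires_grad or a._parents:
                a._accumulate(ga)
            if b.requires_grad or b._parents:
                b._accumulate(gb)
        out._backward = bw
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g, tensors=tensors, offsets=offsets, axis=axis):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._parents:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(idx)])
        out._backward = bw
    return out


# -- convolution and pooling primitives -----------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Cross-correlation of a (B,C,H,W) map with (O,C,kh,kw) filters."""
    x, w = _ensure(x), _ensure(w)
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, filters expect {Ci}")
    s, p, d = stride, padding, dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    span_h, span_w = (kh - 1) * d + 1, (kw - 1) * d + 1
    win = sliding_window_view(xp, (span_h, span_w), axis=(2, 3))
    win = win[:, :, ::s, ::s, ::d, ::d]          # B,C,Ho,Wo,kh,kw
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    y = cols @ wmat.T
    if b is not None:
        y += b.data
    y = y.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)
    if out._parents:
        def bw(g, x=x, w=w, b=b, cols=cols, wmat=wmat,
               dims=(B, C, H, W, O, kh, kw, Ho, Wo, s, p, d)):
            B, C, H, W, O, kh, kw, Ho, Wo, s, p, d = dims
            gym = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
            if w.requires_grad or w._parents:
                w._accumulate((gym.T @ cols).reshape(w.data.shape))
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gcols = (gym @ wmat).reshape(B, Ho, Wo, C, kh, kw)
                gcols = gcols.transpose(0, 3, 1, 2, 4, 5)   # B,C,Ho,Wo,kh,kw
                dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i * d: i * d + Ho * s: s,
                            j * d: j * d + Wo * s: s] += gcols[:, :, :, :, i, j]
                x._accumulate(dxp[:, :, p: p + H, p: p + W] if p else dxp)
        out._backward = bw
    return out


def dwconv1d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Depthwise 1-D convolution of (B,C,L) with per-channel kernels (C,k), same padding."""
    x, w = _ensure(x), _ensure(w)
    B, C, L = x.data.shape
    Cw, k = w.data.shape
    if Cw != C:
        raise ValueError(f"dwconv1d channel mismatch: input has {C}, kernels expect {Cw}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=2)     # B,C,L,k
    y = np.einsum("bclk,ck->bcl", win, w.data, optimize=True)
    if b is not None:
        y += b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)
    if out._parents:
        def bw(g, x=x, w=w, b=b, win=win, dims=(B, C, L, k, p)):
            B, C, L, k, p = dims
            if w.requires_grad or w._parents:
                w._accumulate(np.einsum("bclk,bcl->ck", win, g, optimize=True))
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad or x._parents:
                dxp = np.zeros((B, C, L + 2 * p), dtype=x.data.dtype)
                for t in range(k):
                    dxp[:, :, t: t + L] += g * w.data[None, :, t, None]
                x._accumulate(dxp[:, :, p: p + L])
        out._backward = bw
    return out


def maxpool2d_3x3s2(x: Tensor) -> Tensor:
    """3x3 max pooling, stride 2, padding 1 (the classic ResNet stem pool)."""
    x = _ensure(x)
    B, C, H, W = x.data.shape
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=neg)
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::2, ::2]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, 9)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = _node(y, (x,))
    if out._parents:
        def bw(g, x=x, arg=arg, dims=(B, C, H, W, Ho, Wo)):
            B, C, H, W, Ho, Wo = dims
            dxp = np.zeros((B, C, H + 2, W + 2), dtype=x.data.dtype)
            for idx in range(9):
                m = arg == idx
                if not m.any():
                    continue
                i, j = divmod(idx, 3)
                dxp[:, :, i: i + 2 * Ho: 2, j: j + 2 * Wo: 2] += g * m
            x._accumulate(dxp[:, :, 1: 1 + H, 1: 1 + W])
        out._backward = bw
    return out


def lin2d(x: Tensor, ah: np.ndarray, aw: np.ndarray) -> Tensor:
    """Separable linear map on the spatial axes: out[b,c,i,j] = ah[i,h] x[b,c,h,w] aw[j,w].

    With interpolation matrices this is bilinear resizing; with averaging
    matrices it is adaptive average pooling.  The matrices are constants.
    """
    x = _ensure(x)
    y = np.einsum("ih,bchw,jw->bcij", ah, x.data, aw, optimize=True)
    out = _node(y, (x,))
    if out._parents:
        def bw(g, x=x, ah=ah, aw=aw):
            x._accumulate(np.einsum("ih,bcij,jw->bchw", ah, g, aw, optimize=True))
        out._backward = bw
    return out
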