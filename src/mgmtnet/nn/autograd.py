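"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the primitives the segmentation and
classification networks need: broadcasted arithmetic, matmul, 2D
convolution (via im2col), max pooling, nearest-neighbour upsampling,
reductions and elementwise nonlinearities.  Gradients are accumulated on a
dynamically recorded tape and checked against central differences in the
test suite.

Arrays keep the dtype they are given; float32 is used for training,
float64 for gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2d",
    "relu",
    "leaky_relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "log_softmax",
]


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
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------
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

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # ------------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        return _binop(self, other, np.add,
                      lambda g, a, b: _unbroadcast(g, a.shape),
                      lambda g, a, b: _unbroadcast(g, b.shape))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract,
                      lambda g, a, b: _unbroadcast(g, a.shape),
                      lambda g, a, b: _unbroadcast(-g, b.shape))

    def __rsub__(self, other):
        return as_tensor(other, like=self) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply,
                      lambda g, a, b: _unbroadcast(g * b, a.shape),
                      lambda g, a, b: _unbroadcast(g * a, b.shape))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, other, np.divide,
                      lambda g, a, b: _unbroadcast(g / b, a.shape),
                      lambda g, a, b: _unbroadcast(-g * a / (b * b), b.shape))

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** n, requires_grad=self.requires_grad)
        if out.requires_grad:
            a = self.data

            def bwd(g):
                self._accumulate(g * n * a ** (n - 1))

            out._backward, out._parents = bwd, (self,)
        return out

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad)
        if out.requires_grad:
            a, b = self, other

            def bwd(g):
                if a.requires_grad or a._parents:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad or b._parents:
                    b._accumulate(a.data.T @ g)

            out._backward, out._parents = bwd, (a, b)
        return out

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape),
                     requires_grad=self.requires_grad)
        if out.requires_grad:
            def bwd(g):
                self._accumulate(g.reshape(src))

            out._backward, out._parents = bwd, (self,)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes),
                     requires_grad=self.requires_grad)
        if out.requires_grad:
            def bwd(g):
                self._accumulate(g.transpose(inv))

            out._backward, out._parents = bwd, (self,)
        return out

    # ------------------------------------------------------------------
    # reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad)
        if out.requires_grad:
            shape = self.data.shape

            def bwd(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape).copy())
                    return
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, shape).copy())

            out._backward, out._parents = bwd, (self,)
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _binop(a: Tensor, b, fwd, bwd_a, bwd_b) -> Tensor:
    b = as_tensor(b, like=a)
    out = Tensor(fwd(a.data, b.data),
                 requires_grad=a.requires_grad or b.requires_grad)
    if out.requires_grad:
        ad, bd = a.data, b.data

        def bwd(g):
            if a.requires_grad or a._parents:
                a._accumulate(bwd_a(g, ad, bd))
            if b.requires_grad or b._parents:
                b._accumulate(bwd_b(g, ad, bd))

        out._backward, out._parents = bwd, (a, b)
    return out


def _elementwise(x: Tensor, fwd, dfun) -> Tensor:
    out = Tensor(fwd(x.data), requires_grad=x.requires_grad)
    if out.requires_grad:
        y = out.data

        def bwd(g):
            x._accumulate(g * dfun(x.data, y))

        out._backward, out._parents = bwd, (x,)
    return out


def relu(x: Tensor) -> Tensor:
    return _elementwise(x, lambda a: np.maximum(a, 0.0),
                        lambda a, y: (a > 0).astype(a.dtype))


def leaky_relu(x: Tensor, slope: float = 0.3) -> Tensor:
    return _elementwise(x, lambda a: np.where(a > 0, a, slope * a),
                        lambda a, y: np.where(a > 0, 1.0, slope).astype(a.dtype))


def sigmoid(x: Tensor) -> Tensor:
    def fwd(a):
        out = np.empty_like(a)
        pos = a >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
        ea = np.exp(a[~pos])
        out[~pos] = ea / (1.0 + ea)
        return out

    return _elementwise(x, fwd, lambda a, y: y * (1.0 - y))


def exp(x: Tensor) -> Tensor:
    return _elementwise(x, np.exp, lambda a, y: y)


def log(x: Tensor) -> Tensor:
    return _elementwise(x, np.log, lambda a, y: 1.0 / a)


def sqrt(x: Tensor) -> Tensor:
    return _elementwise(x, np.sqrt, lambda a, y: 0.5 / y)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed through inside the interval only."""
    return _elementwise(x, lambda a: np.clip(a, lo, hi),
                        lambda a, y: ((a >= lo) & (a <= hi)).astype(a.dtype))


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    s = x.data - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    out = Tensor(s - lse, requires_grad=x.requires_grad)
    if out.requires_grad:
        p = np.exp(out.data)

        def bwd(g):
            x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

        out._backward, out._parents = bwd, (x,)
    return out


# ----------------------------------------------------------------------
# spatial ops (NCHW layout)

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation, NCHW input, FCHW weights."""
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out_arr = np.einsum("ncijuv,fcuv->nfij", win, w.data, optimize=True)
    if b is not None:
        out_arr = out_arr + b.data[None, :, None, None]
    out = Tensor(out_arr)
    out.requires_grad = (x.requires_grad or w.requires_grad
                         or (b is not None and b.requires_grad))
    if out.requires_grad:
        def bwd(g):
            if w.requires_grad or w._parents:
                w._accumulate(np.einsum("nfij,ncijuv->fcuv", g, win,
                                        optimize=True))
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                dxp = np.zeros_like(xp)
                for u in range(kh):
                    for v in range(kw):
                        dxp[:, :, u:u + stride * Ho:stride,
                            v:v + stride * Wo:stride] += np.einsum(
                                "nfij,fc->ncij", g, w.data[:, :, u, v],
                                optimize=True)
                if padding:
                    dxp = dxp[:, :, padding:padding + H, padding:padding + W]
                x._accumulate(dxp)

        out._backward = bwd
        out._parents = (x, w) if b is None else (x, w, b)
    return out


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k max pooling; trailing rows/cols beyond a
    multiple of ``k`` are dropped (floor policy)."""
    N, C, H, W = x.data.shape
    Hk, Wk = H // k, W // k
    if Hk == 0 or Wk == 0:
        raise ValueError(f"pool size {k} larger than input {H}x{W}")
    xc = x.data[:, :, :Hk * k, :Wk * k]
    r = xc.reshape(N, C, Hk, k, Wk, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, Hk, Wk, k * k)
    idx = r.argmax(axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0],
                 requires_grad=x.requires_grad)
    if out.requires_grad:
        def bwd(g):
            dr = np.zeros((N, C, Hk, Wk, k * k), dtype=g.dtype)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dxc = dr.reshape(N, C, Hk, Wk, k, k).transpose(
                0, 1, 2, 4, 3, 5).reshape(N, C, Hk * k, Wk * k)
            dx = np.zeros_like(x.data)
            dx[:, :, :Hk * k, :Wk * k] = dxc
            x._accumulate(dx)

        out._backward, out._parents = bwd, (x,)
    return out


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3),
                 requires_grad=x.requires_grad)
    if out.requires_grad:
        def bwd(g):
            x._accumulate(g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5)))

        out._backward, out._parents = bwd, (x,)
    return out
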