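"""A minimal reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the translation network needs: broadcasted
arithmetic, matmul, pointwise nonlinearities, reductions, reshaping, 2D
convolution (via im2col), nearest-neighbour upsampling and spatial-location
gathering. Single-image tensors (no batch axis); the training batch size is
one.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

__all__ = ["Tensor", "conv2d", "upsample_nearest2x", "logsumexp", "set_default_dtype"]

# float32 keeps the conv workloads fast; tests switch to float64 for
# finite-difference gradient checks.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def build(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        import sys
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 100000))
        try:
            build(self)
        finally:
            sys.setrecursionlimit(old_limit)

        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * ((self.data >= lo) & (self.data <= hi)))

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # --------------------------------------------------------------- reshape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = bw
        return out

    def take_columns(self, indices: np.ndarray):
        """Select columns of a 2D tensor: (C, N) -> (C, S)."""
        indices = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[:, indices], parents=(self,))

        def bw(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, (slice(None), indices), g)
                self._accumulate(gx)

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


# ---------------------------------------------------------------------- conv
def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[1] - k) // stride + 1
    wo = (x.shape[2] - k) // stride + 1
    cols = np.empty((c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = x[:, i : i + ho * stride : stride, j : j + wo * stride : stride]
    return cols.reshape(c * k * k, ho * wo), ho, wo


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    gx = np.zeros((c, hp, wp), dtype=gcols.dtype)
    g = gcols.reshape(c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            gx[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += g[:, i, j]
    if pad:
        gx = gx[:, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation) on a (C,H,W) tensor."""
    co, ci, k, _ = weight.shape
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    w2 = weight.data.reshape(co, ci * k * k)
    out_data = (w2 @ cols + bias.data[:, None]).reshape(co, ho, wo)
    out = Tensor(out_data, parents=(x, weight, bias))

    def bw(g):
        g2 = g.reshape(co, ho * wo)
        if weight.requires_grad:
            weight._accumulate((g2 @ cols.T).reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=1))
        if x.requires_grad:
            gcols = w2.T @ g2
            x._accumulate(_col2im(gcols, x.data.shape, k, stride, pad))

    out._backward = bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    """(C,H,W) -> (C,2H,2W) nearest-neighbour upsampling."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2)
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            c, h2, w2 = g.shape
            x._accumulate(g.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4)))

    out._backward = bw
    return out


def logsumexp(t: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    """Numerically stable log-sum-exp along an axis (max treated as constant)."""
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        lse = lse.reshape(tuple(n for i, n in enumerate(lse.shape) if i != axis))
    return lse
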