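"""Reverse-mode automatic differentiation over numpy arrays.

A compact tape-based engine sized for the 1-D convolutional models in this
package (U-net generator, convolutional discriminator, EEGNet-style
classifier).  Arrays are float64 throughout; gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward`.  All operations needed by the
models live here: broadcasting arithmetic, matmul, reductions, activations,
grouped 1-D convolution, pooling, linear upsampling, concatenation and
dropout.  Gradient correctness is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "avg_pool1d", "max_pool1d", "upsample_linear_2x", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
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
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _wrap_like(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._wrap_like(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap_like(other))

    def __rsub__(self, other):
        return self._wrap_like(other) + (-self)

    def __mul__(self, other):
        other = self._wrap_like(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap_like(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap_like(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap_like(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- elementwise
    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out.data)
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bw
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        y = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, y + alpha))
        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), requires_grad=self.requires_grad, parents=(self,))
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bw
        return out


# ------------------------------------------------------------------ functions
def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])
    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, groups: int = 1) -> Tensor:
    """'Same'-padded 1-D convolution (cross-correlation) along the last axis.

    x: (B, Cin, T); w: (Cout, Cin // groups, K); b: (Cout,).  Even kernels use
    asymmetric padding (one sample more on the right).
    """
    B, Cin, T = x.data.shape
    Cout, Cin_g, K = w.data.shape
    if Cin != Cin_g * groups or Cout % groups != 0:
        raise ValueError("channel/group mismatch")
    Cout_g = Cout // groups
    pad_l, pad_r = (K - 1) // 2, K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_l, pad_r)))
    xpg = xp.reshape(B, groups, Cin_g, T + pad_l + pad_r)
    wg = w.data.reshape(groups, Cout_g, Cin_g, K)
    # sum of K shifted batched matmuls: avoids materializing sliding windows
    y = np.zeros((B, groups, Cout_g, T), dtype=x.data.dtype)
    for k in range(K):
        y += np.matmul(wg[:, :, :, k], xpg[:, :, :, k:k + T])
    y = y.reshape(B, Cout, T)
    if b is not None:
        y = y + b.data[None, :, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, requires_grad=any(p.requires_grad for p in parents), parents=parents)

    def bw(g):
        gg = g.reshape(B, groups, Cout_g, T)
        if w.requires_grad:
            dw = np.empty((groups, Cout_g, Cin_g, K), dtype=w.data.dtype)
            for k in range(K):
                dw[:, :, :, k] = np.matmul(
                    gg, xpg[:, :, :, k:k + T].transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(dw.reshape(Cout, Cin_g, K))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            wt = wg.transpose(0, 3, 2, 1)          # (groups, K, Cin_g, Cout_g)
            dxp = np.zeros_like(xpg)
            for k in range(K):
                dxp[:, :, :, k:k + T] += np.matmul(wt[:, k], gg)
            x._accum(dxp.reshape(B, Cin, -1)[:, :, pad_l:pad_l + T])
    out._backward = bw
    return out


def avg_pool1d(x: Tensor, size: int = 2) -> Tensor:
    B, C, T = x.data.shape
    if T % size != 0:
        raise ValueError("time length not divisible by pool size")
    y = x.data.reshape(B, C, T // size, size).mean(axis=3)
    out = Tensor(y, requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(np.repeat(g, size, axis=2) / size)
    out._backward = bw
    return out


def max_pool1d(x: Tensor, size: int = 2) -> Tensor:
    B, C, T = x.data.shape
    if T % size != 0:
        raise ValueError("time length not divisible by pool size")
    xr = x.data.reshape(B, C, T // size, size)
    arg = xr.argmax(axis=3)
    y = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    out = Tensor(y, requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dxr = np.zeros_like(xr)
            np.put_along_axis(dxr, arg[..., None], g[..., None], axis=3)
            x._accum(dxr.reshape(B, C, T))
    out._backward = bw
    return out


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(t: int) -> np.ndarray:
    """Fixed (2T, T) linear-interpolation matrix (edge-clamped midpoints)."""
    if t not in _UPSAMPLE_CACHE:
        U = np.zeros((2 * t, t))
        for i in range(t):
            U[2 * i, i] = 1.0
            j = min(i + 1, t - 1)
            U[2 * i + 1, i] += 0.5
            U[2 * i + 1, j] += 0.5
        _UPSAMPLE_CACHE[t] = U
    return _UPSAMPLE_CACHE[t]


def upsample_linear_2x(x: Tensor) -> Tensor:
    """Doubles the time axis by linear interpolation (B, C, T) -> (B, C, 2T)."""
    B, C, T = x.data.shape
    U = _upsample_matrix(T).astype(x.data.dtype, copy=False)
    out = Tensor(np.einsum("ot,bct->bco", U, x.data), requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(np.einsum("ot,bco->bct", U, g))
    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = ((rng.random(x.data.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    out = Tensor(x.data * mask, requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)
    out._backward = bw
    return out
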