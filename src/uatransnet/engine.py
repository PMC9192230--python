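"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, sized for the CPU-scale
models in this package: dense/convolutional layers, group normalization,
attention (matmul + softmax), bilinear resampling and max pooling.  Every
:class:`Tensor` records its parents and a closure that routes the upstream
gradient to them; :meth:`Tensor.backward` walks the tape in reverse
topological order.

Arrays keep the dtype they were created with, so float32 is used for
training speed and float64 for finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv2d", "group_norm",
           "max_pool2", "upsample_bilinear", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """N-d array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 1000  # ndarray <op> Tensor defers to Tensor's reflected op

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Back-propagate `grad` (default: ones) from this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo, stack, state = [], [self], {}
        while stack:
            t = stack[-1]
            st = state.get(id(t), 0)
            if st == 0:
                state[id(t)] = 1
                for p in t._parents:
                    if state.get(id(p), 0) == 0 and p.requires_grad:
                        stack.append(p)
            else:
                stack.pop()
                if st == 1:
                    state[id(t)] = 2
                    topo.append(t)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars/arrays with this tensor's dtype (no silent upcasts)."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = back
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = back
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        out._backward = back
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def back(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = back
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * 0.5 / y)
        out._backward = back
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = back
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = back
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = back
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (logits shifted by their max)."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def back(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))
    out._backward = back
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patch matrix, stride 1, same padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, c, k, k, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return np.ascontiguousarray(view).reshape(n, c * k * k, h * w)


def _col2im(dcol: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    dcol = dcol.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += dcol[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution, x (N,C,H,W), weight (O,C,k,k)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    o, ci, k, k2 = weight.shape
    if ci != c or k != k2:
        raise ValueError(f"weight shape {weight.shape} incompatible with input {x.shape}")
    pad = k // 2
    col = _im2col(x.data, k, pad)                       # (N, C*k*k, H*W)
    wflat = weight.data.reshape(o, c * k * k)
    y = np.matmul(wflat, col)                           # (N, O, H*W)
    if bias is not None:
        y = y + bias.data.reshape(1, o, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y.reshape(n, o, h, w), _parents=parents)

    def back(g):
        gf = g.reshape(n, o, h * w)
        if weight.requires_grad:
            dw = np.einsum("nop,nkp->ok", gf, col)
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if x.requires_grad:
            dcol = np.matmul(wflat.T, gf)               # (N, C*k*k, H*W)
            x._accum(_col2im(dcol, x.shape, k, pad))
    out._backward = back
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xf = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xf.argmax(axis=-1)
    y = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _parents=(x,))

    def back(g):
        if x.requires_grad:
            gf = np.zeros_like(xf)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gx.reshape(n, c, h, w))
    out._backward = back
    return out


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """1-D bilinear interpolation matrix with aligned corners."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_out == 1 or n_in == 1:
        m[:, 0] = 1.0
        return m
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple) -> Tensor:
    """Bilinear resampling of (N,C,H,W) to spatial `size`, aligned corners."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    h2, w2 = size
    a = _interp_matrix(h2, h, x.data.dtype)
    b = _interp_matrix(w2, w, x.data.dtype)
    y = np.matmul(np.matmul(a, x.data), b.T)
    out = Tensor(y, _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(a.T, g), b))
    out._backward = back
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """GroupNorm over (N,C,H,W); built from primitives so grads come free."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by {groups} groups")
    xg = x.reshape((n, groups, (c // groups) * h * w))
    mu = xg.mean(axis=2, keepdims=True)
    xc = xg - mu
    var = (xc * xc).mean(axis=2, keepdims=True)
    xn = xc / (var + eps).sqrt()
    out = xn.reshape((n, c, h, w))
    return out * gamma.reshape((1, c, 1, 1)) + beta.reshape((1, c, 1, 1))
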