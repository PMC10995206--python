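"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the localization network and the template
GAN need: stride-1 "same" convolutions (one BLAS matmul against all k*k
taps plus contiguous shifted adds — no strided im2col gathers), 2x2 average
pooling, nearest-neighbour upsampling, dense layers, the usual pointwise
nonlinearities, broadcast arithmetic, reductions and a stable log-sum-exp.
Network weights and activations are float32; float64 inputs stay float64,
which lets the loss functions be verified against scalar references at
tight tolerances.

The engine is define-by-run: every operation on :class:`Tensor` records a
backward closure; :meth:`Tensor.backward` replays them in reverse
topological order.  A global ``no_grad`` context disables recording for
cheap inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad



def _wrap(other, like: "Tensor") -> "Tensor":
    """Wrap a non-Tensor operand; python/0-d scalars follow the Tensor's
    dtype (mirroring numpy's scalar casting) instead of upcasting."""
    if isinstance(other, Tensor):
        return other
    arr = np.asarray(other)
    if arr.ndim == 0:
        arr = arr.astype(like.data.dtype)
    return Tensor(arr)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float64:
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS, graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            # leaves with recorded backward do not occur; intermediate
            # grads are discarded once consumed

    # -- arithmetic ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = _wrap(other, self)
        out_data = self.data + other.data
        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = _wrap(other, self)
        out_data = self.data - other.data
        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape))
        return Tensor._make(out_data, (self, other), bw)

    def __rsub__(self, other):
        return _wrap(other, self) - self

    def __mul__(self, other):
        other = _wrap(other, self)
        out_data = self.data * other.data
        def bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other, self)
        out_data = self.data / other.data
        def bw(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))
        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _wrap(other, self) / self

    def __pow__(self, k: float):
        out_data = self.data ** k
        def bw(g):
            return (g * k * self.data ** (k - 1),)
        return Tensor._make(out_data, (self,), bw)

    # -- pointwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data ** 2),))

    def softplus(self):
        x = self.data
        out_data = np.where(x > 20, x, np.log1p(np.exp(np.minimum(x, 20)))).astype(x.dtype)
        sig = 1.0 / (1.0 + np.exp(-x))
        return Tensor._make(out_data, (self,), lambda g: (g * sig,))

    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0)) - 1)
        out_data = np.where(x > 0, x, neg).astype(x.dtype)
        dneg = neg + alpha  # alpha * exp(x) for x <= 0
        def bw(g):
            return (g * np.where(x > 0, 1.0, dneg).astype(x.dtype),)
        return Tensor._make(out_data, (self,), bw)

    # -- reductions / reshaping ---------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape
        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(np.ascontiguousarray(self.data.transpose(axes)), (self,),
                            lambda g: (np.ascontiguousarray(g.transpose(inv)),))

    def logsumexp(self, axis: int):
        m = self.data.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.squeeze(m + np.log(s), axis=axis)
        soft = e / s
        def bw(g):
            return (np.expand_dims(g, axis) * soft,)
        return Tensor._make(out_data, (self,), bw)

    def matmul(self, other: "Tensor"):
        out_data = self.data @ other.data
        def bw(g):
            return (g @ other.data.T, self.data.T @ g)
        return Tensor._make(out_data, (self, other), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape
        def bw(g):
            full = np.zeros(shape, dtype=g.dtype)
            full[idx] = g
            return (full,)
        return Tensor._make(out_data, (self,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._make(out_data, tuple(tensors), bw)


# ---------------------------------------------------------------------
# Spatial ops on channels-last (N, H, W, C) tensors
#
# Convolutions are computed as one GEMM against all k*k taps at once
# followed by k*k contiguous shifted adds; this keeps BLAS fed without
# strided im2col gathers (the bottleneck on a single core).
# ---------------------------------------------------------------------

def _shift_add(dst: np.ndarray, src: np.ndarray, u: int, v: int) -> None:
    """dst[:, i, j] += src[:, i+u, j+v] with zero outside; in place."""
    h, w = dst.shape[1], dst.shape[2]
    di0, di1 = max(0, -u), min(h, h - u)
    si0, si1 = max(0, u), min(h, h + u)
    dj0, dj1 = max(0, -v), min(w, w - v)
    sj0, sj1 = max(0, v), min(w, w + v)
    if di0 < di1 and dj0 < dj1:
        dst[:, di0:di1, dj0:dj1] += src[:, si0:si1, sj0:sj1]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero-padded 'same' 2D convolution (cross-correlation).

    x: (N, H, W, C); w: (k, k, C, Co) with odd k; b: (Co,)
    """
    n, h, wd, c = x.data.shape
    k = w.data.shape[0]
    co = w.data.shape[3]
    p = k // 2
    x2 = x.data.reshape(n * h * wd, c)
    taps = w.data.reshape(k * k, c, co).transpose(1, 0, 2).reshape(c, k * k * co)
    res = (x2 @ taps).reshape(n, h, wd, k, k, co)
    out = np.empty((n, h, wd, co), dtype=res.dtype)
    out[:] = b.data
    for u in range(k):
        for v in range(k):
            _shift_add(out, res[:, :, :, u, v, :], u - p, v - p)

    def bw(g):
        gb = g.reshape(-1, co).sum(axis=0)
        # scatter g back to tap positions: dres[:, i+u, j+v] += g[:, i, j]
        dres = np.zeros((n, h, wd, k, k, co), dtype=g.dtype)
        for u in range(k):
            for v in range(k):
                _shift_add(dres[:, :, :, u, v, :], g, p - u, p - v)
        dres2 = dres.reshape(n * h * wd, k * k * co)
        gw = (x2.T @ dres2).reshape(c, k * k, co).transpose(1, 0, 2).reshape(k, k, c, co)
        gx = (dres2 @ taps.T).reshape(n, h, wd, c)
        return (gx, gw, gb)

    return Tensor._make(out, (x, w, b), bw)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling (H, W must be even)."""
    n, h, w, c = x.data.shape
    out_data = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    def bw(g):
        return (np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25,)
    return Tensor._make(out_data, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    n, h, w, c = x.data.shape
    def bw(g):
        return (g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)),)
    return Tensor._make(out_data, (x,), bw)


def pad2d_to(x: Tensor, mult: int) -> Tensor:
    """Zero-pad (N, H, W, C) bottom/right so H and W are multiples of ``mult``."""
    _, h, w, _ = x.data.shape
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, ph), (0, pw), (0, 0)))
    def bw(g):
        return (g[:, :h, :w, :],)
    return Tensor._make(out_data, (x,), bw)


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Center-crop spatial dims to (h, w)."""
    _, hh, ww, _ = x.data.shape
    r0 = (hh - h) // 2
    c0 = (ww - w) // 2
    return x[:, r0:r0 + h, c0:c0 + w, :]


# ---------------------------------------------------------------------
# Layers and optimizer
# ---------------------------------------------------------------------

class Conv2d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (k, k, c_in, c_out)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.w = Tensor(rng.normal(0.0, std, (d_in, d_out)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b

    @property
    def params(self):
        return [self.w, self.b]


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_params(*layers) -> list[Tensor]:
    out: list[Tensor] = []
    for layer in layers:
        out.extend(layer.params)
    return out


def state_dict(params: Sequence[Tensor]) -> dict:
    return {str(i): p.data for i, p in enumerate(params)}


def load_state(params: Sequence[Tensor], state: dict) -> None:
    for i, p in enumerate(params):
        arr = np.asarray(state[str(i)], dtype=p.data.dtype)
        if arr.shape != p.data.shape:
            raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
        p.data = arr.copy()
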