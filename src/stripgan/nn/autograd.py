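"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's models need: broadcasted
arithmetic, matmul, 2-D convolution (zero padding, arbitrary stride),
average pooling, nearest-neighbour upsampling, channel concatenation,
elementwise nonlinearities and axis reductions.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via topological sort.

The engine is single-threaded numpy and therefore bit-deterministic for a
fixed seed, which the training contracts rely on.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / data generation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
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

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(out):
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(out):
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(out):
            self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(out):
            self._accum(_unbroadcast(out.grad / other.data, self.shape))
            other._accum(
                _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(out):
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(out):
            self._accum(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)

        def backward(out):
            self._accum(out.grad * slope)

        return Tensor._make(self.data * slope, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            self._accum(out.grad * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)

        def backward(out):
            self._accum(out.grad * (1.0 - y**2))

        return Tensor._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(out):
            self._accum(out.grad * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(out):
            self._accum(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in
             ((axis,) if isinstance(axis, int) else tuple(axis))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape):
        old = self.shape

        def backward(out):
            self._accum(out.grad.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        if self.ndim != 2:
            raise ValueError("T is defined for 2-D tensors only")

        def backward(out):
            self._accum(out.grad.T)

        return Tensor._make(self.data.T, (self,), backward)

    def select(self, i: int):
        """Index the leading axis (graph-preserving)."""

        def backward(out):
            g = np.zeros_like(self.data)
            g[i] = out.grad
            self._accum(g)

        return Tensor._make(self.data[i], (self,), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


# -- structured ops ------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation with zero padding.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,).
    """
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = np.einsum("nchwij,ocij->nohw", view, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    ho, wo = out_data.shape[2], out_data.shape[3]

    def backward(out):
        g = out.grad
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nohw->ocij", view, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, i, j],
                            optimize=True)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("spatial dims must be divisible by pool size")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(out):
        g = np.repeat(np.repeat(out.grad, k, axis=2), k, axis=3) / (k * k)
        x._accum(g)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    n, c, h, w = x.shape

    def backward(out):
        g = out.grad.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(g)

    return Tensor._make(out_data, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]

    def backward(out):
        a._accum(out.grad[:, :ca])
        b._accum(out.grad[:, ca:])

    return Tensor._make(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


def stack0(tensors: list[Tensor]) -> Tensor:
    """Stack tensors along a new leading axis (graph-preserving)."""
    ts = list(tensors)

    def backward(out):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(out.grad[i])

    return Tensor._make(np.stack([t.data for t in ts]), tuple(ts), backward)


def softmax(x: Tensor, axis) -> Tensor:
    """Numerically stable softmax over ``axis`` (int or tuple of ints)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    n, k = logits.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    logsumexp = z.exp().sum(axis=1, keepdims=True).log()
    logprob = z - logsumexp
    return -(logprob * Tensor(onehot)).sum() * (1.0 / n)
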