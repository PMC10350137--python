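"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the sleep-staging network: broadcasting
elementwise arithmetic, matmul, reductions, reshaping/slicing, the usual
nonlinearities, a strided 1-D convolution with an efficient custom
vector-Jacobian product, and fused softmax / sigmoid cross-entropy losses.
Gradients are accumulated by a topological backward sweep from the loss.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    old, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = old


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (long sequences)
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path preserves dtype
            out = Tensor._make(self.data + other, (self,), None)
            out._backward = lambda g: self._accum(g)
            return out
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor._make(self.data * other, (self,), None)
            out._backward = lambda g: self._accum(g * other)
            return out
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * (1.0 - y**2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    # -- shape / reduction ---------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors: list, axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)

    def bw(g):
        for t, gi in zip(tensors, np.moveaxis(g, axis, 0)):
            if t.requires_grad:
                t._accum(gi)

    out._backward = bw
    return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor._make(data, tuple(tensors), None)

    def bw(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gi in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(gi)

    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Strided 1-D convolution: (N, Cin, L) * (Cout, Cin, k) -> (N, Cout, Lout)."""
    N, Cin, L = x.data.shape
    Cout, _, k = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    Lp = xp.shape[2]
    Lout = (Lp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride]
    col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(N * Lout, Cin * k)
    Wm = w.data.reshape(Cout, Cin * k)
    out_data = (col @ Wm.T + b.data).reshape(N, Lout, Cout).transpose(0, 2, 1)
    out = Tensor._make(out_data, (x, w, b), None)

    def bw(g):
        gcol = g.transpose(0, 2, 1).reshape(N * Lout, Cout)
        if w.requires_grad:
            w._accum((gcol.T @ col).reshape(Cout, Cin, k))
        if b.requires_grad:
            b._accum(gcol.sum(axis=0))
        if x.requires_grad:
            gx_col = (gcol @ Wm).reshape(N, Lout, Cin, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j : j + stride * Lout : stride] += gx_col[:, :, :, j]
            x._accum(gxp[:, :, pad : Lp - pad] if pad else gxp)

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean (class-weighted) cross-entropy of (N, k) logits vs int targets."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    N = len(targets)
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)[targets]
    wsum = w.sum()
    loss_val = -(w * np.log(np.maximum(p[np.arange(N), targets], 1e-30))).sum() / wsum
    out = Tensor._make(np.asarray(loss_val), (logits,), None)

    def bw(g):
        grad = p.copy()
        grad[np.arange(N), targets] -= 1.0
        logits._accum(g * grad * (w / wsum)[:, None])

    out._backward = bw
    return out


def sigmoid_bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of logits vs 0/1 targets."""
    z = logits.data.ravel().astype(np.float64)
    t = np.asarray(targets, dtype=float).ravel()
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    # stable formulation: max(z, 0) - z*t + log(1 + exp(-|z|))
    loss_val = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    out = Tensor._make(np.asarray(loss_val), (logits,), None)
    out._backward = lambda g: logits._accum(g * ((p - t) / len(t)).reshape(logits.data.shape))
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
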