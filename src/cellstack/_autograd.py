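"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the cell-set transformer and its losses
need: broadcasted arithmetic, stacked matmul, reductions, reshaping, fancy
indexing/concatenation, elementwise transcendentals (including ``lgamma``,
whose derivative is the digamma function), a sort primitive whose gradient
is the inverse permutation, and numerically guarded ``log``/``softplus``.

Float64 throughout: the models here are desk-scale, so determinism and
numerical headroom matter more than throughput.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "no_grad_mode"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "grad_scale")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self.grad_scale = 1.0  # optimizer-visible multiplier (gradient hooks)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            # copy: g may be a view into another node's buffer
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar-vs-0d edge
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack_ = [(t, False)]
            while stack_:
                node, done = stack_.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack_.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack_.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph: closures hold reference cycles that otherwise keep
        # every intermediate buffer alive until a GC pass
        for node in topo:
            node._backward = None
            node._parents = ()
            if not node.requires_grad:
                node.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data ** 2, other.data.shape)
                    )
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw(g):
                if self.requires_grad or self._parents:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.data.shape))
                if other.requires_grad or other._parents:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def log1p(self):
        out = _make(np.log1p(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g / (1.0 + self.data))
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out._parents:
            def bw(g):
                # value-exact; gradient guarded at 0 (subgradient 0 there)
                den = np.maximum(out.data, 1e-8)
                self._accumulate(np.where(out.data > 0, 0.5 * g / den, 0.0))
            out._backward = bw
        return out

    def erf(self):
        out = _make(special.erf(self.data), (self,))
        if out._parents:
            c = 2.0 / np.sqrt(np.pi)
            out._backward = lambda g: self._accumulate(g * c * np.exp(-self.data ** 2))
        return out

    def lgamma(self):
        out = _make(special.gammaln(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * special.digamma(self.data))
        return out

    def softplus(self):
        # stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        d = self.data
        out = _make(np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d))), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * special.expit(d))
        return out

    def sigmoid(self):
        out = _make(special.expit(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(gg, self.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a, b):
        out = _make(np.swapaxes(self.data, a, b), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bw
        return out

    def sort(self, axis=-1):
        """Ascending sort; gradient routed through the sorting permutation."""
        order = np.argsort(self.data, axis=axis, kind="stable")
        out = _make(np.take_along_axis(self.data, order, axis=axis), (self,))
        if out._parents:
            def bw(g):
                full = np.zeros_like(self.data)
                np.put_along_axis(full, order, g, axis=axis)
                self._accumulate(full)
            out._backward = bw
        return out

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        ex = np.exp(shifted)
        y = ex / ex.sum(axis=axis, keepdims=True)
        out = _make(y, (self,))
        if out._parents:
            def bw(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))
            out._backward = bw
        return out

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Fused layer normalization over the last axis."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = _make(xhat * gamma.data + beta.data, (self, gamma, beta))
        if out._parents:
            n = self.data.shape[-1]

            def bw(g):
                if gamma.requires_grad or gamma._parents:
                    gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
                if beta.requires_grad or beta._parents:
                    beta._accumulate(_unbroadcast(g, beta.data.shape))
                if self.requires_grad or self._parents:
                    gh = g * gamma.data
                    term = (gh - gh.mean(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
                    self._accumulate(inv * term)
            out._backward = bw
        return out

    def gelu(self):
        # exact GELU: x * Phi(x)
        return self * 0.5 * ((self * (1.0 / np.sqrt(2.0))).erf() + 1.0)


def _make(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    if live:
        out._parents = tuple(parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)
        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad or t._parents:
                    t._accumulate(np.take(g, i, axis=axis))
        out._backward = bw
    return out


class no_grad_mode:
    """Placeholder context for API symmetry; graph creation is cheap here and
    inference paths call ``.detach()`` where isolation matters."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
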