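"""Neural-network building blocks over the numpy autograd core.

Modules hold named :class:`Parameter` leaves and support ``state_dict`` /
``load_state_dict`` round trips (used by checkpointing and the EMA teacher).
The optimizer is decoupled-weight-decay Adam with global-norm gradient
clipping; per-parameter ``grad_scale`` implements gradient hooks (for the
query position embedding and the confidence classifier, which post-training
scales by 10x).
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "MultiheadAttention",
    "AdamW",
    "warmup_cosine_lr",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: recursive parameter discovery by attribute name."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state_dict key mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_grad_scale(self, scale: float):
        for p in self.parameters():
            p.grad_scale = float(scale)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, n_in, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.gamma, self.beta, eps=self._eps)


class MLP(Module):
    """Feed-forward stack with GELU between hidden layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.gelu()
        return x


class MultiheadAttention(Module):
    """Standard MHA over inputs of shape (batch, seq, dim).

    ``mask_bias`` is an additive (seq, seq) float array (0 where attention is
    allowed, a large negative number where it is blocked).
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 qk_init_scale: float = 1.0):
        if dim % n_heads != 0:
            raise ValueError(f"n_heads={n_heads} must divide dim={dim}")
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        if qk_init_scale != 1.0:
            # near-uniform attention at initialization (weights stay trainable)
            self.wq.weight.data *= qk_init_scale
            self.wk.weight.data *= qk_init_scale
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self._heads = n_heads
        self._dh = dim // n_heads

    def __call__(self, x: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        b, s, dim = x.shape
        h, dh = self._heads, self._dh

        def split(t):
            return t.reshape(b, s, h, dh).swapaxes(1, 2)  # (b, h, s, dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        if mask_bias is not None:
            scores = scores + Tensor(mask_bias)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(b, s, dim)
        return self.wo(out)


class AdamW(Module):
    """Adam with decoupled weight decay and global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: float | None = 1.0):
        self._params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._m = [np.zeros_like(p.data) for p in self._params]
        self._v = [np.zeros_like(p.data) for p in self._params]
        self._t = 0

    def zero_grad(self):
        for p in self._params:
            p.grad = None

    def step(self):
        grads = []
        for p in self._params:
            g = np.zeros_like(p.data) if p.grad is None else p.grad * p.grad_scale
            grads.append(g)
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, g, m, v in zip(self._params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def state(self) -> dict:
        return {"t": self._t, "m": [m.copy() for m in self._m], "v": [v.copy() for v in self._v]}

    def load_state(self, st: dict):
        self._t = int(st["t"])
        self._m = [np.asarray(m, dtype=np.float64).copy() for m in st["m"]]
        self._v = [np.asarray(v, dtype=np.float64).copy() for v in st["v"]]


def warmup_cosine_lr(step: int, total_steps: int, warmup_steps: int,
                     peak_lr: float, min_lr: float = 0.0) -> float:
    """Linear warmup to ``peak_lr`` followed by cosine annealing to ``min_lr``."""
    if warmup_steps > 0 and step < warmup_steps:
        return peak_lr * (step + 1) / warmup_steps
    denom = max(total_steps - warmup_steps, 1)
    frac = min(max(step - warmup_steps, 0) / denom, 1.0)
    return min_lr + 0.5 * (peak_lr - min_lr) * (1.0 + np.cos(np.pi * frac))
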