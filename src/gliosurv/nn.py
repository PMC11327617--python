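"""Neural-network building blocks on top of :mod:`gliosurv.autodiff`.

Contains exactly the layers the survival transformer needs: linear maps,
layer normalization, a small MLP, multi-head (cross-)attention, and an Adam
optimizer.  Parameter initialization follows the usual fan-in scaling.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "LayerNorm",
    "MLP",
    "MultiHeadAttention",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and freeze support."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def unfreeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = True

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())

    def parameter_checksum(self) -> float:
        """Order-stable checksum used to assert the frozen-encoder contract."""
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with GELU, the transformer feed-forward block."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadAttention(Module):
    """Multi-head scaled-dot-product attention, usable as self- or
    cross-attention: queries come from ``alpha``, keys and values from
    ``beta``.  Head outputs are concatenated and linearly recombined."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("embedding dim must be divisible by the head count")
        self.n_heads = n_heads
        self.d_k = dim // n_heads
        self.w_q = Linear(dim, dim, rng, bias=False)
        self.w_k = Linear(dim, dim, rng, bias=False)
        self.w_v = Linear(dim, dim, rng, bias=False)
        self.w_o = Linear(dim, dim, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        # (..., L, D) -> (..., H, L, d_k)
        *lead, L, D = x.shape
        x = x.reshape(*lead, L, self.n_heads, self.d_k)
        return x.swapaxes(-2, -3)

    def _merge(self, x: Tensor) -> Tensor:
        x = x.swapaxes(-2, -3)
        *lead, L, H, dk = x.shape
        return x.reshape(*lead, L, H * dk)

    def attention_weights(self, alpha: Tensor, beta: Tensor) -> Tensor:
        q = self._split(self.w_q(alpha))
        k = self._split(self.w_k(beta))
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.d_k))
        return scores.softmax(axis=-1)

    def __call__(self, alpha: Tensor, beta: Tensor) -> Tensor:
        attn = self.attention_weights(alpha, beta)
        v = self._split(self.w_v(beta))
        return self.w_o(self._merge(attn @ v))


class Adam:
    """Adam optimizer (Kingma & Ba) over an explicit parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
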