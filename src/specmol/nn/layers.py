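"""Parameterized layers built on the autodiff Tensor.

Parameters live in a flat ``dict[str, Tensor]`` registry so checkpoints can
serialize them by name. Initialization is Glorot-uniform from a caller-owned
``numpy.random.Generator``; layers never draw from global randomness.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax_last


class ParamStore:
    """Flat named parameter registry shared by a model's layers."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def add(self, name: str, array: np.ndarray) -> Tensor:
        if name in self.params:
            raise ValueError(f"duplicate parameter name {name!r}")
        t = Tensor(array, requires_grad=True)
        self.params[name] = t
        return t

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            t.data = state[k].astype(np.float64).copy()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, store: ParamStore, name: str, d_in: int, d_out: int,
                 rng: np.random.Generator):
        self.W = store.add(f"{name}.W", glorot(rng, d_in, d_out))
        self.b = store.add(f"{name}.b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP:
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, store: ParamStore, name: str, dims: list[int],
                 rng: np.random.Generator):
        self.layers = [
            Linear(store, f"{name}.fc{i}", dims[i], dims[i + 1], rng)
            for i in range(len(dims) - 1)
        ]

    def __call__(self, x: Tensor, dropout: "Dropout | None" = None) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                if dropout is not None:
                    x = dropout(x)
        return x


class LayerNorm:
    def __init__(self, store: ParamStore, name: str, dim: int):
        self.g = store.add(f"{name}.g", np.ones(dim))
        self.b = store.add(f"{name}.b", np.zeros(dim))
        self.eps = 1e-5

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.g + self.b


class Dropout:
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.training = False
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention over peak sets (no positions)."""

    def __init__(self, store: ParamStore, name: str, dim: int, heads: int,
                 rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"model dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.dk = dim, heads, dim // heads
        self.q = Linear(store, f"{name}.q", dim, dim, rng)
        self.k = Linear(store, f"{name}.k", dim, dim, rng)
        self.v = Linear(store, f"{name}.v", dim, dim, rng)
        self.o = Linear(store, f"{name}.o", dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, _ = x.shape

        def split(t: Tensor) -> Tensor:  # (B,L,D) -> (B,H,L,dk)
            return t.reshape(B, L, self.heads, self.dk).swapaxes(1, 2)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.dk))
        bias = np.where(mask[:, None, None, :], 0.0, -1e9)  # padded keys masked
        attn = softmax_last(scores + bias)
        out = (attn @ v).swapaxes(1, 2).reshape(B, L, self.dim)
        return self.o(out)


class TransformerEncoderLayer:
    """Post-norm transformer block: attention + FFN, each with residual."""

    def __init__(self, store: ParamStore, name: str, dim: int, heads: int,
                 ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(store, f"{name}.attn", dim, heads, rng)
        self.ln1 = LayerNorm(store, f"{name}.ln1", dim)
        self.ff = MLP(store, f"{name}.ff", [dim, ff_dim, dim], rng)
        self.ln2 = LayerNorm(store, f"{name}.ln2", dim)

    def __call__(self, x: Tensor, mask: np.ndarray,
                 dropout: Dropout | None = None) -> Tensor:
        h = self.ln1(x + self.attn(x, mask))
        if dropout is not None:
            h = dropout(h)
        return self.ln2(h + self.ff(h))
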