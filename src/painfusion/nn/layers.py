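"""Neural-network building blocks on top of the autodiff tensor.

Conventions: pre-norm residual transformer blocks, GELU feed-forward networks
for the attention encoders, ELU for the latent augmenter.  Every module takes
a ``numpy.random.Generator`` at construction so that initialization is fully
reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "Sequential",
    "softmax_attention",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:3]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


def softmax_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention softmax(QK^T/sqrt(d_k))V.

    Returns (output, attention weights); weight rows are stochastic.
    """
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class MultiHeadAttention(Module):
    """Multi-head attention; self-attention when kv_dim is None.

    Query and key/value streams may have different widths (cross-attention with
    a learned latent array).  The last computed attention weights are kept on
    ``last_weights`` for inspection.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 kv_dim: int | None = None):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        kv_dim = dim if kv_dim is None else kv_dim
        self.heads = heads
        self.head_dim = dim // heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(kv_dim, dim, rng)
        self.w_v = Linear(kv_dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        *lead, t, _ = x.shape
        return x.reshape(*lead, t, self.heads, self.head_dim).swapaxes(-2, -3)

    def forward(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        context = x if context is None else context
        q = self._split(self.w_q(x))
        k = self._split(self.w_k(context))
        v = self._split(self.w_v(context))
        out, weights = softmax_attention(q, k, v)
        self.last_weights = weights.data
        *lead, _, t, _ = out.shape
        merged = out.swapaxes(-2, -3).reshape(*lead, t, self.heads * self.head_dim)
        return self.w_o(merged)


class FeedForward(Module):
    """Two-layer position-wise network."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 activation: str = "gelu"):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x)
        h = h.gelu() if self.activation == "gelu" else h.elu()
        return self.fc2(h)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._seq = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x


class AttentionBlock(Module):
    """Pre-norm residual block: attention followed by a feed-forward network."""

    def __init__(self, dim: int, heads: int, ffn_hidden: int,
                 rng: np.random.Generator, kv_dim: int | None = None):
        super().__init__()
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(kv_dim) if kv_dim is not None else None
        self.attn = MultiHeadAttention(dim, heads, rng, kv_dim=kv_dim)
        self.norm_ffn = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_hidden, rng)
        self.is_cross = kv_dim is not None

    def forward(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        ctx = self.norm_kv(context) if context is not None else None
        x = x + self.attn(self.norm_q(x), context=ctx)
        return x + self.ffn(self.norm_ffn(x))


__all__.append("AttentionBlock")
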