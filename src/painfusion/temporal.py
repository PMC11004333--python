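"""Final classifier over session embeddings (video, heart-rate or fused).

The 1-D embedding is cut into 100-wide tokens — restoring the per-frame
structure of the concatenated video embedding — projected to an internal
width of 128 and summed with Fourier position features.  A learned latent
array cross-attends to the tokens (1 block, 1 head), three successive
self-attention blocks (8 heads, feed-forward after every attention) refine
the latents, and a linear head over the mean-pooled latents produces the
class logits (2 classes for NP vs P4, 5 for the multi-level task).

Latent count (32) and feed-forward width (1300) are fixed by the 1.63 M
parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .hr_encoder import fourier_positions
from .resample import bicubic_resize

__all__ = [
    "TemporalConfig",
    "Prediction",
    "TemporalNet",
    "tokenize_embedding",
    "temporal_forward",
    "temporal_attention_map",
]


@dataclass(frozen=True)
class TemporalConfig:
    internal_dim: int = 128
    cross_blocks: int = 1
    cross_heads: int = 1
    self_blocks: int = 3
    self_heads: int = 8
    n_latents: int = 32
    n_classes: int = 2
    d_token: int = 100           # frame-embedding width of the video stream
    fourier_bands: int = 32
    fcn_hidden: int = 1300       # fixed by the 1.63 M parameter budget

    def __post_init__(self):
        if self.internal_dim % self.self_heads:
            raise ValueError("internal_dim must be divisible by self_heads")


@dataclass
class Prediction:
    logits: np.ndarray
    probabilities: np.ndarray
    label: int


def tokenize_embedding(e: np.ndarray, d_token: int = 100,
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Reshape a length-N embedding into N/d_token tokens of width d_token.

    Zero-pads to the next multiple when d_token does not divide N and
    reports the padding length.  Also returns the Fourier position features
    for the token axis (computed by the caller's band count separately).
    """
    e = np.asarray(e, dtype=np.float64)
    n = e.shape[-1]
    pad = (-n) % d_token
    if pad:
        e = np.concatenate([e, np.zeros((*e.shape[:-1], pad))], axis=-1)
    tokens = e.reshape(*e.shape[:-1], (n + pad) // d_token, d_token)
    return tokens, e, pad


class TemporalNet(nn.Module):
    """Cross-attention + self-attention classifier over embedding tokens."""

    def __init__(self, cfg: TemporalConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or TemporalConfig()
        rng = np.random.default_rng(seed)
        dim = cfg.internal_dim
        self.token_proj = nn.Linear(cfg.d_token, dim, rng)
        self.pos_proj = nn.Linear(2 * cfg.fourier_bands + 1, dim, rng, bias=False)
        self.latents = Tensor(rng.normal(0, 0.02, (cfg.n_latents, dim)),
                              requires_grad=True)
        self.cross = nn.AttentionBlock(dim, cfg.cross_heads, cfg.fcn_hidden,
                                       rng, kv_dim=dim)
        for i in range(cfg.self_blocks):
            setattr(self, f"self{i}",
                    nn.AttentionBlock(dim, cfg.self_heads, cfg.fcn_hidden, rng))
        self.self_attn = [getattr(self, f"self{i}") for i in range(cfg.self_blocks)]
        self.norm = nn.LayerNorm(dim)
        self.head = nn.Linear(dim, cfg.n_classes, rng)

    def _tokens(self, x: Tensor) -> Tensor:
        d_tok = self.cfg.d_token
        if x.ndim == 1:
            x = x.reshape(1, x.shape[0])
        b, n = x.shape
        pad = (-n) % d_tok
        if pad:
            x = nn.concat([x, Tensor(np.zeros((b, pad)))], axis=1)
        t = (n + pad) // d_tok
        tokens = x.reshape(b, t, d_tok)
        pos = fourier_positions(t, self.cfg.fourier_bands)
        # per-sample scale normalisation keeps predictions batch-independent
        scale = np.maximum(np.abs(tokens.data).max(axis=(-2, -1), keepdims=True),
                           1e-8)
        return (self.token_proj(tokens * Tensor(1.0 / scale))
                + self.pos_proj(Tensor(pos)))

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Logits for a (B, N) embedding tensor (autograd-capable)."""
        tokens = self._tokens(x)
        b = tokens.shape[0]
        lat = self.latents + Tensor(np.zeros((b, 1, 1)))
        lat = self.cross(lat, context=tokens)
        for block in self.self_attn:
            lat = block(lat)
        pooled = self.norm(lat.mean(axis=1))
        return self.head(pooled)

    def forward(self, e: np.ndarray) -> Tensor:
        """Logits for a batch (B, N) or single (N,) numpy embedding."""
        e = np.asarray(e, dtype=np.float64)
        single = e.ndim == 1
        logits = self.forward_tensor(Tensor(e))
        return logits[0] if single else logits

    def predict(self, e: np.ndarray) -> Prediction:
        was_training = self.training
        self.eval()
        with nn.no_grad():
            logits = self.forward(np.asarray(e, dtype=np.float64))
        self.train(was_training)
        z = logits.data if logits.ndim == 1 else logits.data[0]
        p = np.exp(z - z.max())
        p /= p.sum()
        return Prediction(logits=z, probabilities=p, label=int(np.argmax(z)))


def temporal_forward(e: np.ndarray, model: TemporalNet) -> Prediction:
    return model.predict(e)


def temporal_attention_map(e: np.ndarray, model: TemporalNet,
                           height: int = 32, width_per_token: int = 8,
                           ) -> np.ndarray:
    """Per-token saliency strip from the head weights, as a rectangle.

    Token contributions are back-projected through the mean-pool readout:
    each latent's final state is scored against the head weights (averaged
    over classes) and distributed over tokens by the cross-attention
    weights.  The 1 x T strip is bicubic-interpolated to a display rectangle
    and min-max normalised to [0, 1].
    """
    cfg = model.cfg
    was_training = model.training
    model.eval()
    tokens = model._tokens(Tensor(np.atleast_2d(np.asarray(e, dtype=np.float64))))
    b = tokens.shape[0]
    lat = model.latents + Tensor(np.zeros((b, 1, 1)))
    lat = model.cross(lat, context=tokens)
    attn = model.cross.attn.last_weights      # (B, heads, n_latents, T)
    for block in model.self_attn:
        lat = block(lat)
    model.train(was_training)
    w = model.head.weight.data.mean(axis=1)   # (dim,)
    latent_scores = model.norm(lat).data[0] @ w          # (n_latents,)
    token_scores = attn[0].mean(axis=0).T @ latent_scores  # (T,)
    strip = token_scores[None, :]
    rect = bicubic_resize(strip, height, width_per_token * len(token_scores))
    span = rect.max() - rect.min()
    if span < 1e-12:
        return np.zeros_like(rect)
    return (rect - rect.min()) / span
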