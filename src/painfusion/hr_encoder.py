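"""Heart-rate encoder: cross-attention mapping of the per-second BPM vector.

The theta-point heart-rate vector (theta = 5 for a 5.5 s session) is turned
into theta input tokens carrying the BPM value plus Fourier position
features.  A small learned latent array (4 latents x 512, asymmetric
cross-attention: fewer queries than input features) attends to the tokens
once, passes through a feed-forward network, and the latents are flattened
into the 2048-dimensional embedding E_h.  A parameter-free bicubic expansion
then resamples E_h (arranged on a 32x64 grid) to any target length N so it
can be added elementwise to the video embedding.

The feed-forward width (3232) is fixed by the 4.40 M parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .resample import bicubic_resize

__all__ = [
    "HREncoderConfig",
    "HREmbedding",
    "ExpandedHREmbedding",
    "HeartRateEncoder",
    "fourier_positions",
    "bicubic_expand",
]


@dataclass(frozen=True)
class HREncoderConfig:
    internal_dim: int = 512
    cross_heads: int = 1
    depth: int = 1
    n_latents: int = 4
    out_dim: int = 2048
    fourier_bands: int = 32
    fcn_hidden: int = 3232   # fixed by the 4.40 M parameter budget

    def __post_init__(self):
        if self.n_latents * self.internal_dim != self.out_dim:
            raise ValueError("flatten readout needs n_latents * internal_dim == out_dim")


@dataclass
class HREmbedding:
    E_h: np.ndarray   # (2048,)


@dataclass
class ExpandedHREmbedding:
    B_h: np.ndarray   # (N,)


def fourier_positions(length: int, bands: int) -> np.ndarray:
    """Fourier feature position encoding for a 1-D index axis.

    Per position: the normalised coordinate in [-1, 1] followed by sin/cos
    pairs at ``bands`` frequencies log-spaced from 1 to the Nyquist frequency
    of the axis (length/2 cycles).  Shape (length, 2*bands + 1).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    pos = np.linspace(-1.0, 1.0, length) if length > 1 else np.zeros(1)
    max_freq = max(length / 2.0, 1.0)
    freqs = np.logspace(0.0, np.log10(max_freq), bands)
    args = np.pi * pos[:, None] * freqs[None, :]
    return np.concatenate([pos[:, None], np.sin(args), np.cos(args)], axis=1)


class HeartRateEncoder(nn.Module):
    """h in R^theta -> E_h in R^2048 via one cross-attention block."""

    def __init__(self, cfg: HREncoderConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or HREncoderConfig()
        rng = np.random.default_rng(seed)
        dim = cfg.internal_dim
        in_features = 1 + (2 * cfg.fourier_bands + 1)
        self.input_proj = nn.Linear(in_features, dim, rng)
        self.latents = Tensor(rng.normal(0, 0.02, (cfg.n_latents, dim)),
                              requires_grad=True)
        self.block = nn.AttentionBlock(dim, cfg.cross_heads, cfg.fcn_hidden,
                                       rng, kv_dim=dim)
        self.norm = nn.LayerNorm(dim)

    def forward(self, h: np.ndarray) -> Tensor:
        """Encode a batch (B, theta) or single (theta,) heart-rate vector."""
        h = np.asarray(h, dtype=np.float64)
        single = h.ndim == 1
        if single:
            h = h[None]
        b, theta = h.shape
        scaled = (h - 70.0) / 30.0     # fixed affine scaling to O(1) range
        pos = fourier_positions(theta, self.cfg.fourier_bands)
        feats = np.concatenate(
            [scaled[:, :, None], np.broadcast_to(pos, (b, *pos.shape))], axis=2)
        tokens = self.input_proj(Tensor(feats))            # (B, theta, dim)
        lat = self.latents + Tensor(np.zeros((b, 1, 1)))   # (B, n_latents, dim)
        lat = self.norm(self.block(lat, context=tokens))
        out = lat.reshape(b, self.cfg.out_dim)
        return out[0] if single else out

    def embed(self, h: np.ndarray) -> HREmbedding:
        was_training = self.training
        self.eval()
        with nn.no_grad():
            e = self.forward(np.asarray(h, dtype=np.float64)).data
        self.train(was_training)
        return HREmbedding(E_h=e if e.ndim == 1 else e[0])


def bicubic_expand(e: HREmbedding | np.ndarray, n_target: int,
                   grid_shape: tuple[int, int] = (32, 64)) -> ExpandedHREmbedding:
    """Expand E_h to length ``n_target`` by 2-D bicubic resampling.

    The vector is arranged row-major on a 32x64 grid, resampled to a grid of
    at least ``n_target`` elements with the aspect ratio preserved, flattened
    row-major and truncated to exactly ``n_target``.  Parameter-free and
    deterministic; reproduces constants exactly and is the identity when the
    target equals the source size.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    vec = e.E_h if isinstance(e, HREmbedding) else np.asarray(e, dtype=np.float64)
    gh, gw = grid_shape
    if vec.size != gh * gw:
        raise ValueError(f"embedding length {vec.size} does not fit grid {grid_shape}")
    if n_target == vec.size:
        return ExpandedHREmbedding(B_h=vec.astype(np.float64).copy())
    grid = vec.reshape(gh, gw).astype(np.float64)
    scale = np.sqrt(n_target / vec.size)
    out_h = max(int(np.ceil(gh * scale)), 1)
    out_w = max(int(np.ceil(n_target / (out_h * gw) * gw)), 1)
    while out_h * out_w < n_target:
        out_w += 1
    resized = bicubic_resize(grid, out_h, out_w)
    return ExpandedHREmbedding(B_h=resized.reshape(-1)[:n_target])
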