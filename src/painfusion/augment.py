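"""Latent-space augmentations for the fused session embeddings.

Three methods, all operating on embeddings rather than pixels or raw
signals:

* ``AugmNet`` — a learned encoder-decoder (2 + 2 fully connected layers,
  ELU after each) trained jointly with the downstream classification loss;
  its narrow mixing layers corrupt the embedding during training, acting as
  a learned regulariser.  At inference it is a bit-identical passthrough.
* ``basic_augment`` — random polarity inversion plus Gaussian noise scaled
  to a fraction of the embedding's standard deviation.
* ``mask_augment`` — one contiguous span covering 10-20 % of the embedding
  set to zero at a random position (no wrap-around).

AugmNet's layer widths (36, 170, 36) are fixed by its 1.02 M parameter
budget at the default embedding length N = 13,800.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "AugmNetConfig",
    "AugmNet",
    "basic_augment",
    "mask_augment",
]


@dataclass(frozen=True)
class AugmNetConfig:
    n: int = 13800                              # embedding length N
    enc_hidden: tuple[int, int] = (36, 170)     # encoder layer widths
    dec_hidden: int = 36                        # first decoder layer width


class AugmNet(nn.Module):
    """Training-only latent augmenter; identity in eval mode."""

    def __init__(self, cfg: AugmNetConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or AugmNetConfig()
        rng = np.random.default_rng(seed)
        a, b = cfg.enc_hidden
        c = cfg.dec_hidden
        self.enc1 = nn.Linear(cfg.n, a, rng)
        self.enc2 = nn.Linear(a, b, rng)
        self.dec1 = nn.Linear(b, c, rng)
        self.dec2 = nn.Linear(c, cfg.n, rng)

    def forward(self, e: Tensor | np.ndarray) -> Tensor:
        x = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=np.float64))
        if x.shape[-1] != self.cfg.n:
            raise ValueError(f"expected embedding length {self.cfg.n}, "
                             f"got {x.shape[-1]}")
        if not self.training:
            return x                      # inference-inactive contract
        h = self.enc1(x).elu()
        h = self.enc2(h).elu()
        h = self.dec1(h).elu()
        return self.dec2(h).elu()


def basic_augment(e: np.ndarray, invert_p: float = 0.5, noise_sd: float = 0.1,
                  seed: int = 0) -> np.ndarray:
    """Polarity inversion (probability ``invert_p``) + relative Gaussian noise.

    ``noise_sd`` is expressed as a fraction of the embedding's own standard
    deviation, keeping the perturbation scale modality-agnostic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = np.asarray(e, dtype=np.float64).copy()
    if rng.random() < invert_p:
        out = -out
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd * out.std(), out.shape)
    return out


def mask_augment(e: np.ndarray, seed: int = 0,
                 frac_range: tuple[float, float] = (0.10, 0.20)) -> np.ndarray:
    """Zero one contiguous random span of 10-20 % of the embedding length.

    The span never wraps: draws that would be clipped at the end are
    redrawn.
    """
    out = np.asarray(e, dtype=np.float64).copy()
    n = out.shape[-1]
    if n < 10:
        raise ValueError("embedding too short to mask")
    rng = np.random.default_rng(seed)
    lo = int(np.ceil(frac_range[0] * n))
    hi = int(np.floor(frac_range[1] * n))
    span = int(rng.integers(lo, hi + 1))
    while True:
        start = int(rng.integers(0, n))
        if start + span <= n:
            break
    out[..., start:start + span] = 0.0
    return out
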