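"""Transformer-in-Transformer image encoder for per-frame video embeddings.

Each 224x224 image (the resized full face crop or one of the four quadrant
tiles) is decomposed into 196 non-overlapping 16x16 patches, each further
split into 16 4x4 sub-patches.  Sub-patch tokens are refined by an inner
encoder (4 heads), folded back into the patch tokens, and the patch sequence
(plus a class token) is refined by an outer encoder (10 heads), over 12
blocks.  The class-token readout gives a d=100 embedding per image; the five
per-frame embeddings fuse as

    D = d_full + c * (d_tile1 + d_tile2 + d_tile3 + d_tile4),   c = 0.1,

and the per-frame vectors concatenate into the session video embedding
VD = [D_1 || ... || D_f] of length N = d * f.

Free hyperparameters (inner width 24, feed-forward widths 96 and 600) are
fixed so the module counts 2.57 M trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .resample import bicubic_resize
from .video import FaceCrop, make_tileset

__all__ = [
    "SpatialConfig",
    "PatchDecomposition",
    "FrameEmbedding",
    "VideoEmbedding",
    "SpatialEncoder",
    "patchify",
    "frame_fuse",
    "video_forward",
    "spatial_attention_map",
]

# fixed per-channel pixel normalisation (inputs scaled to roughly unit range)
_PIX_MEAN = 0.5
_PIX_STD = 0.5


@dataclass(frozen=True)
class SpatialConfig:
    image_size: int = 224
    patch_size: int = 16          # p
    sub_patch_size: int = 4       # s
    embed_dim: int = 100          # d
    inner_dim: int = 24
    inner_heads: int = 4
    outer_heads: int = 10
    depth: int = 12
    fcn_inner_hidden: int = 96    # 4 x inner_dim
    fcn_outer_hidden: int = 600   # fixed by the 2.57 M parameter budget
    tile_coeff: float = 0.1       # c

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("patch size must divide the image size")
        if self.patch_size % self.sub_patch_size:
            raise ValueError("sub-patch size must divide the patch size")
        if self.embed_dim % self.outer_heads or self.inner_dim % self.inner_heads:
            raise ValueError("embedding dims must be divisible by head counts")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:          # n
        return self.grid**2

    @property
    def n_sub(self) -> int:              # m
        return (self.patch_size // self.sub_patch_size) ** 2


@dataclass
class PatchDecomposition:
    patches: np.ndarray       # (n, p, p, 3), raster order
    sub_patches: np.ndarray   # (n, m, s, s, 3), raster order within each patch


@dataclass
class FrameEmbedding:
    D: np.ndarray                       # (d,)
    parts: np.ndarray | None = None     # (5, d): full frame then 4 tiles


@dataclass
class VideoEmbedding:
    VD: np.ndarray   # (N,) with N = d * f
    f: int
    d: int


def patchify(image: np.ndarray, cfg: SpatialConfig | None = None) -> PatchDecomposition:
    """Split an image into raster-ordered patches and sub-patches."""
    cfg = cfg or SpatialConfig()
    img = np.asarray(image)
    if img.shape != (cfg.image_size, cfg.image_size, 3):
        raise ValueError(
            f"expected {cfg.image_size}x{cfg.image_size}x3, got {img.shape}")
    g, p, s = cfg.grid, cfg.patch_size, cfg.sub_patch_size
    patches = (img.reshape(g, p, g, p, 3)
                  .transpose(0, 2, 1, 3, 4)
                  .reshape(cfg.n_patches, p, p, 3))
    q = p // s
    sub = (patches.reshape(cfg.n_patches, q, s, q, s, 3)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(cfg.n_patches, cfg.n_sub, s, s, 3))
    return PatchDecomposition(patches=patches, sub_patches=sub)


class TNTBlock(nn.Module):
    """Inner encoder on sub-patch tokens, fold-in projection, outer encoder."""

    def __init__(self, cfg: SpatialConfig, rng: np.random.Generator):
        super().__init__()
        c, d, m = cfg.inner_dim, cfg.embed_dim, cfg.n_sub
        self.inner = nn.AttentionBlock(c, cfg.inner_heads, cfg.fcn_inner_hidden, rng)
        self.proj_norm = nn.LayerNorm(m * c)
        self.proj = nn.Linear(m * c, d, rng)
        self.outer = nn.AttentionBlock(d, cfg.outer_heads, cfg.fcn_outer_hidden, rng)
        self._m, self._c = m, c

    def forward(self, patch_tokens: Tensor, sub_tokens: Tensor):
        sub_tokens = self.inner(sub_tokens)                # (B, n, m, c)
        b, n = sub_tokens.shape[0], sub_tokens.shape[1]
        folded = self.proj(self.proj_norm(
            sub_tokens.reshape(b, n, self._m * self._c)))  # (B, n, d)
        pad = Tensor(np.zeros((b, 1, folded.shape[-1])))
        patch_tokens = patch_tokens + nn.concat([pad, folded], axis=1)
        return self.outer(patch_tokens), sub_tokens


class SpatialEncoder(nn.Module):
    """The full image encoder (patchify -> TNT blocks -> class-token readout)."""

    def __init__(self, cfg: SpatialConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or SpatialConfig()
        rng = np.random.default_rng(seed)
        c, d = cfg.inner_dim, cfg.embed_dim
        s3 = cfg.sub_patch_size**2 * 3
        self.sub_embed = nn.Linear(s3, c, rng)
        self.patch_embed = nn.Linear(cfg.n_sub * c, d, rng)
        self.cls_token = Tensor(rng.normal(0, 0.02, (1, 1, d)), requires_grad=True)
        self.pos_patch = Tensor(rng.normal(0, 0.02, (cfg.n_patches + 1, d)),
                                requires_grad=True)
        self.pos_sub = Tensor(rng.normal(0, 0.02, (cfg.n_sub, c)),
                              requires_grad=True)
        for i in range(cfg.depth):
            setattr(self, f"block{i}", TNTBlock(cfg, rng))
        self.blocks = [getattr(self, f"block{i}") for i in range(cfg.depth)]
        self.norm = nn.LayerNorm(d)
        self.readout = nn.Linear(d, d, rng)

    # -- forward pieces -------------------------------------------------------
    def _tokenize(self, images: np.ndarray):
        cfg = self.cfg
        b = images.shape[0]
        x = images.astype(np.float64)
        if x.max() > 1.5:
            x = x / 255.0
        x = (x - _PIX_MEAN) / _PIX_STD
        g, p, s = cfg.grid, cfg.patch_size, cfg.sub_patch_size
        q = p // s
        sub = (x.reshape(b, g, p, g, p, 3)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(b, cfg.n_patches, q, s, q, s, 3)
                .transpose(0, 1, 2, 4, 3, 5, 6)
                .reshape(b, cfg.n_patches, cfg.n_sub, s * s * 3))
        sub_tokens = self.sub_embed(Tensor(sub)) + self.pos_sub
        flat = sub_tokens.reshape(b, cfg.n_patches, cfg.n_sub * cfg.inner_dim)
        patch_tokens = self.patch_embed(flat)
        cls = self.cls_token + Tensor(np.zeros((b, 1, cfg.embed_dim)))
        patch_tokens = nn.concat([cls, patch_tokens], axis=1) + self.pos_patch
        return patch_tokens, sub_tokens

    def forward_tokens(self, images: np.ndarray):
        patch_tokens, sub_tokens = self._tokenize(images)
        for block in self.blocks:
            patch_tokens, sub_tokens = block(patch_tokens, sub_tokens)
        return self.norm(patch_tokens)

    def forward(self, images: np.ndarray) -> Tensor:
        """Encode a batch of images -> (B, d) embeddings."""
        tokens = self.forward_tokens(images)
        return self.readout(tokens[:, 0, :])

    def embed(self, images: np.ndarray, chunk: int = 16) -> np.ndarray:
        """Eval-mode numpy embedding of a (B, H, W, 3) image stack."""
        was_training = self.training
        self.eval()
        with nn.no_grad():
            outs = [self.forward(images[i:i + chunk]).data
                    for i in range(0, len(images), chunk)]
        self.train(was_training)
        return np.concatenate(outs, axis=0)


def frame_fuse(parts, c: float | None = None,
               cfg: SpatialConfig | None = None) -> FrameEmbedding:
    """Fuse the 5 per-image embeddings: D = d_full + c * sum(tiles)."""
    cfg = cfg or SpatialConfig()
    c = cfg.tile_coeff if c is None else c
    parts = np.asarray(parts, dtype=np.float64)
    if parts.shape[0] != 5 or parts.ndim != 2:
        raise ValueError("expected 5 embedding vectors of equal length")
    return FrameEmbedding(D=parts[0] + c * parts[1:].sum(axis=0), parts=parts)


def video_forward(frames, model: SpatialEncoder, c: float | None = None,
                  chunk: int = 16) -> VideoEmbedding:
    """Embed a session: tile each frame, encode all 5f images, fuse, concat."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    stacks = []
    for fr in frames:
        crop = fr if isinstance(fr, FaceCrop) else FaceCrop(image=np.asarray(fr))
        ts = make_tileset(crop)
        stacks.extend([np.asarray(im, dtype=np.float64) for im in ts.images])
    images = np.stack(stacks)                      # (5f, 224, 224, 3)
    emb = model.embed(images, chunk=chunk)         # (5f, d)
    d = emb.shape[1]
    per_frame = emb.reshape(len(frames), 5, d)
    fused = [frame_fuse(p, c=c, cfg=model.cfg).D for p in per_frame]
    vd = np.concatenate(fused)
    return VideoEmbedding(VD=vd, f=len(frames), d=d)


def spatial_attention_map(image: np.ndarray, model: SpatialEncoder,
                          out_size: int | None = None) -> np.ndarray:
    """Patch-level saliency from the readout layer's weights.

    Each final patch token is scored by its alignment with the readout
    weights (averaged over output features), the 14x14 score grid is
    bicubic-interpolated to the image resolution and min-max normalised
    to [0, 1].
    """
    cfg = model.cfg
    was_training = model.training
    model.eval()
    tokens = model.forward_tokens(image[None]).data[0]   # (n+1, d)
    model.train(was_training)
    w = model.readout.weight.data.mean(axis=1)           # (d,)
    scores = tokens[1:] @ w                              # (n,)
    grid = scores.reshape(cfg.grid, cfg.grid)
    size = out_size or cfg.image_size
    up = bicubic_resize(grid, size, size)
    rng_span = up.max() - up.min()
    if rng_span < 1e-12:
        return np.zeros_like(up)
    return (up - up.min()) / rng_span
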