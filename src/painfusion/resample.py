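"""Separable bicubic resampling (Keys kernel, a = -0.5).

Used for the full-frame resize in the tiling pipeline, the grid expansion of
the heart-rate embedding, and attention-map upsampling.  Convention: cubic
convolution with a = -0.5, half-pixel sample centres, edge replication.
Matches Pillow's BICUBIC filter for upsampling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bicubic_resize", "keys_kernel"]


def keys_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic convolution kernel of Keys (1981)."""
    x = np.abs(np.asarray(x, dtype=np.float64))
    out = np.zeros_like(x)
    near = x <= 1
    mid = (x > 1) & (x < 2)
    out[near] = (a + 2) * x[near] ** 3 - (a + 3) * x[near] ** 2 + 1
    out[mid] = a * x[mid] ** 3 - 5 * a * x[mid] ** 2 + 8 * a * x[mid] - 4 * a
    return out


def _resize_axis(arr: np.ndarray, n_dst: int, axis: int) -> np.ndarray:
    """Cubic 4-tap resampling along one axis (edge-replicated, normalised)."""
    n_src = arr.shape[axis]
    if n_src == n_dst:
        return arr
    u = (np.arange(n_dst) + 0.5) * (n_src / n_dst) - 0.5
    base = np.floor(u).astype(int)
    shape = [1] * arr.ndim
    shape[axis] = n_dst
    acc = 0.0
    wsum = 0.0
    for t in range(-1, 3):
        j = base + t
        w = keys_kernel(u - j)
        acc = acc + w.reshape(shape) * np.take(arr, np.clip(j, 0, n_src - 1),
                                               axis=axis)
        wsum = wsum + w
    # normalise tiny numeric drift so constants are reproduced exactly
    return acc / wsum.reshape(shape)


def bicubic_resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Resize a (H, W) or (H, W, C) array to (out_h, out_w[, C])."""
    img = np.asarray(image, dtype=np.float64)
    out = _resize_axis(img, out_h, 0)
    return _resize_axis(out, out_w, 1)
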