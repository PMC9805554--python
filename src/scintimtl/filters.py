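"""Small fixed smoothing kernels shared by the guidance-map code paths."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["gaussian_kernel_3x3", "smooth_3x3"]


def gaussian_kernel_3x3(sigma: float = 1.0) -> np.ndarray:
    """3x3 Gaussian kernel, renormalized to sum to 1."""
    d = np.array([-1.0, 0.0, 1.0])
    k1 = np.exp(-(d**2) / (2.0 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def smooth_3x3(channels: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Apply the normalized 3x3 Gaussian per channel, nearest-edge padding.

    Nearest-edge padding keeps constants constant, so smoothing a partition
    of unity (e.g. a one-hot label encoding) preserves the per-pixel sum of 1
    everywhere, including at the image border.

    channels: (..., H, W); the filter acts on the last two axes.
    """
    k = gaussian_kernel_3x3(sigma)
    out = np.empty_like(channels, dtype=np.float64)
    flat = channels.reshape(-1, *channels.shape[-2:])
    oflat = out.reshape(-1, *channels.shape[-2:])
    for i in range(flat.shape[0]):
        oflat[i] = ndimage.correlate(flat[i].astype(np.float64), k, mode="nearest")
    return out
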