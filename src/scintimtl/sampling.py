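"""Lesion-likelihood patch sampling.

Uniformly drawn training patches from a whole-body scan are almost all empty
background, which drives a segmentation network toward the trivial all-zero
solution. Instead, the binary lesion mask is smoothed into a likelihood map
and patch centers are drawn from it by rejection sampling, so patches
concentrate in and around lesions while a uniform "background floor" mixed
into the map keeps a controlled share of pure-background patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["LikelihoodMap", "PatchPair", "likelihood_map", "sample_patch_centers", "extract_patch_pair"]


@dataclass
class LikelihoodMap:
    """Normalized nonnegative sampling weights over the image domain."""

    weights: np.ndarray            # sums to 1
    normalization: float           # sum of the raw (pre-normalization) map
    sigma: float
    background_floor: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass
class PatchPair:
    """All aligned s x s crops the network consumes for one center."""

    image_patch: np.ndarray                   # normalized to [0, 1]
    lesion_target: np.ndarray                 # binary
    mas_patch: np.ndarray                     # fused pseudo-labels
    annotation_mask_patch: np.ndarray         # binary consensus mask
    skeleton_target: np.ndarray | None = None  # manual labels, if the study has them
    center: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        s = self.image_patch.shape
        for name in ("lesion_target", "mas_patch", "annotation_mask_patch"):
            if getattr(self, name).shape != s:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != image patch {s}")
        if self.skeleton_target is not None and self.skeleton_target.shape != s:
            raise ValueError("skeleton_target shape mismatch")


def likelihood_map(
    mask: np.ndarray, sigma: float = 8.0, background_floor: float = 0.1
) -> LikelihoodMap:
    """Gaussian-smooth the 0/1 lesion mask into sampling weights.

    l = (1 - floor) * normalize(G_sigma * mask) + floor * uniform. The floor
    guarantees every pixel (hence pure-background patches) retains a nonzero
    draw probability. An all-zero mask degenerates to the uniform floor alone.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 <= background_floor < 1:
        raise ValueError("background_floor must be in [0, 1)")
    m = np.asarray(mask, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(m, sigma)
    total = smoothed.sum()
    uniform = np.full(m.shape, 1.0 / m.size)
    if total == 0:
        logger.info("all-zero lesion mask: likelihood map falls back to the uniform floor")
        weights = uniform
    else:
        weights = (1.0 - background_floor) * smoothed / total + background_floor * uniform
    return LikelihoodMap(weights, float(total), sigma, background_floor)


def sample_patch_centers(
    lmap: LikelihoodMap | np.ndarray,
    n: int,
    seed: int,
    patch_size: int | None = None,
    max_rejections: int = 10_000_000,
) -> list[tuple[int, int]]:
    """Draw ``n`` patch centers by rejection sampling from the likelihood map.

    Uniform candidate centers are accepted with probability l(c)/max(l).
    When ``patch_size`` is given, accepted centers are clamped so the full
    s x s window fits inside the image (no padding semantics needed).
    Deterministic per seed. Returns (row, col) tuples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    w = lmap.weights if isinstance(lmap, LikelihoodMap) else np.asarray(lmap, dtype=np.float64)
    wmax = w.max()
    if n > 0 and wmax <= 0:
        raise ValueError("degenerate all-zero likelihood map: cannot accept any center")
    h, wd = w.shape
    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int]] = []
    tries = 0
    batch = max(64, 4 * n)
    while len(centers) < n:
        if tries > max_rejections:
            raise RuntimeError("rejection sampling stalled (acceptance rate too low)")
        rows = rng.integers(0, h, size=batch)
        cols = rng.integers(0, wd, size=batch)
        u = rng.uniform(size=batch)
        acc = u < w[rows, cols] / wmax
        tries += batch
        for r, c in zip(rows[acc], cols[acc]):
            centers.append((int(r), int(c)))
            if len(centers) == n:
                break
    if patch_size is not None:
        half = patch_size // 2
        if patch_size > h or patch_size > wd:
            raise ValueError(f"patch {patch_size} larger than image {h}x{wd}")
        centers = [
            (int(np.clip(r, half, h - patch_size + half)), int(np.clip(c, half, wd - patch_size + half)))
            for r, c in centers
        ]
    return centers


def dump_centers(centers: list[tuple[int, int]], path) -> None:
    """Debug dump of sampled patch centers as a two-column CSV."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["row", "col"])
        w.writerows(centers)


def extract_patch_pair(
    sample,
    mas_result,
    center: tuple[int, int],
    patch_size: int = 128,
    normalization: str = "max",
) -> PatchPair:
    """Crop all aligned maps at one window and normalize the image crop.

    ``normalization``: "max" divides by the study's 16-bit maximum (maps the
    full scan into [0, 1]); "255" divides by the literal 255.0 (then clips),
    for 8-bit-scaled data. The window is clamped to the image bounds, so the
    crop is always exactly s x s.
    """
    pixels = sample.image.pixels
    h, w = pixels.shape
    s = patch_size
    r0 = int(np.clip(center[0] - s // 2, 0, h - s))
    c0 = int(np.clip(center[1] - s // 2, 0, w - s))
    win = (slice(r0, r0 + s), slice(c0, c0 + s))
    img = pixels[win].astype(np.float64)
    if normalization == "max":
        img = img / max(float(pixels.max()), 1.0)
    elif normalization == "255":
        img = np.clip(img / 255.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    skel = getattr(sample, "skeleton_labels", None)
    return PatchPair(
        image_patch=img,
        lesion_target=np.asarray(sample.lesion_mask)[win].astype(np.float64),
        mas_patch=np.asarray(mas_result.fused_labels)[win],
        annotation_mask_patch=np.asarray(mas_result.annotation_mask)[win],
        skeleton_target=None if skel is None else np.asarray(skel)[win],
        center=(r0 + s // 2, c0 + s // 2),
    )
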