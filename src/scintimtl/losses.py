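"""Loss terms for the weakly-supervised multi-task objective.

Four ingredients:

* ``wbce`` — weighted binary cross-entropy for the lesion branch,
  ``-mean[w * y * log(yhat) + (1-y) * log(1-yhat)]`` with ``w`` upweighting
  the (rare) lesion class.
* ``ce`` — multi-class cross-entropy ``-mean[log zhat_i[z_i]]`` for the
  skeleton branch when full labels exist.
* ``pce`` — partial cross-entropy: CE averaged only over pixels flagged
  trusted by a binary annotation mask ``m`` (the weak-supervision case where
  skeleton targets are multi-atlas pseudo-labels).
* ``crf_loss`` — a differentiable quadratic relaxation of the CRF pairwise
  energy, ``sum_ij sum_c zhat_ic (1 - zhat_jc) W_ij``, with ``W`` a bilateral
  Gaussian affinity between nearby pixels. The pair sum runs over a local
  window (default 5x5) rather than all pixel pairs, and is normalized by the
  number of ordered pairs so its magnitude is patch-size independent.

All losses accept the autodiff ``Tensor`` for the prediction argument (plain
arrays are wrapped, giving a constant), return a scalar ``Tensor``, and are
exercised against brute-force oracles and finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "wbce",
    "ce",
    "pce",
    "bilateral_affinity",
    "crf_loss",
    "total_loss",
]

EPS = 1e-7  # probability clamp used inside every log


@dataclass
class LossConfig:
    w: float = 5.0                 # positive-class weight in wBCE
    crf_sigma_xy: float = 3.0      # spatial bandwidth, pixels
    crf_sigma_int: float = 0.1     # intensity bandwidth, normalized units
    crf_window: int = 5            # odd window bounding the pair sum
    term_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crf_branch: str = "skeleton"   # "skeleton" (default), "lesion", or "both"

    def validate(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.crf_window % 2 == 0 or self.crf_window < 3:
            raise ValueError("crf_window must be odd and >= 3")


def _check_shapes(a, b, what: str) -> None:
    if tuple(np.shape(a)) != tuple(np.shape(b)):
        raise ValueError(f"{what}: shape mismatch {np.shape(a)} vs {np.shape(b)}")


def wbce(yhat, y, w: float = 5.0) -> Tensor:
    """Weighted binary cross-entropy, mean over all pixels (and batch)."""
    yhat = as_tensor(yhat)
    y = np.asarray(y, dtype=yhat.dtype.type)
    _check_shapes(yhat.data, y, "wbce")
    p = yhat.clip(EPS, 1.0 - EPS)
    pos = Tensor(y) * p.log()
    neg = Tensor(1.0 - y) * (1.0 - p).log()
    return -(w * pos + neg).mean()


def _per_pixel_ce(zhat: Tensor, z: np.ndarray) -> Tensor:
    """-log zhat[z] per pixel; channel axis is -3.

    Fused gather + clamped log with an analytic backward (a one-hot
    formulation builds C-channel temporaries per step, which dominates the
    training loop for little gain).
    """
    n_classes = zhat.shape[-3]
    z = np.asarray(z)
    if z.min() < 0 or z.max() >= n_classes:
        raise ValueError(f"label outside [0, {n_classes}): range {z.min()}..{z.max()}")
    idx = z[..., None, :, :]
    picked = np.take_along_axis(zhat.data, idx, axis=-3)
    clamped = np.clip(picked, EPS, 1.0)
    out = -np.log(clamped)[..., 0, :, :]

    def bwd(g):
        inside = (picked >= EPS) & (picked <= 1.0)
        gz = np.zeros_like(zhat.data)
        np.put_along_axis(gz, idx, np.where(inside, -g[..., None, :, :] / clamped, 0.0), axis=-3)
        zhat._accumulate(gz)

    return Tensor(out, parents=(zhat,), backward=bwd)


def ce(zhat, z) -> Tensor:
    """Multi-class cross-entropy against integer labels, mean over pixels."""
    zhat = as_tensor(zhat)
    return _per_pixel_ce(zhat, z).mean()


def pce(zhat, z, m) -> Tensor:
    """Partial cross-entropy: CE averaged over the ``m == 1`` pixels only."""
    zhat = as_tensor(zhat)
    m = np.asarray(m, dtype=zhat.dtype.type)
    total = float(m.sum())
    if total == 0:
        raise ValueError("empty annotation mask: no annotated pixel to average over")
    perpix = _per_pixel_ce(zhat, z)
    _check_shapes(perpix.data, m, "pce mask")
    return (perpix * Tensor(m)).sum() / total


def _window_offsets(window: int) -> list[tuple[int, int]]:
    r = window // 2
    return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if (dy, dx) != (0, 0)]


def bilateral_affinity(
    image_patch: np.ndarray,
    sigma_xy: float = 3.0,
    sigma_int: float = 0.1,
    window: int = 5,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Bilateral Gaussian affinities between each pixel and its window.

    Returns ``(offsets, weights)`` where ``weights[o, i, j]`` is
    ``W(p, p + offsets[o]) = exp(-|dp|^2 / 2 sxy^2 - (I_p - I_q)^2 / 2 si^2)``
    for pixel ``p = (i, j)``, and zero where the partner falls outside the
    image. Self-pairs are excluded; the stack is symmetric in the sense that
    ``weights[o][p] == weights[o'][p + off]`` for the opposite offset ``o'``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    img = np.asarray(image_patch, dtype=np.float64)
    h, w = img.shape[-2:]
    offsets = _window_offsets(window)
    weights = np.zeros((len(offsets),) + img.shape, dtype=np.float64)
    for o, (dy, dx) in enumerate(offsets):
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        yd = slice(max(0, dy), min(h, h + dy))
        xd = slice(max(0, dx), min(w, w + dx))
        diff = img[..., ys, xs] - img[..., yd, xd]
        spatial = (dy * dy + dx * dx) / (2.0 * sigma_xy**2)
        weights[o, ..., ys, xs] = np.exp(-spatial - diff**2 / (2.0 * sigma_int**2))
    return offsets, weights


def crf_loss(
    zhat,
    image_patch: np.ndarray,
    config: LossConfig | None = None,
) -> Tensor:
    """Quadratic CRF relaxation over windowed pixel pairs, pair-normalized.

    ``zhat``: (C, H, W) or (N, C, H, W) softmax output; ``image_patch`` the
    matching normalized intensity patch(es) defining the affinities.
    """
    config = config or LossConfig()
    config.validate()
    zhat = as_tensor(zhat)
    offsets, wts = bilateral_affinity(
        image_patch, config.crf_sigma_xy, config.crf_sigma_int, config.crf_window
    )
    h, w = np.shape(image_patch)[-2:]
    n_img = int(np.prod(np.shape(image_patch)[:-2])) or 1
    n_pairs = float(n_img * sum((h - abs(dy)) * (w - abs(dx)) for dy, dx in offsets)) or 1.0
    # Fused evaluation with analytic gradient. Using sum_c z_ic = 1:
    #   L = sum_off sum_i W^off_i (1 - <z_i, z_{i+off}>)
    #   dL/dz_pc = -sum_off 2 W^off_p z_{p+off,c}   (offsets come in +/- pairs
    # and the affinity is symmetric, so both pair roles collapse into one term)
    z = zhat.data
    gz = np.zeros_like(z)
    loss = 0.0
    for o, (dy, dx) in enumerate(offsets):
        w_o = wts[o].astype(z.dtype)
        zs = np.zeros_like(z)
        ys = slice(max(0, -dy), min(h, h - dy))
        yd = slice(max(0, dy), min(h, h + dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        xd = slice(max(0, dx), min(w, w + dx))
        zs[..., ys, xs] = z[..., yd, xd]
        dot = np.einsum("...chw,...chw->...hw", z, zs)
        loss += float(w_o.sum() - (w_o * dot).sum())
        gz -= 2.0 * w_o[..., None, :, :] * zs
    gz /= n_pairs

    def bwd(g):
        zhat._accumulate(np.asarray(g) * gz)

    return Tensor(np.asarray(loss / n_pairs, dtype=z.dtype), parents=(zhat,), backward=bwd)


def total_loss(outputs, patch_pair, mode: str, config: LossConfig | None = None):
    """Compose the three-term objective for one patch.

    supervised:   w1*wBCE(lesion) + w2*CE(skeleton truth)     + w3*CRF
    unsupervised: w1*wBCE(lesion) + w2*pCE(MAS pseudo-labels) + w3*CRF

    Returns ``(total, terms)`` where ``terms`` maps term name -> float for
    logging. The CRF regularizes the skeleton softmax by default; set
    ``config.crf_branch`` to "lesion" or "both" to also smooth the lesion
    probabilities (treated as a 2-class distribution).
    """
    config = config or LossConfig()
    config.validate()
    if mode not in ("supervised", "unsupervised"):
        raise ValueError(f"unknown mode {mode!r}")
    w1, w2, w3 = config.term_weights

    lesion_t = outputs.lesion_prob_t
    skel_t = outputs.skeleton_prob_t
    img = patch_pair.image_patch
    y = patch_pair.lesion_target
    # align batch axes: forward() on a single pair yields (1,1,H,W)/(1,C,H,W)
    if lesion_t.data.ndim == 4 and np.ndim(y) == 2:
        y = y[None, None]
    elif lesion_t.data.ndim == 4:
        y = np.asarray(y)[:, None]

    term_bce = wbce(lesion_t, y, w=config.w)
    if mode == "supervised":
        if patch_pair.skeleton_target is None:
            raise ValueError("supervised mode requires a skeleton_target")
        z = patch_pair.skeleton_target
        z = z[None] if skel_t.data.ndim == 4 and np.ndim(z) == 2 else z
        term_seg = ce(skel_t, z)
    else:
        z = patch_pair.mas_patch
        m = patch_pair.annotation_mask_patch
        if skel_t.data.ndim == 4 and np.ndim(z) == 2:
            z, m = z[None], m[None]
        term_seg = pce(skel_t, z, m)

    img_b = img[None] if skel_t.data.ndim == 4 and np.ndim(img) == 2 else img
    parts = []
    if config.crf_branch in ("skeleton", "both"):
        parts.append(crf_loss(skel_t, img_b, config))
    if config.crf_branch in ("lesion", "both"):
        from .autodiff import concat

        p = lesion_t if lesion_t.data.ndim == 4 else lesion_t.reshape(1, 1, *lesion_t.shape[-2:])
        two = concat([1.0 - p, p], axis=1)
        parts.append(crf_loss(two, img_b, config))
    term_crf = parts[0] if len(parts) == 1 else parts[0] + parts[1]

    total = w1 * term_bce + w2 * term_seg + w3 * term_crf
    terms = {
        "wbce": float(term_bce),
        "ce" if mode == "supervised" else "pce": float(term_seg),
        "crf": float(term_crf),
        "total": float(total),
    }
    return total, terms
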