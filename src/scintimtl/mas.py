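"""Multi-atlas segmentation (MAS) and the guidance products derived from it.

Labeled atlases are registered to a target scan (affine initialization, then
a deformable demons stage, both on intensity mean-squared error), their label
maps are propagated through the recovered deformation, and a per-pixel
majority vote fuses them into a pseudo ground truth. Two by-products feed the
network: the *annotation mask* (pixels where enough atlases agree, used by
the partial cross-entropy loss) and the *Gaussian guidance map* (smoothed
one-hot encoding of the fused labels, consumed by the CSGM).

A deformation field is a float array of shape (2, H, W) holding per-pixel
(row, col) displacements in pixels; warping pulls: out(x) = moving(x + d(x)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filters import smooth_3x3
from .readwrite import LabelSchema, ScintiImage

logger = logging.getLogger(__name__)

__all__ = [
    "Atlas",
    "MasResult",
    "RegistrationParams",
    "register_pair",
    "warp_labels",
    "warp_image",
    "fuse_labels",
    "run_mas",
    "gaussian_guidance_map",
    "guidance_from_labels",
]


@dataclass
class Atlas:
    """A labeled scan used as registration source."""

    image: ScintiImage
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.image.pixels.shape != self.labels.shape:
            raise ValueError("atlas image and labels must share shape")


@dataclass
class MasResult:
    """Fused pseudo ground truth plus per-pixel consensus information."""

    fused_labels: np.ndarray
    vote_fraction: np.ndarray
    annotation_mask: np.ndarray
    consensus_threshold: float = 0.6


@dataclass
class RegistrationParams:
    """Knobs of the affine + demons recipe (all in pixel/intensity units)."""

    affine_iterations: int = 100
    affine_shrink: tuple[int, ...] = (4, 2)
    demons_iterations: int = 40
    demons_smoothing: float = 2.0   # field smoothing sigma, pixels
    intensity_smoothing: float = 1.0  # pre-smoothing against count noise


def _prep(pixels: np.ndarray, sigma: float) -> np.ndarray:
    x = pixels.astype(np.float64)
    if sigma > 0:
        x = ndimage.gaussian_filter(x, sigma)
    return (x / max(x.max(), 1.0)).astype(np.float32)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))


def register_pair(
    fixed: ScintiImage, moving: ScintiImage, params: RegistrationParams | None = None
) -> np.ndarray:
    """Recover the deformation mapping ``moving`` toward ``fixed``.

    Returns a (2, H, W) displacement field. If the recipe fails to improve the
    mean-squared intensity difference relative to the identity field, the
    best field found so far (possibly identity) is returned with a warning —
    never a silent failure.
    """
    import SimpleITK as sitk

    params = params or RegistrationParams()
    if fixed.pixels.shape != moving.pixels.shape:
        raise ValueError("fixed and moving must share shape")
    h, w = fixed.pixels.shape
    f_arr = _prep(fixed.pixels, params.intensity_smoothing)
    m_arr = _prep(moving.pixels, params.intensity_smoothing)
    f_img = sitk.GetImageFromArray(f_arr)
    m_img = sitk.GetImageFromArray(m_arr)

    candidates: list[tuple[float, np.ndarray]] = []
    identity = np.zeros((2, h, w))
    candidates.append((_mse(f_arr, m_arr), identity))

    try:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=params.affine_iterations
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        init = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.AffineTransform(2), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
        reg.SetInitialTransform(init, inPlace=True)
        shrink = list(params.affine_shrink) + [1]
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel([s for s in shrink])
        affine = reg.Execute(f_img, m_img)

        m_aff = sitk.Resample(m_img, f_img, affine, sitk.sitkLinear, 0.0)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(params.demons_iterations)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(params.demons_smoothing)
        disp = demons.Execute(f_img, m_aff)

        composite = sitk.CompositeTransform(2)
        composite.AddTransform(sitk.AffineTransform(affine))
        composite.AddTransform(sitk.DisplacementFieldTransform(sitk.Image(disp)))

        for tf in (composite, affine):
            dense = sitk.TransformToDisplacementField(
                tf, sitk.sitkVectorFloat64, f_img.GetSize(), f_img.GetOrigin(),
                f_img.GetSpacing(), f_img.GetDirection(),
            )
            u = sitk.GetArrayFromImage(dense)  # (H, W, 2) with (x=col, y=row)
            fld = np.stack([u[..., 1], u[..., 0]])
            warped = warp_image(m_arr, fld)
            candidates.append((_mse(f_arr, warped), fld))
    except RuntimeError as err:  # ITK optimizer failures
        logger.warning("registration did not converge cleanly: %s", err)

    best_mse, best_field = min(candidates, key=lambda c: c[0])
    if best_field is identity and len(candidates) > 1 and best_mse > 0:
        logger.warning(
            "registration failed to improve MSE (%.3g); returning identity field", best_mse
        )
    return best_field


def warp_image(pixels: np.ndarray, fld: np.ndarray) -> np.ndarray:
    """Bilinear pull-warp of an intensity image."""
    h, w = pixels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ndimage.map_coordinates(
        pixels.astype(np.float64), np.stack([yy + fld[0], xx + fld[1]]), order=1, cval=0.0
    )


def warp_labels(labels: np.ndarray, fld: np.ndarray) -> np.ndarray:
    """Nearest-neighbor label propagation through a deformation field."""
    if labels.shape != fld.shape[1:]:
        raise ValueError(f"labels {labels.shape} vs field {fld.shape[1:]}")
    h, w = labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ndimage.map_coordinates(
        labels, np.stack([yy + fld[0], xx + fld[1]]), order=0, cval=0
    ).astype(labels.dtype)


def fuse_labels(warped: list[np.ndarray], consensus_threshold: float = 0.6) -> MasResult:
    """Per-pixel majority vote; ties break toward the smallest label id."""
    if len(warped) == 0:
        raise ValueError("need at least one warped label map to fuse")
    stack = np.stack(warped)
    if not all(m.shape == warped[0].shape for m in warped):
        raise ValueError("all label maps must share shape")
    k = stack.shape[0]
    n_labels = int(stack.max()) + 1
    counts = np.zeros((n_labels,) + warped[0].shape, dtype=np.int32)
    for lab in range(n_labels):
        counts[lab] = (stack == lab).sum(axis=0)
    fused = counts.argmax(axis=0).astype(warped[0].dtype)  # argmax -> smallest id on ties
    vote_fraction = counts.max(axis=0) / float(k)
    annotation_mask = (vote_fraction >= consensus_threshold).astype(np.uint8)
    return MasResult(fused, vote_fraction, annotation_mask, consensus_threshold)


def run_mas(
    target: ScintiImage,
    atlases: list[Atlas],
    k: int = 5,
    params: RegistrationParams | None = None,
    consensus_threshold: float = 0.6,
) -> MasResult:
    """Register the first ``k`` atlases to ``target``, propagate and fuse.

    Deterministic for fixed registration parameters and atlas order. The
    annotation mask marks pixels whose vote fraction reaches the consensus
    threshold; those are the pixels the partial cross-entropy trusts.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > len(atlases):
        raise ValueError(f"k={k} exceeds the {len(atlases)} available atlases")
    warped = []
    for atlas in atlases[:k]:
        fld = register_pair(target, atlas.image, params)
        warped.append(warp_labels(atlas.labels, fld))
    return fuse_labels(warped, consensus_threshold)


def guidance_from_labels(labels: np.ndarray, n_channels: int, sigma: float = 1.0) -> np.ndarray:
    """One-hot encode a label patch into ``n_channels`` planes and smooth each
    with the normalized 3x3 Gaussian. Channel values lie in [0, 1] and sum to
    1 at every pixel (partition of unity is preserved by the smoothing)."""
    labels = np.asarray(labels)
    onehot = (labels[None] == np.arange(n_channels).reshape(-1, 1, 1)).astype(np.float64)
    return smooth_3x3(onehot, sigma=sigma)


def save_mas_result(result: MasResult, schema: LabelSchema, prefix) -> None:
    """Write fused labels + vote fraction + annotation mask next to ``prefix``."""
    from .readwrite import write_image, write_label_map

    write_label_map(result.fused_labels, schema, f"{prefix}_fused.png")
    write_image(np.round(result.vote_fraction * 65535).astype(np.uint16), f"{prefix}_votes.png")
    write_image(result.annotation_mask.astype(np.uint16), f"{prefix}_mask.png")


def load_mas_result(prefix, consensus_threshold: float = 0.6) -> MasResult:
    from .readwrite import read_image, read_label_map

    fused, _ = read_label_map(f"{prefix}_fused.png")
    votes = read_image(f"{prefix}_votes.png").astype(np.float64) / 65535.0
    mask = read_image(f"{prefix}_mask.png").astype(np.uint8)
    return MasResult(fused, votes, mask, consensus_threshold)


def gaussian_guidance_map(mas_patch: np.ndarray, schema: LabelSchema, sigma: float = 1.0) -> np.ndarray:
    """Guidance map for a MAS result patch under a label schema (C+1 channels)."""
    present = set(np.unique(mas_patch).tolist()) - {0}
    unknown = sorted(present - set(schema.labels))
    if unknown:
        raise ValueError(f"patch labels not in schema: {unknown}")
    return guidance_from_labels(mas_patch, schema.n_classes + 1, sigma=sigma)
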