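"""Synthetic whole-body bone-scan phantoms.

Real planar bone scans cannot be redistributed, so every stage of the
pipeline is exercised on parametric phantoms that reproduce the features the
method depends on: a body-shaped low-uptake soft-tissue background, a
piecewise "stick body" skeleton whose parts carry distinct anatomical labels,
bright isotropic Gaussian hot spots confined to bone, Poisson count noise,
and smooth random deformations that stand in for inter-subject variability
(and thus provide atlases for the multi-atlas stage).

The skeleton template places nine base parts (skull, spine, paired rib
plates, pelvis, paired arms and legs) and then repeatedly splits the largest
part along its longer axis until the requested number of labels exists, so
every region stays contiguous.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .readwrite import (
    LabelSchema,
    ScintiImage,
    write_image,
    write_label_map,
    write_manifest,
)

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "deform_phantom",
    "warp_sample",
    "random_displacement_field",
    "generate_cohort",
    "cohort_checksum",
    "skeleton_template",
    "MIN_REGIONS",
]

MIN_REGIONS = 9  # the base stick-body parts; fewer would leave unlabeled bone


@dataclass
class PhantomConfig:
    """Generation parameters; intensities are mean gamma counts per pixel."""

    height: int = 512
    width: int = 128
    n_regions: int = 20
    bone_intensity: float = 40.0
    soft_tissue_intensity: float = 10.0
    lesion_count_range: tuple[int, int] = (1, 6)
    lesion_amplitude_range: tuple[float, float] = (30.0, 120.0)
    lesion_sigma_range: tuple[float, float] = (1.5, 4.0)
    deformation_amplitude: float = 3.0
    deformation_scale: float = 24.0
    poisson_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (self.bone_intensity > self.soft_tissue_intensity > 0):
            raise ValueError("need bone_intensity > soft_tissue_intensity > 0")
        if self.n_regions < MIN_REGIONS:
            raise ValueError(
                f"n_regions must be >= {MIN_REGIONS} (the base skeleton parts), got {self.n_regions}"
            )
        if self.lesion_count_range[0] > self.lesion_count_range[1]:
            raise ValueError("bad lesion_count_range")
        if self.bone_intensity + self.lesion_amplitude_range[1] > 65535:
            raise ValueError("intensities exceed the 16-bit range")


@dataclass
class PhantomSample:
    """One generated study: counts image + both ground-truth targets."""

    image: ScintiImage
    lesion_mask: np.ndarray
    skeleton_labels: np.ndarray
    schema: LabelSchema
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "PhantomSample":
        return PhantomSample(
            image=ScintiImage(self.image.pixels.copy(), self.image.view, self.image.id),
            lesion_mask=self.lesion_mask.copy(),
            skeleton_labels=self.skeleton_labels.copy(),
            schema=self.schema,
            metadata=copy.deepcopy(self.metadata),
        )


# ----------------------------------------------------------------- template
def _ellipse(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _bar(h, w, r0, r1, c0, c1):
    m = np.zeros((h, w), dtype=bool)
    m[int(r0 * h) : int(r1 * h), int(c0 * w) : int(c1 * w)] = True
    return m


def _base_parts(h: int, w: int) -> list[tuple[str, np.ndarray]]:
    """Nine contiguous stick-body parts in drawing order (later excludes earlier)."""
    parts = [
        ("skull", _ellipse(h, w, 0.06 * h, 0.50 * w, 0.045 * h, 0.11 * w)),
        ("spine", _bar(h, w, 0.115, 0.56, 0.46, 0.55)),
        ("ribs_left", _bar(h, w, 0.16, 0.40, 0.26, 0.46)),
        ("ribs_right", _bar(h, w, 0.16, 0.40, 0.55, 0.74)),
        ("pelvis", _ellipse(h, w, 0.60 * h, 0.50 * w, 0.055 * h, 0.17 * w)),
        ("arm_left", _bar(h, w, 0.14, 0.52, 0.10, 0.17)),
        ("arm_right", _bar(h, w, 0.14, 0.52, 0.83, 0.90)),
        ("leg_left", _bar(h, w, 0.655, 0.97, 0.36, 0.46)),
        ("leg_right", _bar(h, w, 0.655, 0.97, 0.54, 0.64)),
    ]
    taken = np.zeros((h, w), dtype=bool)
    out = []
    for name, m in parts:
        m = m & ~taken
        taken |= m
        out.append((name, m))
    return out


def _split_part(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Split a part into two contiguous halves across its longer bbox axis."""
    ys, xs = np.nonzero(mask)
    if ys.size < 8:
        return None
    span_y = ys.max() - ys.min()
    span_x = xs.max() - xs.min()
    coord = ys if span_y >= span_x else xs
    cut = int(np.median(coord))
    if span_y >= span_x:
        a = mask.copy()
        a[cut + 1 :, :] = False
        b = mask & ~a
    else:
        a = mask.copy()
        a[:, cut + 1 :] = False
        b = mask & ~a
    if not a.any() or not b.any():
        return None
    return a, b


def skeleton_template(height: int, width: int, n_regions: int) -> tuple[np.ndarray, LabelSchema]:
    """Labeled stick-body skeleton with exactly ``n_regions`` contiguous parts."""
    named = _base_parts(height, width)
    parts = [(f"{name}", m) for name, m in named]
    if n_regions < len(parts):
        raise ValueError(f"n_regions must be >= {len(parts)}")
    while len(parts) < n_regions:
        # split the largest part; deterministic tie-break by list order
        sizes = [m.sum() for _, m in parts]
        order = int(np.argmax(sizes))
        split = _split_part(parts[order][1])
        if split is None:
            raise ValueError(
                f"cannot place {n_regions} regions on a {height}x{width} template; "
                f"limit here is {len(parts)}"
            )
        name, _ = parts[order]
        a, b = split
        parts[order : order + 1] = [(f"{name}_a", a), (f"{name}_b", b)]
    labels = np.zeros((height, width), dtype=np.int32)
    names = []
    for i, (name, m) in enumerate(parts, start=1):
        labels[m] = i
        names.append(name)
    schema = LabelSchema.generic(n_regions, view="anterior", names=names)
    return labels, schema


def _body_mask(skeleton: np.ndarray) -> np.ndarray:
    r = max(2, skeleton.shape[1] // 16)
    return ndimage.binary_dilation(skeleton > 0, iterations=r)


# ---------------------------------------------------------------- generation
def generate_phantom(config: PhantomConfig, seed: int | None = None) -> PhantomSample:
    """Draw one phantom study, deterministic in (config, seed).

    The noiseless base map is soft-tissue counts over the body silhouette and
    bone counts over the skeleton; hot spots add isotropic Gaussian blobs
    whose half-maximum footprint defines the lesion ground truth. With
    ``poisson_noise`` on, the stored image is a Poisson draw of the base map.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.height, config.width
    skeleton, schema = skeleton_template(h, w, config.n_regions)
    body = _body_mask(skeleton)
    base = np.where(body, config.soft_tissue_intensity, 0.0)
    base = np.where(skeleton > 0, config.bone_intensity, base)

    n_lesions = int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
    lesion_mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    drawn = []
    placed: list[tuple[float, float, float]] = []  # (cy, cx, half_max_radius)
    bone = skeleton > 0
    for _ in range(n_lesions):
        amp = float(rng.uniform(*config.lesion_amplitude_range))
        sig = float(rng.uniform(*config.lesion_sigma_range))
        r_half = sig * np.sqrt(2.0 * np.log(2.0))
        # centers where the half-maximum disk fits inside bone, away from
        # previous lesions so ground-truth components stay separable
        interior = ndimage.binary_erosion(bone, iterations=max(1, int(np.ceil(r_half))))
        cand_y, cand_x = np.nonzero(interior if interior.any() else bone)
        ok = None
        for _try in range(200):
            j = int(rng.integers(cand_y.size))
            cy, cx = float(cand_y[j]), float(cand_x[j])
            if all(np.hypot(cy - py, cx - px) > r_half + pr + 2 for py, px, pr in placed):
                ok = (cy, cx)
                break
        if ok is None:
            continue
        cy, cx = ok
        placed.append((cy, cx, r_half))
        blob = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig**2))
        base = base + blob
        lesion_mask |= blob >= amp / 2.0
        drawn.append({"cy": cy, "cx": cx, "amplitude": amp, "sigma": sig})
    lesion_mask &= bone  # lesions lie on bone by construction

    if config.poisson_noise:
        image = rng.poisson(base).astype(np.float64)
    else:
        image = base
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    sid = f"phantom_{(config.seed if seed is None else seed):06d}"
    meta = {"config": asdict(config), "seed": int(config.seed if seed is None else seed),
            "lesions": drawn}
    return PhantomSample(
        image=ScintiImage(image, view="anterior", id=sid),
        lesion_mask=lesion_mask,
        skeleton_labels=skeleton,
        schema=schema,
        metadata=meta,
    )


# --------------------------------------------------------------- deformation
def random_displacement_field(
    shape: tuple[int, int], amplitude: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field (2, H, W): low-res Gaussian noise, cubic-upsampled."""
    h, w = shape
    gh = max(2, int(np.ceil(h / scale)) + 1)
    gw = max(2, int(np.ceil(w / scale)) + 1)
    coarse = rng.normal(0.0, amplitude, size=(2, gh, gw))
    field = np.empty((2, h, w))
    for k in range(2):
        field[k] = ndimage.zoom(coarse[k], (h / gh, w / gw), order=3, mode="nearest")[:h, :w]
    return field


def warp_sample(sample: PhantomSample, field: np.ndarray) -> PhantomSample:
    """Warp image/mask/labels by one shared field; out(x) = in(x + d(x)).

    Intensities are interpolated bilinearly, label maps and masks by nearest
    neighbor; samples pulled from outside the grid become background.
    """
    h, w = sample.image.pixels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([yy + field[0], xx + field[1]])
    img = ndimage.map_coordinates(sample.image.pixels.astype(np.float64), coords, order=1, cval=0.0)
    mask = ndimage.map_coordinates(sample.lesion_mask.astype(np.uint8), coords, order=0, cval=0)
    labels = ndimage.map_coordinates(sample.skeleton_labels, coords, order=0, cval=0)
    out = sample.copy()
    out.image = ScintiImage(
        np.clip(np.round(img), 0, 65535).astype(np.uint16), sample.image.view, sample.image.id + "_warp"
    )
    out.lesion_mask = mask.astype(bool)
    out.skeleton_labels = labels.astype(sample.skeleton_labels.dtype)
    return out


def deform_phantom(
    sample: PhantomSample, amplitude: float, scale: float, seed: int
) -> PhantomSample:
    """Apply a random smooth deformation; amplitude 0 returns an exact copy."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return sample.copy()
    rng = np.random.default_rng(seed)
    field = random_displacement_field(sample.image.pixels.shape, amplitude, scale, rng)
    out = warp_sample(sample, field)
    out.metadata["deformation"] = {"amplitude": amplitude, "scale": scale, "seed": seed}
    return out


# -------------------------------------------------------------------- cohort
def generate_cohort(
    n: int,
    config: PhantomConfig,
    labeled_fraction: float,
    seed: int,
    out_dir,
    overwrite: bool = False,
    val_fraction: float = 0.15,
    test_fraction: float = 0.2,
) -> list[dict]:
    """Write ``n`` phantom studies + manifest, emulating the clinical regime:
    every study carries a lesion mask, only ``labeled_fraction`` of them also
    carry skeleton labels. Labeled status is granted to validation and test
    studies first (they need ground truth for evaluation), then to training
    studies in draw order. Returns the manifest rows.
    """
    if not 0 < labeled_fraction <= 1:
        raise ValueError("labeled_fraction must be in (0, 1]")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    n_test = int(round(n * test_fraction))
    n_val = int(round(n * val_fraction))
    roles = ["test"] * n_test + ["val"] * n_val + ["train"] * (n - n_test - n_val)
    n_labeled = int(round(n * labeled_fraction))
    priority = sorted(range(n), key=lambda i: (roles[i] == "train", i))
    labeled = set(priority[:n_labeled])

    rows = []
    for i in range(n):
        sample = generate_phantom(config, seed=int(rng.integers(2**31 - 1)))
        sid = f"s{i:04d}"
        img_path = out / f"{sid}_image.png"
        les_path = out / f"{sid}_lesion.png"
        write_image(sample.image.pixels, img_path)
        write_image(sample.lesion_mask.astype(np.uint16), les_path)
        row = {
            "id": sid,
            "view": sample.image.view,
            "role": roles[i],
            "labeled_skeleton": i in labeled,
            "image": img_path.name,
            "lesion_mask": les_path.name,
            "skeleton_labels": "",
        }
        if i in labeled:
            skel_path = out / f"{sid}_skeleton.png"
            write_label_map(sample.skeleton_labels, sample.schema, skel_path)
            row["skeleton_labels"] = skel_path.name
        rows.append(row)
    write_manifest(rows, out / "manifest.csv")
    if n > 0:
        sample.schema.to_json(out / "schema.json")
    return rows


def cohort_checksum(out_dir) -> str:
    """SHA-256 over every file in a cohort directory (determinism checks)."""
    h = hashlib.sha256()
    for f in sorted(Path(out_dir).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()
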