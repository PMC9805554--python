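"""Image, label-map and manifest I/O plus the anatomical label schema.

Conventions fixed here once: arrays are row-major, 0-based, origin at the
top-left; planar views are stored as 16-bit grayscale (PNG, or single-frame
secondary-capture DICOM); anterior and posterior views are processed
separately in their native orientation (no mirroring). A whole-body study is
either a directory with one file per view or a single DICOM frame holding the
two views side by side, split at a configurable midline.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ScintiImage",
    "LabelSchema",
    "read_study",
    "read_image",
    "write_image",
    "write_dicom",
    "read_dicom",
    "write_label_map",
    "read_label_map",
    "write_manifest",
    "read_manifest",
]

VIEWS = ("anterior", "posterior")


@dataclass
class ScintiImage:
    """One planar gamma-camera view: nonnegative 16-bit counts + view tag."""

    pixels: np.ndarray
    view: str = "anterior"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D pixel grid, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise ValueError("pixel values must lie in the 16-bit range [0, 65535]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# Structured names for the full-scale presets. Each (stem, count) pair expands
# to numbered regions; counts are chosen so the anterior preset has exactly 56
# foreground labels and the posterior 68, the granularity used for whole-body
# reporting.
_ANTERIOR_PLAN = [
    ("skull", 1), ("cervical_vertebra", 3), ("thoracic_vertebra", 5),
    ("lumbar_vertebra", 5), ("sacrum", 1), ("sternum", 1),
    ("clavicle_left", 1), ("clavicle_right", 1),
    ("rib_left", 8), ("rib_right", 8),
    ("scapula_left", 1), ("scapula_right", 1),
    ("humerus_left", 2), ("humerus_right", 2),
    ("forearm_left", 2), ("forearm_right", 2),
    ("pelvis_left", 1), ("pelvis_right", 1),
    ("femur_left", 2), ("femur_right", 2),
    ("knee_left", 1), ("knee_right", 1),
    ("tibia_left", 1), ("tibia_right", 1),
    ("ankle_left", 1), ("ankle_right", 1),
]
_POSTERIOR_PLAN = [
    ("skull", 1), ("cervical_vertebra", 3), ("thoracic_vertebra", 12),
    ("lumbar_vertebra", 5), ("sacrum", 1),
    ("clavicle_left", 1), ("clavicle_right", 1),
    ("rib_left", 10), ("rib_right", 10),
    ("scapula_left", 1), ("scapula_right", 1),
    ("humerus_left", 2), ("humerus_right", 2),
    ("forearm_left", 2), ("forearm_right", 2),
    ("pelvis_left", 1), ("pelvis_right", 1),
    ("femur_left", 3), ("femur_right", 3),
    ("knee_left", 1), ("knee_right", 1),
    ("tibia_left", 1), ("tibia_right", 1),
    ("ankle_left", 1), ("ankle_right", 1),
]


def _expand(plan) -> list[str]:
    names = []
    for stem, count in plan:
        if count == 1:
            names.append(stem)
        else:
            names.extend(f"{stem}_{i + 1}" for i in range(count))
    return names


@dataclass
class LabelSchema:
    """Ordered map label id -> region name; label 0 is always background."""

    view: str = "anterior"
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 0 in self.labels:
            raise ValueError("label 0 is reserved for background")

    @property
    def n_classes(self) -> int:
        """Number of foreground anatomical regions C."""
        return len(self.labels)

    def hash(self) -> str:
        payload = json.dumps({"view": self.view, "labels": self.labels}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def preset(cls, view: str) -> "LabelSchema":
        """Full-scale preset: 56 anterior / 68 posterior foreground regions."""
        plan = _ANTERIOR_PLAN if view == "anterior" else _POSTERIOR_PLAN
        names = _expand(plan)
        return cls(view=view, labels={i + 1: n for i, n in enumerate(names)})

    @classmethod
    def generic(cls, n_regions: int, view: str = "anterior", names=None) -> "LabelSchema":
        if names is None:
            names = [f"region_{i + 1:02d}" for i in range(n_regions)]
        return cls(view=view, labels={i + 1: n for i, n in enumerate(names)})

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"view": self.view, "labels": {str(k): v for k, v in self.labels.items()}},
                       indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "LabelSchema":
        d = json.loads(Path(path).read_text())
        return cls(view=d["view"], labels={int(k): v for k, v in d["labels"].items()})


# --------------------------------------------------------------------- images
def write_image(pixels: np.ndarray, path) -> None:
    """Write a 2D array as 16-bit grayscale PNG (lossless)."""
    arr = np.asarray(pixels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("values out of 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.array(im)
    if arr.dtype != np.uint16:
        warnings.warn(f"{path}: bit depth is {arr.dtype}, widening to 16-bit")
        arr = arr.astype(np.uint16)
    return arr


def write_dicom(image: ScintiImage, path) -> None:
    """Minimal single-frame 16-bit secondary-capture DICOM."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.PatientID = image.id or "phantom"
    ds.ViewPosition = "AP" if image.view == "anterior" else "PA"
    ds.SeriesDescription = image.view
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = image.pixels.astype("<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom(path) -> ScintiImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if ds.get("BitsAllocated", 16) != 16:
        warnings.warn(f"{path}: bit depth {ds.BitsAllocated}, widening to 16-bit")
    view = "anterior"
    vp = str(ds.get("ViewPosition", "") or ds.get("SeriesDescription", ""))
    if vp.upper() in ("PA", "POSTERIOR") or "posterior" in vp.lower():
        view = "posterior"
    return ScintiImage(arr.astype(np.uint16), view=view, id=str(ds.get("PatientID", "")))


def read_study(path, midline: int | None = None) -> tuple[ScintiImage, ScintiImage]:
    """Read one whole-body study; returns (anterior, posterior).

    ``path`` may be a directory holding one PNG/DICOM per view (file names
    containing ``anterior``/``posterior``), or a single DICOM whose frame
    holds both views side by side, split at ``midline`` (default: half the
    width). Pixel data are returned unmodified (no rescale).
    """
    p = Path(path)
    if p.is_dir():
        found: dict[str, ScintiImage] = {}
        for f in sorted(p.iterdir()):
            low = f.name.lower()
            for view in VIEWS:
                if view in low:
                    if f.suffix.lower() == ".png":
                        found[view] = ScintiImage(read_image(f), view=view, id=p.name)
                    elif f.suffix.lower() in (".dcm", ".dicom"):
                        img = read_dicom(f)
                        found[view] = ScintiImage(img.pixels, view=view, id=p.name)
        for view in VIEWS:
            if view not in found:
                raise ValueError(f"{view} view missing in study {p}")
        return found["anterior"], found["posterior"]
    # single file: both views in one frame, split on the midline
    img = read_dicom(p) if p.suffix.lower() in (".dcm", ".dicom") else ScintiImage(read_image(p), id=p.stem)
    w = img.pixels.shape[1]
    mid = w // 2 if midline is None else midline
    if mid <= 0 or mid >= w:
        raise ValueError(f"midline {mid} outside image width {w}")
    ant = ScintiImage(img.pixels[:, :mid], view="anterior", id=img.id)
    post = ScintiImage(img.pixels[:, mid:], view="posterior", id=img.id)
    return ant, post


# ----------------------------------------------------------------- label maps
def write_label_map(label_map: np.ndarray, schema: LabelSchema, path) -> None:
    """16-bit PNG + sidecar JSON schema; lossless round-trip."""
    arr = np.asarray(label_map)
    present = set(np.unique(arr).tolist()) - {0}
    unknown = sorted(present - set(schema.labels))
    if unknown:
        raise ValueError(f"labels not in schema: {unknown}")
    write_image(arr, path)
    schema.to_json(str(path) + ".json")


def read_label_map(path) -> tuple[np.ndarray, LabelSchema]:
    arr = read_image(path).astype(np.int32)
    schema = LabelSchema.from_json(str(path) + ".json")
    return arr, schema


# ------------------------------------------------------------------ manifests
MANIFEST_COLUMNS = ["id", "view", "role", "labeled_skeleton", "image", "lesion_mask", "skeleton_labels"]


def write_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=MANIFEST_COLUMNS)
        w.writeheader()
        for r in rows:
            w.writerow({k: r.get(k, "") for k in MANIFEST_COLUMNS})


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as f:
        rows = list(csv.DictReader(f))
    for r in rows:
        r["labeled_skeleton"] = r["labeled_skeleton"] in ("True", "true", "1")
    return rows
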