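"""Whole-image tiled inference and the evaluation metrics.

Metrics follow the conventions of planar bone-scan reading: Dice similarity
(DSC) for overlap, its mean over anatomical classes (mDSC) for the skeleton
task, and lesion-count precision/recall where a ground-truth hot spot counts
as detected if any predicted component overlaps it (greedy one-to-one
matching by overlap area; an IoU-threshold variant sits behind a flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mas import MasResult, guidance_from_labels
from .readwrite import LabelSchema, ScintiImage

__all__ = [
    "DetectionCounts",
    "EvalReport",
    "dsc",
    "mdsc",
    "lesion_detection_metrics",
    "segment_whole_image",
    "evaluate",
]

EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity for components


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); both-empty counts as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    s = int(a.sum()) + int(b.sum())
    if s == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / s


def mdsc(pred: np.ndarray, truth: np.ndarray, schema: LabelSchema | int) -> float:
    """Mean per-class DSC over foreground classes present in the truth.

    Classes absent from both maps are excluded rather than scored 0; an
    all-background truth is an error (there is nothing to average).
    """
    n = schema.n_classes if isinstance(schema, LabelSchema) else int(schema)
    present = [c for c in range(1, n + 1) if (truth == c).any()]
    if not present:
        raise ValueError("truth contains no foreground class")
    return float(np.mean([dsc(pred == c, truth == c) for c in present]))


@dataclass
class DetectionCounts:
    tp: int
    n_pred: int
    n_truth: int

    @property
    def precision(self) -> float | None:
        return None if self.n_pred == 0 else self.tp / self.n_pred

    @property
    def recall(self) -> float | None:
        return None if self.n_truth == 0 else self.tp / self.n_truth

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.n_pred + other.n_pred,
                               self.n_truth + other.n_truth)


def lesion_detection_metrics(
    pred: np.ndarray, truth: np.ndarray, min_iou: float = 0.0
) -> DetectionCounts:
    """Count detected lesions by greedy one-to-one component matching.

    Components are 8-connected. Predicted components are matched to truth
    components in descending order of overlap area, each side used at most
    once; a pair matches when its overlap is positive (``min_iou == 0``) or
    its IoU reaches ``min_iou``.
    """
    pred_lab, n_pred = ndimage.label(np.asarray(pred, dtype=bool), structure=EIGHT)
    truth_lab, n_truth = ndimage.label(np.asarray(truth, dtype=bool), structure=EIGHT)
    pairs = []
    for p in range(1, n_pred + 1):
        pm = pred_lab == p
        hit = np.unique(truth_lab[pm])
        for t in hit[hit > 0]:
            tm = truth_lab == t
            inter = int((pm & tm).sum())
            iou = inter / int((pm | tm).sum())
            if inter > 0 and iou >= min_iou:
                pairs.append((inter, p, int(t)))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, p, t in pairs:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        tp += 1
    return DetectionCounts(tp=tp, n_pred=n_pred, n_truth=n_truth)


def segment_whole_image(
    image: ScintiImage,
    model,
    mas_result: MasResult,
    patch_size: int = 128,
    stride: int | None = None,
    normalization: str = "max",
    batch_tiles: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile the scan, average per-pixel probabilities across overlapping
    tiles, then threshold (lesion, 0.5) and argmax (skeleton).

    Deterministic: tiles are visited in raster order and the model has no
    stochastic layers.
    """
    h, w = image.pixels.shape
    s = patch_size
    if h < s or w < s:
        raise ValueError(f"image {h}x{w} smaller than patch {s}")
    stride = stride or s // 2
    rows = sorted({*range(0, h - s + 1, stride), h - s})
    cols = sorted({*range(0, w - s + 1, stride), w - s})
    img = image.pixels.astype(np.float64)
    img = img / max(float(img.max()), 1.0) if normalization == "max" else np.clip(img / 255.0, 0, 1)
    nc = model.config.n_skeleton_classes
    lesion_sum = np.zeros((h, w))
    skel_sum = np.zeros((nc, h, w))
    count = np.zeros((h, w))
    tiles = [(r, c) for r in rows for c in cols]
    for i in range(0, len(tiles), batch_tiles):
        chunk = tiles[i : i + batch_tiles]
        imgs = np.stack([img[r : r + s, c : c + s] for r, c in chunk])[:, None]
        guid = None
        if model.config.use_csgm:
            guid = np.stack([
                guidance_from_labels(mas_result.fused_labels[r : r + s, c : c + s], nc,
                                     sigma=model.config.csgm_sigma)
                for r, c in chunk
            ])
        out = model.forward_batch(imgs.astype(np.float32), guid)
        for j, (r, c) in enumerate(chunk):
            lesion_sum[r : r + s, c : c + s] += out.lesion_prob[j, 0]
            skel_sum[:, r : r + s, c : c + s] += out.skeleton_prob[j]
            count[r : r + s, c : c + s] += 1.0
    lesion_prob = lesion_sum / count
    skel_prob = skel_sum / count
    return lesion_prob >= 0.5, skel_prob.argmax(axis=0).astype(np.int32)


@dataclass
class EvalReport:
    """Aggregate + per-image metrics for one dataset split."""

    lesion_mdsc: float
    lesion_counts: DetectionCounts
    skeleton_mdsc: float | None
    per_image: list[dict] = field(default_factory=list)

    @property
    def lesion_precision(self) -> float | None:
        return self.lesion_counts.precision

    @property
    def lesion_recall(self) -> float | None:
        return self.lesion_counts.recall

    def summary(self) -> dict:
        c = self.lesion_counts
        return {
            "lesion_mdsc": self.lesion_mdsc,
            "lesion_precision": c.precision,
            "lesion_precision_counts": f"{c.tp}/{c.n_pred}",
            "lesion_recall": c.recall,
            "lesion_recall_counts": f"{c.tp}/{c.n_truth}",
            "skeleton_mdsc": self.skeleton_mdsc,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.summary(), indent=1))
        import csv

        if self.per_image:
            with open(out / "per_image.csv", "w", newline="") as f:
                w = csv.DictWriter(f, fieldnames=list(self.per_image[0]))
                w.writeheader()
                w.writerows(self.per_image)


def evaluate(
    samples: list,
    model,
    mas_results: list[MasResult],
    patch_size: int = 128,
    min_iou: float = 0.0,
) -> EvalReport:
    """Run tiled inference over a split and aggregate every metric.

    ``samples`` need ground truth (lesion masks always; skeleton labels where
    available). Detection counts are pooled over the split; lesion mDSC is
    the mean per-image Dice; skeleton mDSC the mean per-image class-mean Dice
    over the images that carry skeleton truth.
    """
    per_image = []
    counts = DetectionCounts(0, 0, 0)
    lesion_dscs = []
    skel_mdscs = []
    for sample, masr in zip(samples, mas_results):
        pred_lesion, pred_skel = segment_whole_image(
            sample.image, model, masr, patch_size=patch_size
        )
        d = dsc(pred_lesion, sample.lesion_mask)
        c = lesion_detection_metrics(pred_lesion, sample.lesion_mask, min_iou=min_iou)
        counts = counts + c
        lesion_dscs.append(d)
        row = {"id": sample.image.id, "lesion_dsc": d, "tp": c.tp,
               "n_pred": c.n_pred, "n_truth": c.n_truth, "skeleton_mdsc": ""}
        skel = getattr(sample, "skeleton_labels", None)
        if skel is not None and (skel > 0).any():
            m = mdsc(pred_skel, skel, model.config.n_skeleton_classes - 1)
            skel_mdscs.append(m)
            row["skeleton_mdsc"] = m
        per_image.append(row)
    return EvalReport(
        lesion_mdsc=float(np.mean(lesion_dscs)) if lesion_dscs else float("nan"),
        lesion_counts=counts,
        skeleton_mdsc=float(np.mean(skel_mdscs)) if skel_mdscs else None,
        per_image=per_image,
    )
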