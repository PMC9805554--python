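"""Semi-supervised two-phase training of the multi-task network.

Phase 1 (pseudo-label pre-training) runs on every training study: the lesion
branch is supervised by its mask (weighted BCE) while the skeleton branch
learns from multi-atlas pseudo-labels through partial cross-entropy restricted
to the atlas-consensus mask, regularized by the CRF term. Phase 2 (refinement)
continues on the small manually-labeled subset with full cross-entropy.
After every epoch, whole-image tiled inference on the validation split yields
a lesion Dice and a skeleton mDSC; the checkpoint with the highest validation
mDSC is kept.

The public surface is the scikit-learn style estimator
:class:`MultiTaskSegmenter`; :func:`train` and :func:`run_ablation` are thin
functional wrappers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Adam
from .evaluate import dsc, evaluate, mdsc, segment_whole_image
from .losses import LossConfig, ce, crf_loss, pce, wbce
from .mas import Atlas, MasResult, RegistrationParams, guidance_from_labels, run_mas
from .network import ModelConfig, MultiTaskUNet
from .phantom import PhantomSample
from .readwrite import LabelSchema, ScintiImage, read_image, read_label_map, read_manifest
from .sampling import extract_patch_pair, likelihood_map, sample_patch_centers

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "StudyRecord",
    "MultiTaskSegmenter",
    "train",
    "run_ablation",
    "load_dataset",
    "prepare_mas",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale settings)."""

    lr: float = 1e-3
    lr_decay: float = 1e-8
    batch_size: int = 100
    weight_decay: float = 1e-4
    momentum_beta: float = 0.9
    max_epochs: int = 1000
    patches_per_image: int = 100
    patch_size: int = 128
    seed: int = 0
    phase_schedule: tuple[int, int] | None = None  # (pseudo-label, refinement); default 3:1
    likelihood_sigma: float = 8.0
    background_floor: float = 0.1
    normalization: str = "max"
    # ablation switches
    patch_input: bool = True
    semi_supervised: bool = True
    csgm: bool = True
    share_encoder: bool = True

    def phases(self) -> tuple[int, int]:
        if self.phase_schedule is not None:
            return self.phase_schedule
        p1 = int(round(self.max_epochs * 0.75))
        return (p1, self.max_epochs - p1)


@dataclass
class StudyRecord:
    """One training/validation study: sample + its precomputed MAS result."""

    sample: PhantomSample
    mas: MasResult | None = None
    labeled: bool = True
    role: str = "train"


class MultiTaskSegmenter(BaseEstimator):
    """Shared-encoder dual-decoder segmenter with semi-supervised training.

    Parameters mirror :class:`ModelConfig`, :class:`TrainConfig` and
    :class:`LossConfig`; fitted state lives in trailing-underscore
    attributes (``model_``, ``history_``, ``best_epoch_`` ...). The estimator
    composes with scikit-learn tooling through ``get_params``/``set_params``;
    ``fit`` takes a list of :class:`StudyRecord` (X) and an optional
    validation list.
    """

    def __init__(
        self,
        base_width: int = 16,
        depth: int = 4,
        share_encoder: bool = True,
        use_csgm: bool = True,
        patch_input: bool = True,
        semi_supervised: bool = True,
        lr: float = 1e-3,
        lr_decay: float = 1e-8,
        weight_decay: float = 1e-4,
        momentum_beta: float = 0.9,
        batch_size: int = 100,
        max_epochs: int = 1000,
        patches_per_image: int = 100,
        patch_size: int = 128,
        phase_schedule: tuple[int, int] | None = None,
        likelihood_sigma: float = 8.0,
        background_floor: float = 0.1,
        lesion_weight: float = 5.0,
        crf_sigma_xy: float = 3.0,
        crf_sigma_int: float = 0.1,
        crf_window: int = 5,
        term_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
        normalization: str = "max",
        seed: int = 0,
    ):
        self.base_width = base_width
        self.depth = depth
        self.share_encoder = share_encoder
        self.use_csgm = use_csgm
        self.patch_input = patch_input
        self.semi_supervised = semi_supervised
        self.lr = lr
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.momentum_beta = momentum_beta
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patches_per_image = patches_per_image
        self.patch_size = patch_size
        self.phase_schedule = phase_schedule
        self.likelihood_sigma = likelihood_sigma
        self.background_floor = background_floor
        self.lesion_weight = lesion_weight
        self.crf_sigma_xy = crf_sigma_xy
        self.crf_sigma_int = crf_sigma_int
        self.crf_window = crf_window
        self.term_weights = term_weights
        self.normalization = normalization
        self.seed = seed

    # ------------------------------------------------------------- internals
    def _loss_config(self) -> LossConfig:
        return LossConfig(
            w=self.lesion_weight,
            crf_sigma_xy=self.crf_sigma_xy,
            crf_sigma_int=self.crf_sigma_int,
            crf_window=self.crf_window,
            term_weights=self.term_weights,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr, lr_decay=self.lr_decay, batch_size=self.batch_size,
            weight_decay=self.weight_decay, momentum_beta=self.momentum_beta,
            max_epochs=self.max_epochs, patches_per_image=self.patches_per_image,
            patch_size=self.patch_size, seed=self.seed,
            phase_schedule=self.phase_schedule,
            likelihood_sigma=self.likelihood_sigma,
            background_floor=self.background_floor,
            normalization=self.normalization,
            patch_input=self.patch_input, semi_supervised=self.semi_supervised,
            csgm=self.use_csgm, share_encoder=self.share_encoder,
        )

    def _draw_epoch_patches(self, records, rng, supervised_only: bool):
        """Fresh rejection-sampled patch set (resampled every epoch)."""
        cfg = self._train_config()
        pool = []
        for rec in records:
            if supervised_only and not rec.labeled:
                continue
            lm = likelihood_map(rec.sample.lesion_mask, cfg.likelihood_sigma,
                                cfg.background_floor)
            if cfg.patch_input:
                centers = sample_patch_centers(
                    lm, cfg.patches_per_image, seed=int(rng.integers(2**31 - 1)),
                    patch_size=cfg.patch_size,
                )
            else:
                # whole-image-style baseline: uniform windows over the scan
                h, w = rec.sample.image.pixels.shape
                half = cfg.patch_size // 2
                centers = [
                    (int(rng.integers(half, h - cfg.patch_size + half + 1)),
                     int(rng.integers(half, w - cfg.patch_size + half + 1)))
                    for _ in range(cfg.patches_per_image)
                ]
            for cen in centers:
                pair = extract_patch_pair(rec.sample, rec.mas, cen, cfg.patch_size,
                                          normalization=cfg.normalization)
                if not rec.labeled:
                    pair.skeleton_target = None
                pool.append(pair)
        order = rng.permutation(len(pool))
        return [pool[i] for i in order]

    def _batch_loss(self, model, pairs, supervised: bool, loss_cfg: LossConfig):
        imgs = np.stack([p.image_patch for p in pairs])[:, None].astype(np.float32)
        guid = None
        if model.config.use_csgm:
            nc = model.config.n_skeleton_classes
            guid = np.stack([
                guidance_from_labels(p.mas_patch, nc, sigma=model.config.csgm_sigma)
                for p in pairs
            ]).astype(np.float32)
        out = model.forward_batch(imgs, guid)
        y = np.stack([p.lesion_target for p in pairs])[:, None]
        w1, w2, w3 = loss_cfg.term_weights
        term_bce = wbce(out.lesion_prob_t, y, w=loss_cfg.w)
        if supervised:
            z = np.stack([p.skeleton_target for p in pairs])
            term_seg = ce(out.skeleton_prob_t, z)
        else:
            z = np.stack([p.mas_patch for p in pairs])
            m = np.stack([p.annotation_mask_patch for p in pairs])
            term_seg = pce(out.skeleton_prob_t, z, m)
        img_b = np.stack([p.image_patch for p in pairs])
        term_crf = crf_loss(out.skeleton_prob_t, img_b, loss_cfg)
        total = w1 * term_bce + w2 * term_seg + w3 * term_crf
        terms = {"wbce": float(term_bce), "seg": float(term_seg), "crf": float(term_crf)}
        return total, terms

    def _validate(self, model, val_records):
        lesion_dscs, skel_mdscs = [], []
        for rec in val_records:
            pred_lesion, pred_skel = segment_whole_image(
                rec.sample.image, model, rec.mas, patch_size=self.patch_size,
                normalization=self.normalization,
            )
            lesion_dscs.append(dsc(pred_lesion, rec.sample.lesion_mask))
            truth = rec.sample.skeleton_labels
            if rec.labeled and truth is not None and (truth > 0).any():
                skel_mdscs.append(mdsc(pred_skel, truth, model.config.n_skeleton_classes - 1))
        return (
            float(np.mean(lesion_dscs)) if lesion_dscs else float("nan"),
            float(np.mean(skel_mdscs)) if skel_mdscs else float("nan"),
        )

    # ------------------------------------------------------------------- fit
    def fit(self, X: list[StudyRecord], y=None, val_records: list[StudyRecord] | None = None):
        """Train on study records (MAS results must be precomputed).

        ``X``: training records; lesion masks are required for every record,
        skeleton labels for the ``labeled`` subset. ``val_records`` drive the
        per-epoch model selection; without them the final epoch is kept.
        """
        records = list(X)
        val_records = list(val_records or [])
        if any(r.mas is None for r in records + val_records):
            raise ValueError("every record needs a precomputed MAS result (see prepare_mas)")
        labeled = [r for r in records if r.labeled]
        cfg = self._train_config()
        loss_cfg = self._loss_config()
        loss_cfg.validate()

        n_classes = 0
        for r in records + val_records:
            n_classes = max(n_classes, int(r.mas.fused_labels.max()))
            if r.labeled and r.sample.skeleton_labels is not None:
                n_classes = max(n_classes, int(r.sample.skeleton_labels.max()))
        schema = getattr(records[0].sample, "schema", None)
        if schema is not None:
            n_classes = max(n_classes, schema.n_classes)

        model = MultiTaskUNet(ModelConfig(
            base_width=self.base_width, depth=self.depth,
            n_skeleton_classes=n_classes + 1,
            share_encoder=self.share_encoder, use_csgm=self.use_csgm,
            seed=self.seed,
        ))
        opt = Adam(model.parameters(), lr=cfg.lr, lr_decay=cfg.lr_decay,
                   momentum=cfg.momentum_beta, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 1)

        p1, p2 = cfg.phases()
        if not cfg.semi_supervised:
            p1, p2 = 0, cfg.max_epochs
        if p2 > 0 and not labeled:
            raise ValueError("refinement phase requested but no labeled study available")

        history: list[dict] = []
        best = {"epoch": -1, "mdsc": -np.inf, "state": None}
        aborted = False
        for epoch in range(p1 + p2):
            supervised = epoch >= p1
            pool = self._draw_epoch_patches(
                labeled if supervised else records, rng, supervised_only=supervised
            )
            epoch_terms = {"wbce": 0.0, "seg": 0.0, "crf": 0.0}
            n_batches = 0
            for i in range(0, len(pool), cfg.batch_size):
                batch = pool[i : i + cfg.batch_size]
                total, terms = self._batch_loss(model, batch, supervised, loss_cfg)
                if not np.isfinite(float(total)):
                    logger.error("NaN/inf loss at epoch %d; aborting with last-good checkpoint", epoch)
                    aborted = True
                    break
                opt.zero_grad()
                total.backward()
                opt.step()
                for k in epoch_terms:
                    epoch_terms[k] += terms[k]
                n_batches += 1
            if aborted:
                break
            val_dsc, val_mdsc = self._validate(model, val_records) if val_records else (np.nan, np.nan)
            row = {
                "epoch": epoch,
                "phase": "supervised" if supervised else "pseudo_label",
                **{k: v / max(n_batches, 1) for k, v in epoch_terms.items()},
                "val_lesion_dsc": val_dsc,
                "val_skeleton_mdsc": val_mdsc,
            }
            history.append(row)
            select = val_mdsc if np.isfinite(val_mdsc) else (val_dsc if np.isfinite(val_dsc) else -epoch)
            if select > best["mdsc"]:
                best = {"epoch": epoch, "mdsc": select, "state": model.state_dict()}
        if best["state"] is not None:
            model.load_state_dict(best["state"])
            self.best_epoch_ = best["epoch"]
        else:
            self.best_epoch_ = len(history) - 1
        self.model_ = model
        self.history_ = history
        self.n_classes_ = n_classes
        self.schema_hash_ = schema.hash() if schema is not None else ""
        return self

    # --------------------------------------------------------------- predict
    def predict(self, X: list[StudyRecord]):
        """Whole-image inference: list of (lesion_mask, skeleton_labels)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        for rec in X:
            out.append(segment_whole_image(
                rec.sample.image, self.model_, rec.mas,
                patch_size=self.patch_size, normalization=self.normalization,
            ))
        return out

    def save_history(self, path) -> None:
        import csv

        with open(path, "w", newline="") as f:
            if not self.history_:
                return
            w = csv.DictWriter(f, fieldnames=list(self.history_[0]))
            w.writeheader()
            w.writerows(self.history_)


# ------------------------------------------------------------------ wrappers
def train(records, val_records=None, **params) -> MultiTaskSegmenter:
    """Functional wrapper: fit a :class:`MultiTaskSegmenter` and return it."""
    est = MultiTaskSegmenter(**params)
    return est.fit(records, val_records=val_records)


ABLATION_FLAGS = ("patch_input", "semi_supervised", "use_csgm", "share_encoder")


def run_ablation(
    grid: list[dict],
    train_records,
    val_records,
    test_records,
    seeds: tuple[int, ...] = (0,),
    **params,
) -> list[dict]:
    """One training run per flag combination and seed; returns metric rows.

    ``grid`` rows map flag name -> bool for the four architecture/training
    switches (missing flags default to off, mirroring the ablation table
    layout where the baseline row has every box unchecked).
    """
    rows = []
    for flags in grid:
        unknown = set(flags) - set(ABLATION_FLAGS)
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
        for seed in seeds:
            run_params = dict(params)
            run_params.update({f: bool(flags.get(f, False)) for f in ABLATION_FLAGS})
            run_params["seed"] = seed
            est = MultiTaskSegmenter(**run_params)
            est.fit(train_records, val_records=val_records)
            report = evaluate(
                [r.sample for r in test_records], est.model_, [r.mas for r in test_records],
                patch_size=est.patch_size,
            )
            rows.append({
                **{f: bool(flags.get(f, False)) for f in ABLATION_FLAGS},
                "seed": seed,
                "lesion_mdsc": report.lesion_mdsc,
                "lesion_precision": report.lesion_precision,
                "lesion_recall": report.lesion_recall,
                "skeleton_mdsc": report.skeleton_mdsc,
                "best_epoch": est.best_epoch_,
            })
    return rows


# ---------------------------------------------------------------- data prep
def load_dataset(data_dir) -> list[StudyRecord]:
    """Read a cohort directory written by :func:`phantom.generate_cohort`."""
    data_dir = Path(data_dir)
    rows = read_manifest(data_dir / "manifest.csv")
    schema = LabelSchema.from_json(data_dir / "schema.json")
    records = []
    for row in rows:
        pixels = read_image(data_dir / row["image"])
        lesion = read_image(data_dir / row["lesion_mask"]).astype(bool)
        skel = None
        if row["labeled_skeleton"]:
            skel, _ = read_label_map(data_dir / row["skeleton_labels"])
        sample = PhantomSample(
            image=ScintiImage(pixels, view=row["view"], id=row["id"]),
            lesion_mask=lesion,
            skeleton_labels=skel if skel is not None else np.zeros_like(pixels, dtype=np.int32),
            schema=schema,
            metadata={"role": row["role"]},
        )
        records.append(StudyRecord(sample=sample, mas=None,
                                   labeled=row["labeled_skeleton"], role=row["role"]))
    return records


def prepare_mas(
    records: list[StudyRecord],
    k: int = 5,
    params: RegistrationParams | None = None,
    consensus_threshold: float = 0.6,
) -> list[StudyRecord]:
    """Compute the MAS pseudo ground truth for every record in place.

    Atlases are the labeled *training* studies; when a target is itself an
    atlas, it is left out of its own atlas set (its remaining k-1 or fewer
    peers vote instead) to avoid self-matching.
    """
    atlas_records = [r for r in records if r.labeled and r.role == "train"]
    if not atlas_records:
        raise ValueError("no labeled training study available as atlas")
    for rec in records:
        pool = [a for a in atlas_records if a is not rec] or atlas_records
        kk = min(k, len(pool))
        atlases = [Atlas(a.sample.image, a.sample.skeleton_labels) for a in pool[:kk]]
        rec.mas = run_mas(rec.sample.image, atlases, k=kk, params=params,
                          consensus_threshold=consensus_threshold)
    return records
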