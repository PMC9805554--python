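"""scintimtl: multi-task lesion detection and anatomical localization in
whole-body bone scintigraphy.

A shared-encoder dual-decoder U-Net segments hot-spot lesions (binary,
sigmoid head) and the skeleton into anatomical regions (multi-class, softmax
head) from planar gamma-camera views. Skeleton supervision is semi-
supervised: multi-atlas segmentation provides pseudo ground truth, injected
both as training targets (partial cross-entropy over an atlas-consensus
mask, CRF-regularized) and as a channel-spatial guidance signal at the
skeleton head. Synthetic phantoms stand in for clinical scans throughout.
"""


def _tune_allocator() -> None:
    # Training allocates many multi-megabyte temporaries; keeping them on the
    # glibc heap (instead of fresh mmap segments) lets the allocator recycle
    # pages and speeds the train loop several-fold. Best effort, Linux/glibc.
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)   # M_MMAP_THRESHOLD
        libc.mallopt(-1, (1 << 31) - 1)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from .evaluate import EvalReport, dsc, evaluate, lesion_detection_metrics, mdsc, segment_whole_image
from .losses import LossConfig, bilateral_affinity, ce, crf_loss, pce, total_loss, wbce
from .mas import Atlas, MasResult, fuse_labels, gaussian_guidance_map, register_pair, run_mas, warp_labels
from .network import ForwardOutput, ModelConfig, MultiTaskUNet, build_model, csgm, forward
from .phantom import PhantomConfig, PhantomSample, deform_phantom, generate_cohort, generate_phantom
from .readwrite import LabelSchema, ScintiImage, read_study, write_label_map
from .sampling import LikelihoodMap, PatchPair, extract_patch_pair, likelihood_map, sample_patch_centers
from .training import MultiTaskSegmenter, StudyRecord, TrainConfig, load_dataset, prepare_mas, run_ablation, train

__version__ = "0.1.0"

__all__ = [
    "Atlas", "EvalReport", "ForwardOutput", "LabelSchema", "LikelihoodMap",
    "LossConfig", "MasResult", "ModelConfig", "MultiTaskSegmenter",
    "MultiTaskUNet", "PatchPair", "PhantomConfig", "PhantomSample",
    "ScintiImage", "StudyRecord", "TrainConfig", "bilateral_affinity",
    "build_model", "ce", "crf_loss", "csgm", "deform_phantom", "dsc",
    "evaluate", "extract_patch_pair", "forward", "fuse_labels",
    "gaussian_guidance_map", "generate_cohort", "generate_phantom",
    "lesion_detection_metrics", "likelihood_map", "load_dataset", "mdsc",
    "pce", "prepare_mas", "read_study", "register_pair", "run_ablation",
    "run_mas", "sample_patch_centers", "segment_whole_image", "total_loss",
    "train", "warp_labels", "wbce", "write_label_map",
]
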