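# Methods

This note documents the models and procedures implemented in `scintimtl`,
the defaults chosen where the design was open, and what the synthetic
experiments do and do not establish.

## Problem setting

A whole-body bone scan is a pair of planar 16-bit count images (anterior /
posterior, nominally 256×1024 per view) acquired after ⁹⁹ᵐTc-MDP injection.
Two outputs are wanted per view: a binary mask of hot-spot lesions and a
labeling of the skeleton into anatomical regions (presets: 56 anterior, 68
posterior, background reserved as label 0). Lesion masks are assumed
available for every training study; dense skeleton labels only for a small
subset. The two views are processed independently in their native
orientation; coordinates are row-major with origin at the top-left.

## Multi-atlas pseudo-labeling

Each of k (default 5) labeled atlases is registered to the target with an
affine stage (SimpleITK `ImageRegistrationMethod`, mean-squares metric,
multi-resolution shrink 4/2/1) followed by a deformable stage
(fast symmetric-forces demons, 40 iterations, field smoothing σ = 2 px).
Inputs are Gaussian-smoothed (σ = 1 px) and max-normalized first, as count
noise otherwise dominates the metric. The recipe is deliberately swappable
behind the `register_pair` contract; a candidate field is accepted only if
it lowers the mean-squared intensity difference relative to identity,
otherwise the best field found so far (possibly identity) is returned with
a warning. Displacement fields are dense (2, H, W) pixel offsets in pull
convention: `out(x) = moving(x + d(x))`; labels are propagated by
nearest-neighbor resampling.

Warped labels are fused by per-pixel majority vote, ties toward the
smallest label id for determinism. Two derived products feed training:

* **annotation mask** `m` — pixels whose vote fraction reaches a consensus
  threshold (default 0.6). The partial cross-entropy averages only over
  these pixels, which directly limits the error accumulation
  ("confirmation bias") that plain pseudo-label training suffers when a
  model is supervised by its own mistakes.
* **guidance map** `M` — the (C+1)-channel one-hot encoding of the fused
  labels smoothed per channel with a normalized 3×3 Gaussian (σ = 1, sum 1,
  nearest-edge padding so a partition of unity stays a partition of unity).

## Network

U-Net backbone: blocks of two 3×3 convolutions with instance normalization
and ReLU; max-pool downsampling; transposed-convolution (2×2, stride 2)
upsampling; skip connections at every level feed both decoders identically.
Default depth is 4 down-sampling stages (desk-scale experiments use 3);
`base_width` is 16 at desk scale with a 64 preset for full scale. The lesion
head is a 1×1 convolution + sigmoid. The skeleton head is a 1×1 convolution
to C+1 logits, refined by the parameter-free CSGM

    F' = F ⊗ G₃ₓ₃(M) + F,

then softmax. CSGM is applied at the logits because that is the only point
where the required shape equality between features and the (C+1)-channel
guidance holds without extra projections. With the multiplicative form,
zero logits would silence the guidance entirely, so when CSGM is enabled the
skeleton-head bias is initialized to 1: at initialization the softmax argmax
then already follows the atlas prior, and training refines from there
rather than from noise. With `share_encoder=False` each branch receives its
own encoder (the single-task ablation).

## Losses

All log terms clamp probabilities at ε = 1e-7. Defaults:

* `w` (wBCE positive-class weight): 5. Lesions occupy a small fraction of
  even lesion-centered patches; values 2–10 behave similarly.
* CRF: bilateral affinity `W_ij = exp(−‖pᵢ−pⱼ‖²/2σ_xy² − (Iᵢ−Iⱼ)²/2σ_int²)`
  with σ_xy = 3 px, σ_int = 0.1 (normalized intensity units), restricted to
  a 5×5 window — the dense all-pairs sum is quadratic in patch area and the
  bilateral-filter formulation is local by construction. The pair sum is
  normalized by the number of ordered in-bounds pairs so the term's
  magnitude is independent of patch size and the unweighted three-term sum
  is meaningful. The CRF regularizes the skeleton softmax by default; a
  two-class variant for the lesion head sits behind `crf_branch`.
* Term weights default to (1, 1, 1), i.e. the plain sum of the three terms.

The CRF term is evaluated in closed form with an analytic gradient
(`dL/dz_pc = −2 Σ_off W_p^off · z_{p+off,c}`, using channel sums of 1 and
affinity symmetry); cross-entropy uses a fused gather. Both are validated
against nested-loop oracles and finite differences.

## Patch sampling

Likelihood smoothing σ defaults to 8 px; the background floor mixes 10 % of
a uniform distribution into the normalized smoothed mask, guaranteeing
pure-background patches while keeping lesion-centered ones dominant.
Accepted centers are clamped so the patch never needs padding. Image patches
are normalized by the study maximum into [0, 1] by default; a literal
`/255` mode (clipped) is kept for 8-bit-scaled data. Full-scale defaults:
100 patches of 128×128 per study per epoch, resampled fresh every epoch.

## Training

Adam with β₁ = 0.9 (the conventional momentum value), β₂ = 0.999, weight
decay 1e-4, initial learning rate 1e-3 with inverse-time decay 1e-8, batch
size 100, up to 1000 epochs at full scale. Phase schedule: ¾ of the epochs
train on every study with the unsupervised objective (pCE on MAS labels
under the consensus mask), ¼ refine on the labeled subset with full CE.
After each epoch, whole-image tiled inference (stride = patch/2, per-pixel
probability averaging, lesion threshold 0.5, skeleton argmax) on the
validation split produces a lesion Dice and skeleton mDSC; the checkpoint
maximizing validation mDSC is selected, matching how the model is deployed.
A NaN loss aborts with the last good checkpoint.

The `patch_input=False` ablation replaces likelihood-driven centers by
uniformly drawn windows — the desk-scale stand-in for whole-image input,
isolating the sampling strategy's contribution at equal compute.

Desk-scale experiments (the test suite and `scripts/acceptance.py`) use a
256×64 matrix with 20 regions, 20 studies (13 train of which 5 labeled / 3
val / 4 test), depth 3, base width 16, 64×64 patches, 10 patches per study
and 16–18 epochs at learning rate 3e-3 — sizes chosen so a complete run
takes minutes on one CPU while every mechanism (two-phase schedule, CSGM,
consensus masking, model selection) is exercised. The ablation comparison
runs three seeds on a still smaller 128×32 / 9-region cohort.

## Phantom generator

The generator emulates exactly the features the method depends on:

* body-shaped low-uptake background (soft tissue ≈ 10 counts) obtained by
  dilating the skeleton silhouette;
* a contiguous, non-overlapping "stick-body" skeleton (≈ 40 counts): nine
  base parts (skull, spine, rib plates, pelvis, paired arms and legs) split
  along their long axes until the requested region count exists — the
  anatomical region definitions of clinical reading are not public, so the
  schema is parametric and shipped as data;
* isotropic Gaussian hot spots (amplitude 30–120 counts, σ 1.5–4 px, 1–6
  per study) centered where their half-maximum disk fits inside bone; the
  half-maximum footprint is the lesion ground truth — a reproducible
  boundary for a continuous blob;
* Poisson count noise on the summed rate map;
* smooth random deformations (low-resolution Gaussian fields, default
  amplitude 3 px at scale 24 px, cubic-upsampled, shared across image,
  mask and labels) providing atlas variability.

What the phantom does **not** model: attenuation, scatter, collimator blur,
patient-specific anatomy, cold lesions, injection-site artifacts, bladder
uptake, or genuine anterior/posterior appearance differences. Passing the
synthetic experiments therefore demonstrates that the pipeline's mechanisms
work as specified — not clinical-grade accuracy; absolute numbers on
phantoms are systematically higher than on clinical data because phantom
contrast and geometry are cleaner.

## Numerical choices and degenerate inputs

* Probability clamp ε = 1e-7 in every log; sigmoid input clipped at ±60.
* Majority-vote ties → smallest label id; max-pool ties → first element.
* Both-empty masks score Dice 1 (correct negatives are not penalized);
  a truth map with no foreground class is an error for mDSC; classes absent
  from both maps are excluded from the mean rather than scored 0.
* Lesion detection uses 8-connected components and greedy one-to-one
  matching by overlap area; any positive overlap counts by default, an
  IoU ≥ 0.1 criterion sits behind a flag. Counts are pooled over a split.
* An all-zero lesion mask degrades the likelihood map to the uniform floor
  (logged); rejection sampling on an identically zero map is an error.
* Registration failure can never silently corrupt labels: the identity
  field is the worst case returned.
* The training loop allocates many multi-megabyte temporaries; at import
  the package raises the glibc malloc mmap/trim thresholds so these buffers
  are recycled on the heap (several-fold speedup of the train loop;
  best-effort and harmless elsewhere).

## Known limitations

* The autodiff engine implements exactly the operations this architecture
  needs; it is not a general-purpose framework (no GPU, no graph-level
  fusion beyond the CRF/CE custom ops).
* The skeleton-region schema of the phantom is synthetic; per-region names
  in the full-scale presets are plausible labels, not a clinical standard.
* Demons registration assumes mono-modal intensity agreement; strongly
  lesion-laden studies can bias the field locally — one motivation for the
  consensus mask.
* 2D planar only; no SPECT/CT support.
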