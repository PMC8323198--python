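# Methods

## Problem and scope

`msffnet` segments multimodal brain MRI (T1, T1c, T2, FLAIR) into the BRATS
2015 label taxonomy — 0 background, 1 necrosis, 2 edema, 3 non-enhancing
tumor, 4 enhancing tumor — and scores the three overlapping evaluation
regions used by that protocol: complete tumor {1,2,3,4}, tumor core {1,3,4}
and enhancing tumor {4}.  The package provides the full pipeline: reading
and writing MHA/NIfTI cases, the minimal pre-processing (crop +
z-scoring), the segmentation architectures, the class-imbalance losses, the
region metrics, a phantom generator so everything is testable without a
BRATS download, and a training/inference loop with a scikit-learn-style
estimator on top.

## Architecture

The model is a parallel two-part design rather than an encoder–decoder:

* **Feature extraction network (FEN).**  Five stages of "conv units"
  (3×3 convolution, stride 1, same padding → batch normalization → ReLU).
  Stage 1 has four units, stages 2–5 have two — twelve convolution layers
  in total.  Stages 1–4 end with a 2×2 stride-2 max pool followed by
  dropout, so stage *s* runs at 1/2^(s−1) of the input resolution and the
  input size must be divisible by 16.
* **Multi-scale feature fusing network (MSFFN).**  Eight feature maps are
  tapped from the encoder: all four stage-1 unit outputs at full resolution
  (these carry the fine spatial detail that small structures need) and the
  last-unit output of stages 2–5.  The low-resolution taps are up-sampled
  bilinearly (2×/4×/8×/16×) back to the input size, all eight maps are
  concatenated along channels, fused by three conv units, passed through
  dropout and a 1×1 convolution to 5 channels, and normalized per pixel by
  a softmax.

With the default widths (16, 32, 64, 128, 256) and fusing width 64 the
concatenated tensor has 4·16 + 32 + 64 + 128 + 256 = 544 channels and the
whole network holds 1,576,005 parameters.  Counting every convolution
kernel and bias plus the four batch-norm values per channel (scale, shift,
moving mean, moving variance) at 4 bytes each gives 6,304,020 bytes —
6.3 decimal megabytes.  The widths are a deliberate reconstruction: they
follow the conventional doubling pattern and were chosen so the parameter
budget lands on that printed figure; the same arithmetic is frozen into an
independent layer-by-layer oracle in the test suite.  The final classifier
is a 1×1 (not 3×3) convolution for the same reason.  Dropout is 0.2
wherever a dropout layer appears.

The **U-net baseline** uses encoder channels (32, 64, 128, 256, 512), two
conv units per stage, skip concatenations, and a decoder built from
bilinear up-sampling + conv units (mirroring the main model's up-sampling
choice), with BN everywhere for parity.  At ~31 MB it is roughly five times
larger than the proposed model; only that ordering is asserted, since the
baseline's exact historical configuration (transposed conv vs. resize,
BN bookkeeping) cannot be pinned down.

## Losses

Let p_{i,k} be the softmax output and g_{i,k} the one-hot annotation at
pixel i for class k; all sums pool over every pixel of the batch (a batch
is treated exactly as one large image).

* cross entropy: −(1/N) Σ_i Σ_k g_{i,k} log p_{i,k}, with p clipped to
  [1e−7, 1−1e−7];
* per-class soft Dice loss: 1 − 2Σpg / (Σp + Σg);
* per-region Dice loss: the same ratio applied to the summed member
  channels of a region (background, complete, core, enhancing);
* combined Dice loss: sum over the four region Dice losses;
* sliced Dice loss: sum over the five per-class Dice losses;
* recall loss: 1 − Σpg / Σg for a class or region — its denominator
  contains only ground-truth mass, so false positives are free and the
  gradient pushes sensitivity up;
* HL1 = α·CE + β·RL_complete + γ·RL_core + δ·RL_enhancing, defaults
  (20, 0.5, 1, 0.5);
* HL2 = α·combined-Dice + β·RL_complete + γ·RL_core + δ·RL_enhancing,
  defaults (1, 0.1, 1.3, 0.5).

Numerical conventions: a smoothing constant ε = 1e−5 is added to both the
numerator and denominator of every ratio loss, so an absent target scores a
perfect 0 rather than dividing by zero.  The core-region recall loss is
implemented without the stray factor 2 that appears in one printed version
of its formula; with the factor the loss could go negative and would be
inconsistent with the per-class and other region recall definitions, so it
is treated as a typo.  Every loss optionally returns its analytic gradient
with respect to p, verified against central finite differences.

## Numerical engine

No deep-learning framework is used: the package ships a small NumPy engine
(`msffnet.nn`) with exactly the layers the architectures need — conv, BN,
ReLU, 2×2 max pool, dropout, bilinear up-sampling, softmax — each with a
hand-derived backward pass, plus Adam.  Tensors are float32 channels-last
(N, H, W, C).  Convolutions are computed as k² shifted GEMMs over the
padded image (one fat GEMM for all taps when the scratch fits in ~300 MB):
this avoids materializing im2col patch matrices, whose strided copies
otherwise dominate NumPy runtime.  Bilinear resampling is expressed as two
dense 1-D resize matrices (align_corners=False convention), making its
adjoint exact.  Convolutions support zero or circular padding; circular
padding plus wrap-mode resampling makes the whole network exactly
shift-equivariant for translations that are multiples of the total pooling
factor, which the test suite uses as a convolutionality check.  Gradient
correctness of every layer is established by finite differences (exact in
float64; ~1e−4 agreement through the float32 stack).

## Pre-processing and augmentation

Cases are center-cropped in-plane (240 → 176 removes 32 voxels per border,
keeping the whole brain in BRATS geometry), then each modality of each case
is z-scored over all voxels of the cropped volume — the simplest
deterministic reading of "zero mean, unit variance"; no brain-mask-only
statistics, no bias-field correction, no histogram matching.  Axial slices
feed the 2-D network with channel order (T1, T1c, T2, FLAIR).  Training
defaults to keeping only slices with brain content (any pixel different
from the corner background value); prediction always processes every slice
so volumes reassemble exactly.  Augmentation is random horizontal/vertical
flips and 90°-multiple rotations: label-exact, interpolation-free, and the
identical spatial map applies to image and annotation.  Arbitrary-angle
rotations were deliberately excluded — they would require interpolating
integer labels.

## Training and inference

Adam with a triangular cyclical learning rate between 1e−6 and 1e−3
(half-cycle length configurable, default 400 iterations), batch size 40 by
default, loss selectable among {ce, sliced_dice, combined_dice, hl1, hl2}.
Splits are by case, never by slice.  The best checkpoint is the one with
the lowest validation loss; validation region DSC is logged but not used
for selection.  Training aborts with a diagnostic on a non-finite loss.
Prediction runs slice-wise, takes the per-pixel argmax over the five class
probabilities and restacks to the case's Z extent.  Ensembles average the
members' softmax maps before the argmax (majority voting is available
behind a flag); averaging was chosen because it uses the full probability
information.  Five-member ensembles re-seed the 80/20 case split per
member.

## Phantom generator

The generator emulates the structure of a BRATS case: an ellipsoidal brain
(background exactly zero, as in skull-stripped data) optionally containing
a nested tumor — an edema shell around a core partitioned into a necrotic
center, a non-enhancing ring and an enhancing rim.  All shells are level
sets of one ellipsoidal distance field perturbed by a single smooth
low-frequency noise field, so the nesting enhancing ⊆ core ⊆ complete holds
by construction.  Modality intensities come from a fixed table chosen for
clinical-like contrast (T1c-bright enhancing rim, FLAIR-bright edema,
T1-dark necrosis; healthy brain at 100, noise SD 10, so FLAIR separates
edema from brain by 6 SDs), with additive Gaussian noise inside the brain.
Tumors occupy a few percent of the volume, reproducing the severe class
imbalance.  Defaults: every case carries a tumor (as in BRATS), edema
semi-axes 30–42 % of the half-dimensions, core at 55–70 % of the edema
radius, necrotic center at 45 % and enhancing rim beyond 80 % of the core
radius.

What the phantoms do *not* emulate: real anatomy (no atlas), bias fields,
Rician noise statistics, multi-focal or infiltrative growth, inter-rater
label noise.  Passing the desk-scale checks therefore demonstrates that the
architecture, losses, metrics and pipeline are implemented correctly and
that the training loop can fit a separable nested-structure task — it does
not certify clinical BRATS-level accuracy, which requires the real dataset
and its online scorer.

## Metrics

DSC = 2|P∩G|/(|P|+|G|), PPV = |P∩G|/|P|, Sensitivity = |P∩G|/|G|, computed
per evaluation region on whole 3-D volumes per case (as the online system
does), then averaged unweighted over a cohort.  Degenerate masks follow the
convention both-empty → 1, one-empty → 0, so a correct all-negative
prediction is not penalized; the reference system's own rule for this case
is undocumented, which is why the convention is stated prominently here.

## Desk-scale test problem sizes

The full-size architecture (176×176, widths 16–256) is instantiated for
parameter counting, shape contracts and single-step gradient checks.  The
learning checks in the test suite run the same architecture family at
reduced width and volume so they complete on one CPU: the HL2 learning
check trains a (8, 12, 16, 24, 32)/16 model on 40 phantoms of 64×64×16
(batch 10, 11 epochs); the loss-direction comparison trains
(6, 8, 12, 16, 24)/12 models on 12 phantoms of 48×48×12 per seed for
6 epochs, three seeds per loss.  The acceptance thresholds applied to these
runs (held-out complete-region DSC ≥ 0.80; HL1 mean sensitivity ≥ CE mean
sensitivity, report-only) are independent of the scaling.

## Known limitations

* 2-D slice-wise segmentation only; no 3-D context, no CRF post-processing.
* The published channel configuration and dropout rate are reconstructed
  from the parameter budget, not copied from a reference implementation.
* The NumPy engine targets clarity and test-scale problems; it is orders of
  magnitude slower than a GPU framework at full BRATS scale.
* Gaussian phantom noise and ellipsoidal geometry make the synthetic task
  considerably easier than clinical data.
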