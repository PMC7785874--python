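# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `raunet`, in the order the pipeline runs.

## Problem setting

Automatic liver and tumor segmentation in abdominal CT is usually solved
coarse-to-fine: find the liver roughly, segment it precisely inside a
restricted volume of interest (VOI), then search for lesions only inside the
segmented liver. `raunet` implements that three-stage cascade with a family
of residual attention-aware U-Nets: a 2D network for slice-wise liver
localization and a 3D network (two separately trained instances) for liver
and tumor VOI segmentation.

## Preprocessing

CT voxels are Hounsfield units (HU). A global window clips intensities to
[−100, 200] HU — wide enough to keep liver parenchyma (40–50 HU), blood,
water, and hypodense lesions, while clamping air (≈ −1000 HU) and bone
(≥ 400 HU) to the window edges. Windowing is followed by zero-mean and then
min–max normalization, so network inputs lie exactly in [0, 1]. Notes:

* Statistics are per volume. This needs no dataset-wide pass and matches
  single-case inference.
* Because min–max is applied last, the zero-mean step is absorbed by it in
  exact arithmetic; the composition is kept as stated for clarity, and the
  min–max step is the range-defining one.
* A constant volume has no intensity range and raises
  `DegenerateVolumeError` rather than dividing by zero.
* Windowing happens before any resampling, so interpolation never mixes
  out-of-window values into tissue intensities.

## Network family

Both networks share one layer plan parameterized by the base width `c`
(default 32), expressed for the 3D case on a 224×224×32 input:

* **Encoder** — a stem convolution (1→c), then five max-pool + residual
  stages widening c → c → 2c → 4c → 8c → 16c, plus a second 16c residual
  block at the bottom (7×7×1 for the default input).
* **Decoder** — nearest-neighbour upsampling whose per-axis factors mirror
  the encoder pools in reverse; each skip connection passes through an
  attention-residual module and is concatenated with the upsampled path
  before a residual block narrowing back down to c.
* **Head** — a convolution over the final concatenation and a 1-kernel
  convolution to a single sigmoid channel, so outputs are probabilities.

**Residual unit.** Three pre-activation BN→ReLU→conv sets in bottleneck
form: a 1-kernel conv to C/4 channels, the spatial (3-per-axis) conv at C/4,
and a 1-kernel conv back to C, plus an identity path that is a 1-kernel
convolution exactly when the input and output channel counts differ. The
bottleneck is what keeps the full 3D network at 2,776,945 trainable
parameters (≈3M, under the 4M budget); three full-width 3-kernel convs per
block would exceed 50M at these channel widths, an order of magnitude out of
budget.

**Attention-residual module.** Output is `(1 + S(x)) · F(x)`, where the
trunk `F` is one residual unit and the soft mask `S` is an encoder–decoder
of depth D: D max-pool+residual descents, a bottom residual unit, D
residual+upsample ascents with long-range additive skips (each skip passes
through its own residual unit), closed by two 1-kernel convolutions and a
sigmoid. Depths are fixed at (0, 1, 2, 3) from the deepest skip to the
shallowest; at depth 0 the mask branch has no pooling. Setting S ≡ 0
reduces the module exactly (bitwise) to its trunk, which the tests verify;
mathematically S ∈ (0, 1), though float32 sigmoid saturates to the closed
endpoints for |logit| ≳ 17.

**Anisotropic pooling.** Pooling halves every even spatial axis and leaves
collapsed (size-1) axes untouched; an odd axis larger than 1 is a
configuration error. The decoder records the encoder's factors and mirrors
them, so skip shapes always match. This is what lets the same code accept
224×224×32 (axial size reaches 1 at the bottom) and smaller desk-scale
inputs such as 64×64×16. In-plane sizes must survive five halvings.

The published layer table contains one internally inconsistent row (a
pooling output listed as 56×56×4×64 between a 56×56×8×64 input and a
28×28×4×128 successor); the implementation realizes the consistent chain
28×28×4×64, and the shape-conformance test encodes that correction.

## Numpy NN engine

No deep-learning framework is used; `raunet.ndnn` is a small tape-based
reverse-mode autodiff engine sufficient for these networks: stride-1
same-padding convolutions (implemented as one GEMM per kernel offset, which
bounds peak memory at one activation volume), batch norm, max pooling by
reshape with first-occurrence argmax tie-break, nearest upsampling, concat,
ReLU/sigmoid, and Adam. Details:

* Arrays are float32, channels-last `(N, *spatial, C)`.
* Batch norm: momentum 0.9, epsilon 1e-3 (the engine's defaults; the
  moderate momentum lets running statistics converge within the short
  desk-scale runs this package targets, keeping eval-mode inference
  consistent with training). Eval mode uses running statistics and gives
  them no gradient.
* Convolution weights are He-normal initialized from an explicit
  `numpy.random.Generator`; everything stochastic is seed-driven, and two
  forward passes with fixed weights are bitwise identical.
* Gradients of every primitive are tested against finite differences, and
  conv/pool forwards against scipy/scikit-image oracles.

## Training

The loss is soft Dice, `1 − (2Σs·g + ε)/(Σs² + Σg² + ε)` over all voxels,
with ε = 1e-5 so the empty/empty case is defined (loss ≈ 0). Optimization
is Adam (lr 1e-3, β₁ 0.9, β₂ 0.999); the learning rate is multiplied by 0.1
when the validation loss has not improved by more than 1e-4 for 20
consecutive epochs. The patch split inside a training run is 80/20
train/validation (runs with fewer than five patches reuse the train loss as
the validation signal). A non-finite loss aborts with a diagnostic.

Patch sampling per stage:

* **Localizer (2D)** — every axial slice containing liver plus one third as
  many randomly drawn liver-free slices, resized in-plane to 256×256.
* **Liver (3D)** — the liver boundary box resized in-plane to the patch's
  in-plane size (default 224×224), then random axial windows of 32 slices.
  Boxes thinner than the window are zero-padded and the padding is masked
  out of the loss.
* **Tumor (3D)** — 150 windows (default 128×128×32) per volume at native
  resolution, no resizing; half the window centers are drawn from tumor
  voxels and half from non-tumor liver voxels, degrading to liver-only
  centers when the liver is lesion-free. Windows are shifted, never padded,
  when a center sits near the volume edge.

Ensembling (e.g. of the five cross-validation fold models) is voxelwise
probability averaging before thresholding; for five members at threshold
0.5 this subsumes a majority vote. The k-fold splitter is volume-level and
stratified by tumor presence.

## Cascade inference

1. **Localization** — each axial slice is linearly resized to 256×256,
   segmented by the 2D network, thresholded at 0.5, and restacked in
   original order; 26-connected component labeling keeps the largest
   component; the mask is resized back to the native grid
   (nearest-neighbour) and its bounding box is expanded by a 10-voxel
   margin per direction, clamped to the volume.
2. **Liver** — the box is resized in-plane to the inference window's
   in-plane size, tiled with axial windows at 50% overlap, each window
   ensemble-predicted, probabilities fused by voxelwise averaging
   (uncovered voxels are 0), resized back (linear), thresholded at 0.5, and
   reduced to the largest 26-connected component.
3. **Tumor** — windows tile the liver region at native resolution with 50%
   overlap per axis, probabilities are fused and thresholded, and every
   voxel outside the liver mask is cleared. No largest-component step:
   multiple lesions are legitimate. An empty tumor mask is a valid result.

Fixed numerical conventions: threshold 0.5 at every stage; linear
interpolation for intensities and probabilities, nearest-neighbour for
masks; 26-connectivity for all component analysis. Empty stage outputs
raise `EmptySegmentationError` carrying the stage name (except the tumor
stage, where empty is meaningful).

## Metrics

Per case: Dice, Jaccard, VOE = 1 − Jaccard, signed RVD
(= (|A| − |B|)/|B|, prediction minus reference, so over-segmentation is
positive), ASSD and MSD in millimetres. Pooled: Dice-global over summed
voxel counts. Surfaces are border voxels (mask minus its 26-connected
single-voxel erosion; volume-edge voxels count as surface); distances are
Euclidean between voxel centers scaled by the voxel spacing. Conventions
for degenerate inputs: Dice is 1 for empty/empty and 0 one-sided; RVD is
undefined (NaN in reports) for an empty reference; surface distances
require two nonempty masks. Overlap metrics are exact integer-count ratios;
the distance metrics are verified against a brute-force all-pairs oracle to
1e-9.

## Phantom generator

The generator emulates the *structure* of contrast abdominal CT at
configurable scale: air background (−1000 HU), a partial annular bone
shell (500 HU, open posteriorly, central 70% of the axial extent), an
ellipsoidal liver with voxels drawn uniformly from 40–50 HU, and spherical
lesions at liver HU plus a contrast offset (default −30 HU, i.e. hypodense,
the low-contrast regime that makes tumor segmentation hard), plus additive
Gaussian noise (default sd 5 HU, a moderate clinical noise level that keeps
the ~30 HU lesion contrast detectable but non-trivial). Defaults: 160×160×64
voxels at 2.0×2.0×2.5 mm spacing — the geometry of a 512×512 scan at desk
scale — with a flag-free path to full 512×512×N grids. Lesion centers are
drawn uniformly inside the ellipsoid shrunk by radius/min-semiaxis, a
conservative containment bound; masks are rasterized analytically so the
ground truth is exact.

What the phantom does **not** model: organ shape variability, neighbouring
soft-tissue organs of similar radiodensity (stomach, heart, kidney),
partial-volume and respiratory artifacts, and lesion texture. Passing the
cohort tests therefore demonstrates that the architecture, training loop,
and cascade logic are correct and that the networks can learn
intensity+shape structure — not that desk-scale training generalizes to
clinical CT, which requires the real datasets and full-scale training this
package's tests deliberately avoid.

## Desk-scale test sizes

The test suite trains quarter-width networks (base width 8) on 64×64×16
patches and 256×256 slices, and runs the cascade with 128×128×16 liver and
64×64×16 tumor windows on 160×160×64 phantoms. These sizes were chosen as
the smallest that exercise all five resolution levels of the architecture
and still leave clear margins on the tested contracts (overfit Dice ≥ 0.95
on two patches; per-case liver Dice ≥ 0.90 on a held-out five-phantom
cohort, typically ≥ 0.99). Full-width networks and the published window
sizes (224×224×32, 128×128×32) are the library defaults.

## Known limitations

* CPU-only numpy training is orders of magnitude slower than a GPU
  framework; the package targets correctness and desk-scale verification,
  not benchmark-scale training.
* The 2D localizer's exact depth/width is mirrored from the 3D plan (the
  published description calls it "a simple version" without a table); this
  is an interpretation, made explicit here.
* Decoder residual rows are implemented as one residual unit each; the
  attention trunk is one residual unit (counts consistent with the
  parameter budget).
* The inference tiling strides (50% overlap) and the fusion rule
  (averaging) are reasonable fixed conventions; the cascade's published
  description confirms overlap and "voting" exist but pins down neither.
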