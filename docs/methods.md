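# Methods

## The model

`densicount` counts objects by estimating a density map: a non-negative 2-D
field whose integral over any region equals the expected number of objects
there. Supervision comes entirely from point annotations — one coordinate
per animal — which is the cheapest annotation a human counter can produce.

**Targets.** Each point contributes an isotropic Gaussian kernel of
bandwidth σ = 4 px, evaluated at pixel centers on a
(2·r·σ + 1)² window (truncation radius r = 4 bandwidths) and divided by the
window sum, so every interior point carries total mass exactly 1 on the
discrete grid. Kernels overlapping the image border are clipped **without**
renormalization: mass outside the frame is genuinely lost, which is what
makes tiling consistent — cropping the full-scene density map distributes an
edge-straddling object's mass across tiles so tile counts sum exactly to the
scene count. The fixed bandwidth reflects near-constant object size in
scale-controlled aerial imagery; a nearest-neighbour adaptive bandwidth
(mean distance to the 3 nearest points × 0.3, floored at 0.5 px) is
available for perspective-distorted data but is off by default. The
full-resolution map is sum-pooled by the network's output stride (8) into
the learning target, and cells of that target strictly exceeding
ε = 10⁻³ form the binary segmentation target. A cell exactly at ε is
background.

**Architecture.** A VGG-19 convolutional trunk truncated before its fifth
max-pool (16 convolutions, four 2 × 2 pooling stages → 1/16 resolution,
512 channels), bilinear ×2 upsampling (half-pixel-center convention, corners
not aligned) to 1/8 resolution, then two branches of three convolutions
(kernel sizes 3, 3, 1) reducing channels 512 → 256 → 64 → 1. The
segmentation branch ends in a sigmoid, the density branch in a ReLU, so the
output invariants (probabilities in [0, 1], densities ≥ 0) hold by
construction. The segmentation prediction builds the feature mask
M_d = 1[S ≥ 0.5] + α·1[S < 0.5] (α = 0.1, the 0.5 boundary counting as
foreground) which multiplies the shared features before the density branch.
The mask is treated as a constant in the backward pass: the indicator has
zero derivative almost everywhere, and detaching it avoids an ill-defined
gradient through the threshold. The segmentation branch consumes the
*unmasked* features. Inputs of any size are zero-padded bottom/right to a
multiple of 16 so no pixels drop out of the pooling stages.

**Loss.** The density branch is trained with the masked multi-scale
structural loss SL*: mean over three levels of 1 − SSIM between the
prediction and target, both multiplied by the binary segmentation target
before average-pooling by 2^(i−1) (level 1 is the identity; odd trailing
rows/columns are truncated by the pooling). Masking removes the vast
near-zero background from the objective so the regressor concentrates on
cells that carry count mass; the fused inference path makes discarding
those background cells safe. SSIM here is the single closed-form index over
whole-map statistics (means, 1/M-normalized variances, covariance) with
additive stabilizers C₁ = 0.01 and C₂ = 0.03 taken literally; a
sliding-window variant (uniform filter) is available but off by default,
as the closed form involves one statistic per map. SSIM is defined so that
identical maps score exactly 1 and no pair scores above 1; the loss applies
the single outer 1 − SSIM. The segmentation branch is trained with a
class-balanced binary cross-entropy (background term weighted h = 0.5;
probabilities clamped to [10⁻⁷, 1 − 10⁻⁷] before logs), and the total loss
is SL* + λ·CE with λ = 0.1 — density estimation is the main task.

**Inference.** D_out = D_pred · 1[S_pred ≥ 0.5]; the count is the total
mass of D_out over the padded-resolution output map, which is returned
whole. Computing the count on the full padded map (rather than a crop to
the original footprint) makes the count bit-identical whether or not the
caller pre-pads, and keeps "count = mass of the returned map" exact; the
original size is recorded for callers that want a display crop.

**Training protocol.** 3:1:1 random split (validation/test floored, the
remainder to training); per-sample augmentation is a random crop (default
256 × 256) and a horizontal flip with probability 0.5, applied identically
to the image and the precomputed full-resolution density map, which is then
sum-pooled ×8 into the target — cropping before pooling preserves
fractional mass at crop borders. Adam with learning rate 10⁻⁵ and L2 weight
decay 10⁻⁴ (added to the gradient), batch 16, 600 epochs; validation with
the full fused inference path on uncropped images after epoch 100; the
selected checkpoint minimizes validation MAE + RMSE, ties to the earliest
epoch. One epoch is one pass over the training image list with one random
crop per image. Every epoch reseeds its generator from (seed, epoch), so a
run resumed from a checkpoint (parameters + Adam state) reproduces the
uninterrupted run exactly.

## The numerical engine

The network runs on a compact numpy engine inside the package
(`densicount.nn`): stride-1 im2col convolution, 2 × 2 max pooling (ties to
the first element, deterministically), separable bilinear ×2 upsampling
implemented as explicit row/column weight matrices (so its adjoint is the
transposed matrices), hand-derived analytic gradients for the SSIM chain
and the cross-entropy, and bias-corrected Adam. Parameters and activations
are float32; loss values and their gradients are computed in float64 on the
output maps and cast at the boundary. Gradient correctness is enforced in
the test suite by finite-difference checks on the losses and adjoint
(dot-product) identities on every linear layer. Backbone convolutions are
He-initialized (training from scratch must not start in a vanishing-signal
regime); branch convolutions are initialized from a zero-mean Gaussian with
standard deviation 0.01, biases at zero. An ImageNet-pretrained backbone
can be injected from an `.npz` file via `use_pretrained_backbone` /
`pretrained_path`; nothing in the package or its tests depends on it.
Inputs are normalized per channel with the ImageNet mean/std conventional
for VGG-family backbones.

## Synthetic data

The generator emulates the statistical regime of aerial survey tiles:
objects ~5 px across rendered as anisotropy- and amplitude-jittered
Gaussian-profile blobs, darker than the background by a contrast of 0.35
(±30% jitter) as dark-plumaged animals against pale ground; backgrounds
flat, smoothly textured (two scales of filtered noise), or carrying a
linear illumination gradient, plus sensor noise; object centers
rejection-sampled with a minimum spacing of 2 px so near-touching
individuals occur as they do in dense colonies; per-image counts drawn
uniformly within the density-level bands L0 (0) … L4 (1001–2000), with the
level composition of a dataset following a requested mix exactly. The
background and tint derive from a random stream independent of the object
stream, so two scenes with the same seed that differ only in object count
are pixel-identical outside object footprints. Scenes default to 448 × 448,
the standard survey tile size.

What the generator does **not** model: biological texture and posture,
shadows cast by objects, species mixtures, blur/compression artifacts, and
spatial clustering of objects within a scene (placement is uniform). Tests
passing on this data therefore establish the correctness of the machinery —
mass bookkeeping, losses, optimization, selection, metrics — and that the
model can learn to count blob-like objects on cluttered backgrounds; they
do not certify accuracy on real survey imagery, which depends on training
data of the actual species and sensor.

## Desk-scale study configuration

CPU-scale runs (the learning smoke test, `examples/04`, and
`scripts/acceptance.py`) use: the `tiny` backbone (identical pooling
structure at 1/8 channel width, branch widths 64 → 32 → 16 → 1), 106
scenes of 128 × 128 px → a 64/21/21 split, level mix L0/L1/L2 =
0.30/0.35/0.35 (the composition of a real survey training archive
restricted to its three sparse levels), 64-px crops, batch 8, 40 epochs,
validation after epoch 20, and learning rate 10⁻³. The raised learning
rate compensates for the short schedule and the small randomly-initialized
backbone; the full-scale defaults remain those of `TrainConfig`. The
reference point for these runs is the predict-the-training-mean baseline,
which any model that has learned a count signal must beat decisively.

## Degenerate inputs and edge cases

Empty annotation sets are legitimate (background-only images train the
model's background rejection and are evaluated in level L0). Empty count
lists, shape mismatches, non-binary SL* masks, negative counts and
out-of-bounds points raise typed errors. Maps too small for the requested
pooling pyramid reduce the number of levels with a warning. A non-finite
training loss aborts with a diagnostic rather than continuing. Level
buckets with no images report n = 0 and metrics as not-applicable; the
dataset-level percentage error is not-applicable when the true total is
zero. Predicted counts are never rounded.

## Known limitations

- Whole-map SSIM statistics are the default; windowed SSIM changes the
  loss surface and is untested at scale here.
- The numpy engine is single-threaded BLAS-bound; full-width VGG-19
  training at survey scale is impractical on CPU (the tiny backbone exists
  for exactly this reason). Checkpoints are portable, so full-scale weights
  trained elsewhere can be loaded for inference.
- Counts are non-negative reals; the model provides regions, not locations
  — per-individual positions are out of scope by design.
- Bit-exact reproducibility holds within a fixed BLAS/numpy build; across
  different builds, floating-point reduction order may differ.
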