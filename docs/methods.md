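# Methods

This note documents the models, conventions and design choices behind
`placim`, in the order data flows through the pipeline.

## Phantom generator

The generator emulates the T2-weighted appearance of placental invasion
on a 2D slice, not abdominal anatomy. Each phantom is built from:

- a textured background (level ≈ 0.25, smooth noise amplitude 0.03);
- an elliptical **placenta** (level ≈ 0.55) whose area fraction is drawn
  from `placenta_area_frac_range` (default 0.06–0.14 of the frame), with
  random axis ratio 0.65–0.9, orientation and centre jitter;
- a bright **myometrium ring** (level ≈ 0.85) of nominal thickness
  `myometrium_thickness_px` (default 5 px), a band of the Euclidean
  distance field around the ellipse;
- additive Gaussian noise `noise_sigma` (default 0.02 in [0,1] intensity
  units — mild, in keeping with the good-quality T2WI the task assumes).

The invasion grade controls the lesion signs:

| grade | placenta–ring gap | ring | extra signs |
|---|---|---|---|
| 0 none | 2 px (decidua) | intact | homogeneous placenta (texture amplitude 0.01) |
| 1 accreta | contact | intact | amplitude 0.05 |
| 2 increta | contact | thinned to 30 % in a random sector | amplitude 0.09 + dark bands (−0.25) |
| 3 percreta | contact | interrupted in the sector | amplitude 0.13 + bands + a placental capsule bulging through the ring |

The texture amplitudes increase strictly with grade, so intra-mask
intensity variance is non-decreasing in the label in expectation; with
the same RNG state all grades share their geometry draws, which the tests
exploit for paired comparisons. Masks are single 4-connected components
(the bulge is attached to the ellipse). Each record gets its own RNG
substream keyed by (root seed, record index), so a dataset is a pure
function of its spec and partial regeneration is reproducible. Plane
tags (transverse/sagittal/coronal) are round-robin metadata only.

What a green test on phantoms does **not** establish: performance on
clinical MRI. There is no k-space simulation, no bias field, no fetus,
no organ context, and the class signal is injected through exactly the
cues the features measure. Phantoms prove the pipeline's plumbing and
learnability, not clinical validity.

## NumPy layer stack

No deep-learning framework is assumed; `placim._nn` implements
same-padding stride-1 convolution (im2col + einsum), max-pooling,
nearest-neighbour upsampling, batch normalisation, linear layers, the
dynamic convolution, and SGD, all in float32 with hand-derived backward
passes. Every layer's gradient is checked against central finite
differences in the test suite, and the convolution against
`scipy.signal.correlate2d`. SGD clips the global gradient norm at 5 by
default; without clipping, occasional loss spikes overflow float32 and
destroy a run (observed, seed-dependent).

## Segmentation

The U-net has `depth` contracting stages (double 3×3 conv + ReLU, 2×2
max-pool, channels doubling from `base_channels`), a double-conv
bottleneck, and a symmetric expansive path (nearest ×2 upsample + conv,
skip concatenation, double conv), ending in a 1×1 conv and sigmoid. All
convolutions are same-padded, so the probability map matches the input
shape; inputs must be divisible by 2^depth. Inputs are z-normalised per
image (MR intensity scales are arbitrary; without this the net stalls in
the constant-output local optimum of the loss). The loss is the average
of binary cross-entropy and Dice loss — the Dice term counteracts the
foreground/background imbalance of a small placenta. The segmentation
threshold is 0.5 with ≥ counting as foreground, and by default only the
largest connected component is kept, since the downstream shape features
assume one region. Defaults for training (SGD, batch 8, lr 0.001,
200 epochs) follow the reference configuration; the tests use scaled-down
settings (depth 2, base 8, ~30 epochs, lr 0.02 with momentum 0.9) that
reach held-out pixel F1 ≥ 0.8 on noise-free phantoms in seconds.

## ROI

The analysis region extends the placenta mask outward by `d` pixels,
defined as all pixels with Euclidean distance ≤ d from the region
(equivalently dilation by a Euclidean disk), clipped at the frame.
Default d = 40, the best-performing setting in the source experiments;
the sweep utility re-runs features + classifier for d ∈ {0,10,20,40,60}.
Coordinates are 0-based row-major; bounding boxes half-open. Radiomic
and deep features are both computed on the *extended* ROI (configurable).
The codec input is the ROI's minimal bounding rectangle, bilinearly
resized to `input_size`.

## Radiomic features

The 100-feature catalog is 18 first-order + 9 shape + 73 texture
(GLCM 22, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14); definitions follow the
standard radiomics formulations so the names carry their usual meaning.
Conventions that matter for reproducibility:

- **Discretization**: 32 equal-width bins over the ROI's own min–max
  (affine-invariant); the top edge closes, a constant ROI maps to level 1.
- **GLCM**: symmetric, distance 1, features computed per angle
  (0°/45°/90°/135°) and averaged; pairs with either pixel outside the ROI
  are skipped.
- **GLRLM**: runs along the same four angles, broken at the ROI border,
  features angle-averaged.
- **GLSZM**: zones are 8-connected equal-level components (full
  connectivity, the standard convention).
- **GLDM**: dependence = 1 + number of 8-neighbours within α = 0 levels.
- **Degenerate ROIs**: entropy 0, uniformity 1, skewness/kurtosis 0,
  GLCM correlation/IMC 0 — vectors are always finite.
- **Shape**: pixel-count area; perimeter by the weighted boundary-segment
  estimator with diagonal correction; circularity 2√(πA)/P; axis lengths
  from second moments; elongation minor/major; single-component masks
  only.

## Deep features (dynamic-convolution codec)

Encoder: `stages` Group-A blocks (dynamic conv → ReLU → batch-norm →
max-pool — ReLU before BN is kept as the printed order, switchable to the
conventional order), then global average pooling and a linear layer to
the 100-dim bottleneck. Decoder: mirrored Group-B blocks (nearest ×2
upsample → dynamic conv → ReLU → BN; upsample-then-conv avoids
checkerboard artifacts) and a final 1×1 conv + sigmoid so reconstructions
stay in [0,1]. Each dynamic convolution holds N = 4 candidate kernels
(configurable); a squeeze-and-excitation attention (global average pool →
FC → ReLU → FC → softmax at temperature 1) yields per-sample weights
summing to 1, and the layer convolves with the weighted kernel sum — the
linearity identity (aggregated-kernel result = weighted sum of per-kernel
convolutions) is asserted to 1e-5 in the tests. Channel widths double per
stage from `base_channels`, capped at `max_channels` (64). Training
minimises MSE reconstruction; afterwards the decoder goes unused and the
frozen encoder emits the 100-vector. The reconstruction target is the
raw bounding-rectangle crop (not masked). Defaults: 5 stages, 128×128
input, SGD batch 8 / lr 0.001 / 200 epochs; scaled-down test settings
are stages 2, 64×64, ≤ 30 epochs, lr 0.2 with momentum 0.9.

## Fusion classifier

Features are concatenated radiomic ‖ deep (200 dims; the two families
are deliberately balanced at 100 each) and z-scored per dimension with
statistics from the training split only, stored inside the model — there
is no interface that refits them at prediction time. The MLP widths are
200-100-20-4 (the first width is the input dimension), ReLU between
hidden layers, softmax output with max-subtraction; cross-entropy loss,
SGD. Exact probability ties resolve to the lowest class index, a
deterministic contract. Cases with several images are typed by majority
vote over image-level predictions, ties again to the lowest index.

## Evaluation

Two accuracy notions coexist and are always reported side by side:
macro one-vs-rest accuracy (mean over classes of (TP_i+TN_i)/N) and
overall accuracy (trace/N). On the reference 163-case confusion matrix
they give 0.939 and 0.877 respectively — conflating them is a real
pitfall, hence the explicit duplication. Macro sensitivity averages
per-class recall over classes present (absent classes are excluded);
macro specificity averages TN_i/(FP_i+TN_i). Multi-class AUC is
one-vs-rest, macro-averaged over classes with both positives and
negatives (the scheme is a choice; none is canonical for four classes).
Reported values round to 3 decimals, half away from zero.

## Pipeline

Splits are case-level and stratified before any fitting; an overlap
between splits is a hard error, and label access is funnelled through a
single instrumented function so the tests can verify test labels are
first touched at evaluation. If the segmenter predicts an empty mask for
a record, the pipeline falls back to the ground-truth mask (with the
annotation available in the phantom world) rather than aborting. Every
stage is seeded; the run manifest carries a SHA-256 hash of the full
configuration, and an identical configuration reproduces a bit-identical
report. The extension sweep shares phantoms, split and segmenter across
d values and retrains features + codec + classifier per d.

## Known limitations

- 2D only; no volumetric features or 3D context.
- Phantom realism is deliberately minimal (see above).
- The dynamic convolution loops over the batch for the per-sample
  aggregated kernel; fine at desk scale, not tuned for large batches.
- Optimiser hyper-parameters for the scaled-down demonstrations (lr,
  momentum, batch size) were chosen for stable convergence within seconds
  on CPU and differ from the reference full-scale settings, which remain
  the defaults.
- The comparison "fused features beat radiomics-only" is direction-level:
  on phantoms the radiomic features already capture most of the injected
  class signal, so the margin is small and a few repetitions tie at
  perfect sensitivity.
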