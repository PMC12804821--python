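# Methods

## The model

`caucseg` segments RGB field images into five pixel classes
({carrot, sugar beet, sunflower, weed, soil} = {0..4}) with an encoder–decoder
network designed around a small parameter budget.  Inputs are square RGB
images scaled to [0, 1]; the side length must be divisible by 16 (four 2×2
max-pooling levels).  The parameter count is independent of the input size.

**Stem and trunk.**  A standard 3×3 convolution lifts the image to 64
channels.  The encoder then applies four Linear Concatenated Blocks (LCBs) at
filter allocations N = 16, 32, 64, 128, each followed by 2×2 max pooling and
channel-wise dropout; the middle layer is a single 3×3 depthwise-separable
convolution (DSC) with 256 filters; the decoder mirrors the encoder with
parameter-free ×2 nearest-neighbour upsampling, channel dropout, an
attention-gated skip from the matching encoder level, concatenation, and an
LCB at N = 128, 64, 32, 16.

**LCB.**  With allocation N and input width Nᵢ the dataflow is
DSC→N, concat with input (Nᵢ+N), 1×1 → N/2, dropout(0.1),
DSC→N, concat (3N/2), 1×1 → N/2, dropout(0.1), DSC→N.
The concatenations reuse feature maps cheaply; the 1×1 bottlenecks at N/2
keep the channel growth from compounding.

**Attention gate (AG).**  Additive soft attention in the convention of the
attention-U-Net literature: the skip X (H×W×M) and the deeper feature
Y (H/2×W/2×2M) are projected to an intermediate width by 1×1 convolutions
(with batch normalization), Y's projection is upsampled ×2, the sum passes
ReLU → 1×1 → sigmoid, and the resulting per-pixel gate in (0,1) multiplies X.
Intermediate widths are 128/64/32/16 at the four levels.

**CBAM.**  Channel attention: sigmoid(MLP(avg-pool) + MLP(max-pool)) with a
shared two-layer MLP at reduction ratio 8; spatial attention: sigmoid of a
7×7 convolution over the channel-wise average and maximum planes; both applied
multiplicatively in sequence.  One CBAM refines each decoder LCB output;
the four refined maps are upsampled ×8/×4/×2/×1 to the input grid and
concatenated (128+64+32+16 = 240 channels) before a 3×3 convolution to the
five class logits and a per-pixel softmax.

**Ablation variants.**  V4 removes the CBAM fusion (head on the last LCB);
V3 replaces attention gates with plain concatenation; V2 removes both; V1 is
a conventional double-conv U-Net with widths 32/64/128/256 and a single
512-filter middle convolution, sized to match the magnitude of a standard
U-Net baseline (≈ 5.5 M parameters).  The full model is V5.

## Parameter budget and its calculus

Counting kernel weights only, a K×K standard convolution costs K²·IC·N while
its depthwise-separable factorization costs K²·IC + IC·N, a per-layer ratio of
PR₁ = 1/K² + 1/N (K = 3 throughout).  Across the model's 25 DSC layers
(three per LCB at N ∈ {16, 32, 64, 128} on each side plus the 256-filter
middle) the average is ≈ 13.9 %.  The 1×1 bottlenecks make a whole LCB cost
PR₂ = (3 + N/2 + N²/(4(N+Nᵢ)))/(9+N) of the same block without them; under
the side patterns (encoder Nᵢ = x, N = 2x; decoder Nᵢ = 2x, N = x) this
specializes to 1/3 + 2x/(3(9+2x)) and 1/3 + x/(4(9+x)), pooling to ≈ 58.3 %
over the eight blocks at x ∈ {16, 32, 64, 128}.  `empirical_pr2` validates the
closed form by constructing both block variants and enumerating their kernel
weights; the two agree to better than 1e-12 on a 6×6 (N, Nᵢ) grid.  Two notes:

* The first encoder LCB actually receives the 64-channel stem output, so its
  true Nᵢ breaks the x-pattern; the complexity report carries both the
  idealized (pattern) and graph-derived PR₂ values.
* The x = N reading of the side forms is the one under which the pooled
  average lands at ≈ 58 % with side means ≈ 63 % / ≈ 53.5 %.

**Counting conventions.**  The headline total (363,603 ≈ 0.36 M) is a
framework-style summary: convolution kernels, biases, batch-norm scale/shift
*and* batch-norm moving statistics, and the attention MLP weights.  Each DSC
carries batch normalization and ReLU after both its depthwise and pointwise
stages (the canonical depthwise-separable arrangement), each 1×1 bottleneck
and each AG projection is also batch-normalized, and the zero-initialized
output head has a bias but no normalization.  Kernel-weight-only counts (used
by the calculus and its oracle) exclude biases and all normalization terms.
The layer census counts each DSC once as a 3×3 layer (its internal pointwise
stage is part of the same layer): 27 three-by-three (stem + 24 LCB DSCs +
middle + head), 28 one-by-one (16 bottlenecks + 12 AG projections), and 4
seven-by-seven (the CBAMs).

## Training

Categorical cross-entropy on one-hot labels, Adam at learning rate 0.001,
batch size 8, 50 epochs, 5-fold crop-stratified cross-validation — these are
the `TrainConfig` defaults; desk-scale runs shrink the input size, epochs and
batch size without touching the architecture.  Channel dropout rates are 0.1
at the shallow trunk levels and 0.2 at the deep ones (mirrored on the decoder
side), with element-wise dropout 0.1 inside every LCB.

Numerical choices:

* **Zero-initialized head.**  The output convolution starts at zero, so an
  untrained model emits an exactly uniform softmax and its loss is exactly
  log 5 per pixel — a calibrated starting point that also anchors a test.
  All other convolutions use He-normal initialization; computation is float32
  (the autodiff core is dtype-agnostic; gradient checks run in float64).
* **Batch normalization.**  eps 1e-3, running-statistics momentum 0.9.
  After the last epoch the moving statistics are recomputed with frozen
  weights and dropout disabled (precise-BN recalibration, cumulative
  averaging over batches): dropout inflates activation variances during
  training, and statistics averaged under that noise systematically mis-scale
  inference-mode activations.
* **Tiny-overfit setting.**  The capacity sanity check (8 synthetic images,
  ≤ 60 epochs, CPU) runs at 32×32 with batch size 2 and Adam lr 0.01: the
  epoch budget then provides enough optimizer steps to pass the soil-majority
  baseline (~95 %) and reach ≈ 97 % training pixel accuracy in ~30 s.
* **Argmax ties** in class decoding break toward the lowest class index.

## Synthetic data

The generator emulates the statistical structure of real crop-field datasets:
~94 % of pixels are textured brown soil (filtered-noise brightness field plus
grain), one crop species per image drawn as shape-separable canopies (carrot:
thin feathery rosettes; sugar beet: broad paired ellipses; sunflower: large
radially-lobed discs), and 2–5 small irregular weeds scattered off the crop
row.  Blob areas are budgeted from `soil_fraction_target` (default 0.94), so
the realized mean soil fraction tracks the target; the same seed reproduces a
sample byte-for-byte.  Masks are perfect ground truth in the unified palette
(carrot blue, sugar beet green, sunflower turquoise, weed red, soil black);
an optional boundary-jitter flag adds annotation noise.

What it does *not* emulate: photorealistic texture, lighting and occlusion,
NIR channels, within-species morphological variation, or the actual color
statistics of real annotations.  Passing tests therefore demonstrate that the
implementation is correct and that the network can learn shape/color-separable
vegetation classes — not that it reaches any particular accuracy on real
fields.

## Label codec and pipeline

The three source annotation palettes paint crop/weed/soil differently (one
marks crops red and weeds green; the other two the reverse), so masks are
recolored into the unified palette before anything else; per-class pixel
counts are preserved.  Real-world masks may carry compression artifacts:
pixels within Euclidean RGB distance 30 of a palette color snap to it, and
anything farther raises an error naming the color and coordinates rather than
silently relabeling.

Dataset preparation follows the study design: a per-crop 90:10 hold-out split
*precedes* resampling, so no test image is ever an augmented copy of a
training image.  Undersized datasets are upsampled to the per-crop targets
(1000 train / 100 test) by appending augmented copies — each copy applies one
or two random ops from {rotation ±25°, zoom 0.8–1.2, shear ±10°, h/v flip,
width/height shift ±10 %} identically to image and mask; the image is warped
bilinearly with reflect padding, the mask as a class raster with
nearest-neighbour interpolation and soil fill, so augmented masks stay
palette-pure.  The oversized dataset is randomly sub-sampled without
replacement.  Test sets are augmented with the same op menu (configurable).

## Metrics

All rates derive from one-vs-rest pixel confusion tallies.  Micro accuracy is
overall pixel accuracy (pooled TP over total — identical to micro precision
and recall for single-label pixels); per-class and macro modes use the
one-vs-rest accuracy form.  F1 is the harmonic mean of precision and recall in
the matching mode.  The loss is the per-pixel mean categorical cross-entropy
(probabilities clipped at 1e-7).  MIoU is the unweighted mean over classes of
pixel-pooled IoU, excluding classes absent from both prediction and truth;
a with/without-soil pair is reported because the background class dominates
pooled scores.  Zero denominators define the rate as 0 and record a warning.
Mean response time is measured wall-clock per image and reported with its
variance, never asserted.

## Problem sizes

The test suite and the reproduction script run at reduced scale by design:
synthetic fixtures at 32–96 px, the pipeline-count check on fixture datasets
of 60/1800/146 pairs at 32 px, the architecture checks (parameter total,
census, stage shapes) on the full 224 px graph, and the overfit run as above.
The full suite completes in about a minute on one CPU; the reproduction
script in well under a minute.

## Known limitations

* No GPU path; wall-clock limits full-scale (3000 × 224² × 50-epoch) training,
  which this package does not attempt.
* The plain-U-Net baseline (V1) is specified only loosely by magnitude; its
  exact layout is a package choice.
* The AG internals follow the standard additive-attention convention; the
  original block was published as a figure and other gating variants exist.
* Checkpoints store weights as npz archives; they are runtime artifacts, not
  portable across architecture descriptor changes.
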