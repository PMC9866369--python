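# Methods

## Problem and model

`graincount` estimates how many undigested cereal grains appear in an
image of a dairy-cow dropping — a proxy for how well the herd digests
its ration — without detecting or localizing individual grains. The
supervision is a *dot annotation*: one point per grain at its center.
Counting is cast as density-map regression. Each dot is replaced by an
isotropic Gaussian kernel

    G(x, y) ∝ exp(−((x−x₀)² + (y−y₀)²) / (2σ²)),

and the superposition of these kernels over the frame is the target
density surface D(x). A convolutional encoder–decoder network is trained
to regress D from the image; at prediction time the object count is the
integral (pixel sum) of the predicted surface, and the integral over any
sub-window estimates the count inside that window.

### Kernel normalization

Two normalizations are supported because the two natural conventions
serve different purposes:

* `unit_integral` (default for training targets): the truncated kernel
  is divided by its discrete sum, so each dot deposits exactly one unit
  of mass and counting is a plain pixel sum.
* `unit_peak`: the kernel is divided by its maximum so the central value
  is exactly 1 — the common way such kernels are written down. Counting
  then divides the map integral by the discrete mass of one unit-peak
  kernel, so an isolated interior dot still counts as 1.0.

Numerical conventions, chosen once:

* Dots are snapped to the nearest pixel (`floor(x + 0.5)`) before kernel
  placement; the density target is a sum of shifted copies of one
  precomputed kernel grid, which makes flip equivariance exact. The tie
  case of a coordinate with fractional part exactly .5 breaks toward
  +infinity and is the one place flip equivariance can be off by one
  pixel; continuous generator coordinates never hit it.
* Kernels are truncated at radius 4σ (σ = 2 px, radius 8 by default) and
  clipped, not renormalized, at the frame border. Consequently a dot
  closer than the truncation radius to a border contributes slightly
  less than one unit of mass, and moving a dot toward a border can only
  decrease the recovered count. Keeping annotation dots at least 4σ from
  the border (as the synthetic generator does by default) preserves
  counts to better than 1e-6.

## Architectures

Both families map a single-channel image to a same-sized density map.
All convolutions are same-padded; input spatial dimensions must be
divisible by 2^n_blocks (3 blocks by default, so 8).

* **FCRN variant** — VGG-style downsampling path in which block *i*
  contains *i* convolution+ReLU layers followed by 2×2 max-pooling
  (1+2+3 = 6 convolutions at the default depth); a 1×1-convolution
  bottleneck in place of a fully connected layer; then a stack of UpConv
  units (stride-2 2×2 transposed convolution, ReLU, 3×3 convolution).
  The first convolution uses a 5×5 kernel for a larger early receptive
  field; all others are 3×3.
* **U-Net variant** — two 3×3 convolution+ReLU layers per block on the
  contracting path, a two-convolution bridge, and an expanding path that
  upsamples with a 2×2 transposed convolution, concatenates the
  same-resolution encoder features (one skip per level), and applies two
  more convolutions.

Feature maps start at `base_channels` (32 by default) and double at each
pooling step, mirrored on the way up. The final layer is a 1×1
convolution to one channel followed by a ReLU so predicted densities are
non-negative (configurable to linear). Weights use seeded orthogonal
initialization with zero biases; there is no batch normalization, no
dropout, and no pretraining — the intended data regime (a few hundred
images) cannot meaningfully move pretrained weights, so transfer
learning is deliberately out of scope.

The layers themselves (same-padded convolution, ReLU, 2×2 max-pool,
stride-2 transposed convolution) are implemented in NumPy with
hand-written reverse-mode gradients, evaluated as im2col plus one BLAS
matrix product in float32 and channels-last layout. Gradient correctness
is verified against central finite differences in float64. ReLU uses the
subgradient ReLU'(0) = 0; max-pooling routes the gradient to the first
maximum on ties. Because the whole stack is deterministic NumPy, two
runs with the same seeds agree bit for bit on one thread.

## Training protocol

* Random 80/20 train/test split of the dataset (simple random, not
  stratified), reproducible from a seed.
* Online augmentation: each epoch draws one of {none, horizontal flip,
  vertical flip} per sample, uniformly. Labels flip with the pixels, so
  counts are invariant; the flipped density target is computed by
  flipping the precomputed target, which is exact (see above).
* Each input patch is standardized to zero mean and unit standard
  deviation (a constant patch maps to zeros). Images larger than
  `patch_size` (256 by default) are center-cropped first, with out-of-window
  dots dropped.
* Loss: mean squared error between the predicted map and the density
  target, averaged over pixels and batch. Averaging (rather than summing)
  decouples the learning rate from image size.
* Targets are multiplied by a global `target_scale` of 100: unit-integral
  Gaussian targets have per-pixel magnitudes of order 1e-3, where
  float32 MSE gradients are poorly conditioned. Counting divides the
  scale back out, so reported counts are unaffected.
* Optimizer: momentum SGD, learning rate 0.01 divided by 10 every 10
  epochs, momentum 0.8, weight decay 0.005, batch sizes 1/8/16 in the
  comparison harness. The default epoch budget is 200 and every run in
  this repository states its own (the tests and the acceptance script
  use 30-epoch runs on the small synthetic task, where the schedule has
  already decayed the learning rate twice).

All randomness — split, shuffling, augmentation draws, initialization —
derives from explicit seeds; there is no hidden global state.

## Evaluation

Per-image counts are the integrals of the predicted maps, reported as
raw reals (no rounding — rounding would discard calibration
information). Aggregates are

    MAE  = (1/N) Σ |xᵢ − yᵢ|,    RMSE = sqrt((1/N) Σ (xᵢ − yᵢ)²),

so RMSE ≥ MAE always, with equality iff all absolute errors coincide.
Evaluation uses full frames (not patches) and the training-time
preprocessing. The comparison harness trains every
(architecture, batch size) cell on one shared split with one shared
initialization seed so the cell effect is isolated, and reports the
two-architectures-by-three-batch-sizes table as CSV. The all-zeros
predictor, whose MAE is the mean true count, serves as the scale
reference for the synthetic experiments.

## Synthetic data

The generator emulates the structure of the real imagery — small bright
grain-like blobs on a darker textured, unevenly lit background, with an
exact dot at each blob center — while making no attempt at photorealism.
A scene is built as: base gray level drawn from `background_level_range`;
low-frequency texture (Gaussian-filtered noise, σ = 8 px, ±15%
amplitude); a linear illumination ramp with random direction and
strength up to `illumination_gradient_max`; anti-aliased additive
ellipses with semi-axes from `grain_axis_range`, random orientation, and
brightness lift from `grain_intensity_range`; then white noise and
clipping to [0, 1]. Dot coordinates are the exact sub-pixel ellipse
centers, kept at least `min_center_margin` px from every border, and
optionally at least `min_center_separation` px apart (rejection
sampling). Defaults are 256×256 frames with 5–60 grains of semi-axes
2–5 px, matching the working resolution of the pipeline; the per-image
count range in the real data is not documented, so the default is a
configurable guess.

The scaled-down study conditions used by the tests and the acceptance
script are 64×64 frames with 5–15 well-separated grains (centers ≥ 6 px
apart, semi-axes 1.5–3 px, margin 8 px = the kernel truncation radius),
300 scenes split 240/80%-train vs 60/20%-test, and 30-epoch training
runs with `base_channels` 16 — sizes at which a full run of both
architectures completes in minutes on one CPU while still being a
genuine learning problem (the zeros baseline MAE is ~10 counts).

What passing on synthetic data does **not** show: robustness to real
fecal texture, moisture/specular effects, camera blur, perspective and
scale variation, annotation noise, or grains that differ in appearance
from smooth bright ellipses. Results on the synthetic task demonstrate
that the pipeline is implemented correctly and can learn to count, not
that it reaches any particular accuracy on farm imagery.

## Design choices where the design was open

* CSV point lists are the canonical annotation format; dots burned into
  marker images are an import path (8-connected components of
  near-marker-color pixels, one dot per component centroid). Points are
  lossless and testable; burned-in dots are not.
* The FCRN downsampling depth is 3 blocks with a 1×1 bottleneck standing
  in for the "fully connected as convolution" layer; the upsampling path
  mirrors the channel schedule.
* Checkpoints are NumPy `.npz` archives holding the architecture spec
  plus every parameter array; round-tripping is bit-exact.
* Validation errors name the offending field throughout, and every CLI
  command echoes its config into the output directory for provenance.

## Known limitations

* Training is CPU-bound and single-threaded NumPy; it is practical at
  the 64×64 study scale and at small channel counts, but a 256×256,
  base-32 run of 200 epochs is an overnight job, not a test.
* Bit-exact determinism is guaranteed within one BLAS configuration;
  different BLAS builds or thread counts may differ in the last float.
* Counts near borders are biased low by kernel truncation (documented
  above); adaptive or renormalized border kernels are out of scope.
* Sub-pixel dot placement is not modeled in the density targets (dots
  snap to pixels); at σ = 2 px this is negligible for counting.
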