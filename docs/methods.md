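# Methods

## Problem

Post-void residual (PVR) urine volume is routinely estimated from two
orthogonal B-mode ultrasound planes of the bladder.  `vesica` implements a
complete, self-contained version of an automatic pipeline for this task:
a lightweight multitask CNN detects and segments the bladder on the
sagittal and transverse planes, a geometric post-processor extracts the
three bladder axes from the two masks, and the volume follows from the
shape-coefficient formula

    volume ≈ c · depth · height · width        (axes in cm, volume in mL)

with `c` drawn from an empirical table (spherical 0.52, triangular prism
0.66, unknown 0.72, cylinder 0.81, cuboid 0.89).  Because no public image
set exists for this task, the package ships a synthetic phantom simulator
that provides exact geometric ground truth; every quantitative claim made
by the tests is computed on that simulator.

## Synthetic phantom simulator (`vesica.phantom_sim`)

The bladder is modelled as an ellipsoid with semi-axes `a, b, c` (mm),
a 3-D centre and a small random rotation; its volume is exactly
`(4/3)π·a·b·c`.  `sample_phantom` inverts this formula so a requested
volume is met to machine precision, with the two axis ratios drawn from a
configurable eccentricity interval ((0.7, 1.0) by default; (1.0, 1.0)
gives spheres for measurement protocols).

Images are rendered directly on the scan-converted grid (default 570×330
pixels at 0.35 mm/px, matching a ~200×115 mm field of view):

* **Background speckle** — fully developed speckle has exponentially
  distributed intensity (squared magnitude of a circular complex Gaussian
  scatter sum).  Pixels are drawn i.i.d. from
  `(1 − s) + s · Exp(1)` where `s` is `speckle_scale` (1 = fully
  developed, 0 = noise-free uniform limit used by oracle tests).
* **Anechoic lumen** — intensity inside the exact ellipse cross-section is
  multiplied by 0.03; optional posterior enhancement brightens the column
  below the lumen by 1.6.
* **Log compression** — `255·log1p(50·I)/log1p(200)` plus a gain offset,
  rounded to uint8.  Per-sample gain is drawn uniformly in ±15 counts and
  the depth setting rescales the pixel spacing, emulating knob variation.
* **Free-hand variation** — the phantom centre is placed uniformly at
  random within the in-view region, and each plane's cut may be offset
  from the true centre by up to 20 % of the corresponding semi-axis
  (disabled in oracle tests).

Masks are the exact rasterized cross-section interiors (pixel-centre
test), so the geometric ground truth is never corrupted by the noise
model.  A cosmetic sector crop is available (`sector_angle`); the default
view is rectilinear because a 70° sector cannot contain the cross-section
of a 300 mL bladder at the default spacing, and the crop never touches
the masks.

What the simulator does **not** model: spatially correlated speckle,
attenuation/shadowing, refraction, probe-geometry distortions, neighbour
organs, or annotation noise.  Passing tests therefore demonstrate that
the pipeline is implemented correctly and recovers geometry under
realistic intensity statistics — not that the network would reach the
same Dice on clinical images.

## Network (`vesica.net_arch`)

Input: a single-channel image resized bilinearly to 192×192 and scaled to
[0, 1].  The shared encoder is a single-channel MobileNetV2 (width 1.0)
truncated immediately after the last stride-16 bottleneck stage with 96
channels, so the encoder output is 12×12×96.

Segmentation path: two parallel branches over the encoder map —

* **QSE branch** (two quantizable squeeze-and-excitation blocks,
  96→256→256).  A QSE block global-averages the map to a 1×1×C squeeze
  vector, tiles it back to 12×12×C, concatenates with the input
  (12×12×2C) and mixes with a 1×1 convolution + batch norm + ReLU6.
  Classic SE gating multiplies two activation tensors, which per-tensor
  8-bit affine pipelines handle poorly; QSE injects the same global
  channel context through convolution weights only, and a graph audit
  verifies the model contains no activation×activation product.
* **Detail branch**: two stacked depthwise-separable 3×3 blocks
  (96→256→256).  Separable convolutions are used here because two dense
  3×3 convolutions at 256 channels would by themselves exceed the
  parameter budget below.

The branches are concatenated (12×12×512), merged by one
depthwise-separable block to 12×12×256, reduced by a 1×1 convolution to
the two pixel classes, upscaled ×16 bilinearly to 192×192×2 and passed
through a per-pixel softmax.  The classification path is global average
pooling (1×1×96) → dense → 2-way softmax.  ReLU6 is used throughout
(quantization-standard), batch normalization after every convolution.

Parameter account (default config): backbone 541 952, segmentation path
413 986, classification head 194 — **956 132 trainable parameters**,
under the hard 1 M budget enforced by `build_model`, with exact
closed-form per-layer accounting checked against the stored tensors.

The graph is built on a small numpy layer library (`vesica.nn`) with
analytic backprop, verified against finite differences in the test suite.

### Resolution transfer

Every layer is convolutional or globally pooled, so one set of weights
runs at any input size divisible by 16.  The standard protocol trains the
bulk of the segmentation stage at 96×96 (4× cheaper per epoch), then
fine-tunes it for a few epochs at 192×192 (progressive resizing, reduced
rate 3e-4) before training the classification head, calibrating and
quantizing at 192×192, where the segmentation logit grid is finest
(12×12).  The fine-tune matters: without it the boundary placement
learned on the 6×6 logit grid biases the axes of small bladders by
several percent.

## Training (`vesica.train_quant`)

Three stages: (1) segmentation path + shared backbone trained on
bladder-positive images only (masks exist only for those); classification
head frozen.  (2) classification head trained on positives + negatives
with backbone and segmentation path frozen.  (3) the two weight sets are
merged — backbone/segmentation from stage 1, head from stage 2.  Because
stage 2 cannot touch the shared backbone, the merged model reproduces
each stage's output bit for bit (asserted in tests).

Stage 2 runs the frozen backbone in inference mode, so the head is fitted
to the exact deployment-time features (batch statistics would otherwise
shift under the merged running statistics).  With augmentation disabled —
the 194-parameter head does not overfit — the pooled features are
computed once and cached, making stage 2 essentially a logistic
regression fit.

Losses: segmentation uses the combo loss
`α·CE + (1 − α)·(1 − softDice)` with `α = 0.5` by default (balanced
mixing; configurable); softDice is `2Σp·y/(Σp + Σy)` without a smoothing
term, defined as 1 when both masses vanish.  Classification uses plain
cross-entropy.  Optimization is Adam (initial rate 1e-3 for stage 1,
1e-2 for the cached head), reduce-on-plateau scheduling (factor 0.5,
plateau patience 5) and early stopping with patience 20 epochs; the best
validation-loss weights are restored.  Augmentation: random intensity
shift (±10 counts) and random left–right flip applied jointly to image
and mask.

Quantization-aware training rounds every weight tensor to the symmetric
signed 8-bit grid in the forward pass with straight-through gradients.

## 8-bit quantization

`quantize_model` folds batch norm into the preceding convolutions, fixes
per-tensor symmetric int8 weight codes (scale = max|w|/127), runs a
calibration batch to record per-node activation ranges, and emits a model
whose inference applies per-tensor affine (0–255, zero-point) activation
quantization after every node.  Inference is simulated on the exact
de-quantized values, so it is bit-deterministic.  A degenerate (constant
zero) calibration range falls back to scale 1 with a warning.  The
quantized model serializes to an `.npz` of int8 codes, scales, biases and
activation ranges and round-trips exactly.

## Axis detection and volume (`vesica.measure`)

All geometry runs in pixel units on the largest 8-connected component of
the mask; millimetres enter only through the pixel spacing, and
centimetres only inside the volume formula.

* **Depth (sagittal)** — the minimum-*area* rotated bounding rectangle of
  the region (rotating calipers over the convex hull of the boundary
  pixels' corner points; an axis-aligned mode exists for comparison).
  Both box diagonals are sampled at 0.25 px steps; each chord spans the
  outermost pair of mask intersections (robust to re-entrant contours),
  and the longer chord is the depth.  Ties go to the diagonal leaving the
  topmost(-leftmost) corner.  On rasterized shapes the minimum-area box
  may legitimately tilt a few degrees relative to the analytic shape; the
  axis-aligned mode reproduces analytic chord values exactly.
* **Height / width (transverse)** — maxima over columns/rows of the
  first-to-last foreground extent ("maximum distances" reading); a
  centre-chord mode is available behind a flag.
* **Gating** — when a model is supplied, both planes must be classified
  bladder-positive, otherwise no volume is emitted (an invalid
  segmentation must not reach the user).  `model=None` injects the
  ground-truth masks and labels: the geometry-only oracle route.

For a perfect sphere the coefficient 0.52 under-estimates π/6 ≈ 0.5236 by
0.69 % — the irreducible bias of the coefficient formula.  The "unknown"
coefficient is 0.72 (the value the measurement table validates; the
literature also quotes 0.7, which we do not use).

## Evaluation (`vesica.metrics_eval`, `vesica.study`)

Dice (empty-vs-empty defined as 1.0, a convention that never triggers on
bladder-positive evaluations), 2×2 confusion matrix/accuracy, and signed
percent volume errors (magnitudes in summaries).  `evaluate_run` follows
the repeated-measurement protocol: each nominal volume is re-rendered and
re-measured `n_repeats` times (default 5).

`vesica.study.run_synthetic_study` is the standard reduced-scale
experiment used by the acceptance script: 128 positive + 128 negative
biplane pairs (256 + 256 plane images, 80/20 train/val), stage 1 for 14
epochs at 96 px plus a 4-epoch fine-tune at 192 px, head + quantization
at 192 px, then 10 measurements each
of spherical 50/150/300 mL phantoms with c = 0.52, through the quantized
model and through the oracle-mask route.  These sizes are the package's
chosen desk-scale protocol: large enough for stable behaviour, small
enough for a single CPU in a few minutes.

## Numerical choices and edge cases

* Probabilities are clipped at 1e-7 inside losses.
* Early-stopping improvement is strict (`< best − 1e-9`).
* Chord sampling uses ≥ 4 samples per pixel of segment length; fewer than
  two in-mask samples raises a degenerate-region error naming the plane.
* Masks with fewer than three distinct boundary corners cannot support a
  rotated box and raise a no-region error.
* The two box diagonals tie exactly on circles; the deterministic pick is
  the diagonal from the first (topmost) corner.
* Dataset generation, training, quantization and measurement are pure
  functions of their seeds; one global seed fans out to stage seeds via
  `numpy` seed sequences.

## Known limitations

* The speckle is spatially white; real speckle has a correlation cell set
  by the point-spread function, making real boundaries blurrier.
* Bladder-free images contain pure speckle, so synthetic classification
  is easier than clinical PVR detection (accuracy near 1.0 is expected
  here and should not be read as a clinical claim).
* Quantized inference is simulated in float on de-quantized values; true
  integer kernels (and their rounding-mode quirks) are out of scope.
* The measurement protocol assumes near-spherical phantoms when using
  c = 0.52; strongly eccentric bladders need a different coefficient, and
  the coefficient choice dominates the error budget.
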