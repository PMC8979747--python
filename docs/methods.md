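# Methods

This note documents the models and procedures implemented in `dyndet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

The package targets lesion detection in grayscale medical images with a
two-stage detector (region proposal network + Box_Head) and focuses on three
training-time components:

1. **Dynamic label assignment.** A proposal is a second-stage positive iff
   its maximum IoU over the ground-truth boxes reaches the current threshold
   `T_now` (boundary inclusive). Early proposals are poor, so a low fixed
   threshold is needed to harvest positives at all; late in training the same
   threshold floods the head with mediocre positives. `T_now` therefore
   tracks proposal quality: each iteration the K_I-th largest
   proposal-to-ground-truth IoU is recorded, and once per cadence the
   threshold is reset to `max(T_now, mean(recorded))`, clamped.

2. **Dynamic balanced Smooth L1 (DBS L1) regression loss.** On the absolute
   regression error `x` (normalized box-delta space),

       L(x) = (a/b)(bx + 1) ln(bx + 1) - a x   for x < a,
       L(x) = x + C                            otherwise,

   where `a = alpha_now`. Requiring value- and gradient-continuity at
   `x = a` with outer slope 1 pins the constants: `a ln(ba + 1) = 1` gives
   `b = (e^{1/a} - 1)/a` in closed form, and `C = 1/b - a^2`. Relative to
   the quadratic inlier branch of Smooth L1, the logarithmic branch puts a
   much steeper gradient on small errors — and increasingly so as `a`
   shrinks — so well-localized ("high-quality") samples keep contributing
   as training sharpens. `alpha_now` tracks the error distribution the same
   way `T_now` tracks IoUs: per iteration the K_alpha-th *smallest* absolute
   regression error of the foreground proposals is recorded; once per
   cadence `alpha_now := min(alpha_now, median(recorded))`, clamped, and
   `(b, C)` are re-solved.

   The one-way update rules (`max` for the threshold, `min` for the factor)
   follow the reference dynamic-training implementation: both quantities are
   meant to track a one-way drift (proposals improve, errors shrink), and
   plain re-assignment lets one noisy window undo earlier progress — at CPU
   scale we observed the factor sequence 1.0 → 0.84 → 0.98 → 0.42 under
   plain assignment. With the one-way rule the monotone trajectories are
   structural.

3. **Self-calibrated convolution.** A channel-preserving block that splits a
   (C, H, W) map into halves, computes a context signal for the first half
   in a downsampled space (average pooling rate `r`, one convolution,
   bilinear upsampling back to (H, W)), gates the half's convolution
   response with `sigmoid(X1 + context)`, refines with a second convolution,
   and concatenates with a plain convolution of the other half. The four
   filter groups have shape (C/2, C/2, k, k), so the block costs roughly the
   same as the (C, C, k, k) convolution it replaces (it has exactly C fewer
   parameters than a biased plain convolution). By default the block
   replaces the 3x3 convolution in the RPN head; placement in the last
   backbone stage is a config option.

## Defaults and open choices

The emulated study states: input 512x512, 12 epochs, SGD lr 0.01, momentum
0.9, weight decay 1e-4, softmax cross-entropy for classification, and an
initial loss factor of 1.0. Everything else is our choice:

- **Dynamic schedules**: `K_alpha = 10`, `K_I = 75` per batch, shared
  cadence 100 iterations, `alpha` clamped to [0.05, 1.0] (the floor keeps
  `e^{1/alpha}` representable), `T_now` initial 0.4 clamped to [0.4, 0.9].
  The initial threshold matters under the one-way rule: starting at 0.5
  leaves the box regressor training almost exclusively on the appended
  ground-truth boxes early on (whose regression targets are zero), so it
  never learns to correct imperfect proposals; 0.4 is also the reference
  implementation's starting point.
  The first cadence window doubles as warm-up. On an iteration with no
  foreground proposals the current `alpha` is recorded as a neutral
  statistic so both cadence buffers flush on the same iterations.
- **Loss branch point**: the linear branch is `x + C` with slope exactly 1;
  a free outer slope would change `(b, C)`.
- **Statistics source**: schedule statistics are computed on genuine RPN
  proposals only. Ground-truth boxes are appended to the proposal set for
  sampling (standard practice so the head always sees positives), but their
  IoU of 1 and regression error of 0 would otherwise saturate both
  schedules immediately.
- **Detector plumbing** (the study is silent): 9 anchors (scales 2/4/8
  stride-units, ratios 0.5/1/2), RPN NMS 0.7 with 100 train / 50 test
  proposals kept, 64 RoIs per image at 1:3 positive ratio, class-agnostic
  box regression with (0.1, 0.1, 0.2, 0.2) delta standardization, head NMS
  0.5, score threshold 0.05, gradient-norm clipping at 35, and a step
  learning-rate schedule (x0.1 at 3/4 and 11/12 of the epochs).
- **Backbone and head**: a four-stage convolution stack (5x5 stem then 3x3,
  channels 16/32/64/64, total stride 8) sized so the full pipeline trains
  on one CPU. The Box_Head reads hypercolumn RoI features (6x6 bins, 2x2
  bilinear samples per bin, from both the stride-4 and stride-8 maps — the
  fine texture that separates the lesion classes does not survive to stride
  8 in so shallow a network) through two 256-unit fully connected layers.
  Deep pretrained backbones are out of scope (no framework, no weights), so
  the config rejects anything but `small-conv`.
- **SC-conv details**: pooling rate defaults to 4 (the original
  self-calibrated design), 'same' zero padding (the calibration sum
  requires shape compatibility), bilinear upsampling with the half-pixel
  convention, contiguous channel split, no normalization or extra
  nonlinearity inside the block, and the gate is `sigmoid(X1 + X1')`
  applied multiplicatively to the K3 response (the published formula's
  grouping is ambiguous; this reading matches the original design).
- **Numerical layer**: training runs through a small reverse-mode autodiff
  engine on numpy (im2col convolutions, matrix-based bilinear resampling,
  matrix-gather RoIAlign). Every operator's
  gradient is verified against central finite differences in the tests.
  Fixed seed + fixed data gives bit-identical trajectories on one CPU.

## Synthetic phantoms

The generator emulates the *structure* of the emulated study's private CT
data, not its appearance: grayscale images, 1-3 boxed lesions per image,
three classes with ~7 : 2.6 : 1 imbalance (defaults 2273/845/324), balanced
by 1x/3x/8x oversampling where every copy beyond the first is passed through
one random augmentation (flips, rotation +-15 deg, shear +-10 deg, gamma in
[0.7, 1.5], histogram equalization). The classes differ by shape/texture
family: smooth bright ellipses, star-shaped lesions with a deep
cosine-modulated margin (5-9 arms, angular amplitude 0.42 of the base
radius — deep enough that the arms survive edge smoothing at the 96-pixel
benchmark scale; a probe classifier on ground-truth crops separates the
three classes at ~93%), and compact clusters of small bright foci under a
single box (foci within 0.6 base radii of the cluster center, so the box is
dominated by lesion rather than background). Boxes
are tight around the binary lesion mask. Geometric augmentations update
boxes by mapping the box's inscribed ellipse through the same affine map
used to warp the image (for the elliptical-ish lesions this tracks the
warped mask far more tightly than mapping box corners, whose hull inflates a
rotated square by ~22% at 15 degrees); flips map corners exactly.
Oversampling is applied to the training split only, after a stratified
70/15/15 split (the emulated protocol does not say on which side of the
split it ran; training-only avoids leakage of augmented replicas).

What passing tests on phantoms do **not** show: performance on real CT
(anatomy, scanner noise, ambiguous lesion margins, annotation noise are all
absent), nor anything about the GPU-scale accuracy numbers of the emulated
study, which require its private data.

## Scaled benchmark

`dyndet.experiments.phantom_benchmark` runs the full protocol at CPU scale:
a pool of 250 phantoms at 96x96 with the study's imbalance (165/61/24),
stratified 200 train / 50 held out, training-split oversampling (1x/3x/8x,
giving ~430 training images), the 12-epoch SGD recipe above, and AP50/AP75
evaluation on the held-out images (mAP = mean of the six per-class cells).
These problem sizes are the package's benchmark conditions; one run takes a
few minutes on one CPU. The acceptance script runs the benchmark twice
(DBS L1 and plain Smooth L1) under identical seeds as a non-inferiority
comparison — at this scale the dynamic loss is expected to match or beat
Smooth L1, not to reproduce the study's GPU-scale margins.

## Known limitations

- AP uses all-point interpolation; 11-point or 101-point interpolation
  would differ slightly on sparse synthetic evaluations (the six-cell mAP
  aggregation is interpolation-free arithmetic).
- Detection-score ties are broken by detection order (documented, stable).
- The dynamic threshold is applied to the second stage only; whether it
  should also gate RPN sampling is left as a config-free design decision
  (the RPN keeps fixed 0.3/0.7 thresholds).
- `r > min(H, W)` in the self-calibrated block is clamped to the map size
  inside the detector (tiny test maps); the functional API rejects it.
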