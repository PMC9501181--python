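# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, the numerical conventions, and what the
synthetic-data experiments do and do not demonstrate.

## Network

The segmentation network is a bilateral encoder-decoder. Both encoder
branches consume the same preprocessed image (`224 × 224 × 3`, values in
[0, 1], grayscale replicated to three channels).

### Semantic branch (windowed self-attention)

Patch partition is a 4 × 4 stride-4 convolution with 48 kernels; a linear
embedding lifts tokens to 96 channels, followed by layer normalization.
Three attention blocks at 96/192/384 channels alternate with patch-merging
layers (2 × 2 neighbourhood concatenation, pre-norm, linear 4C → 2C without
bias), producing 56² × 96 → 28² × 192 → 14² × 384 → 7² × 768.

Each block is a pair of pre-norm residual stages: plain window attention
(W-MSA), then shifted-window attention (SW-MSA), each followed by a 2-layer
MLP (expansion 4, GELU). Attention within a window of M² tokens is
`softmax(QKᵀ/√d + B)V` per head, with a learned relative-position bias
table of (2M − 1)² entries per head indexed by the token-pair offset.

Open choices and how they were fixed:

* **Window size.** M = 7 at every stage. 56/28/14 are all divisible by 7,
  and the *relative* window coverage grows with depth (a 7-token window
  spans 1/8 of the map at stage 1 but 1/2 at stage 3), which preserves the
  intended coarse-to-global progression without a per-stage schedule. When
  a map is smaller than M on both sides (possible in reduced desk-scale
  configurations), attention falls back to a single full-map window and
  the shift becomes a no-op.
* **Divisibility.** Maps not divisible by M are right/bottom zero-padded
  before partitioning and cropped after the inverse; padded tokens take
  part in attention as zeros.
* **Shift and mask.** The shifted stage rolls the map by ⌊M/2⌋ and adds
  −100 to the pre-softmax score of token pairs of which exactly one was
  carried across the image border by the roll (per axis). Labels are
  assigned in rolled coordinates by the three-slice scheme; the tests
  verify the mask against a first-principles wrap oracle and verify
  roll-equivalence of the shifted stage with the mask disabled.
* **Heads.** 3/6/12 heads at 96/192/384 channels, d = C/heads — the usual
  doubling schedule for hierarchical attention encoders.
* **Initialization.** Truncated normal (σ = 0.02, clipped at 2σ) for
  attention and MLP weights and the bias table; layer-norm ε = 1e−5.
  All randomness flows from `ModelConfig.random_seed`.

### Detail branch (depthwise-separable CNN)

Stem: two 3 × 3 stride-2 convolutions to 112² × 16 and 56² × 96. Four
bottleneck feature-extraction modules follow: 1 × 1 reduce (C → C/4, no
activation) → depthwise-separable 3 × 3 (stride 1 or 2, ReLU6) →
depthwise-separable 3 × 3 (no activation) → 1 × 1 expand (ReLU6), with a
residual shortcut exactly when stride 1 and equal channel counts make the
shapes agree. Every convolution is followed by batch normalization
(ε = 1e−5, momentum 0.1); the two deliberately linear positions are the
documented exception to the ReLU6 default. The bottleneck ordering
(reduce first, expand last) follows from the stated roles of the two
1 × 1 convolutions; the reduction ratio 4 is the conventional residual
bottleneck. Depthwise-separable layers keep the parameter count strictly
below a dense 3 × 3 convolution of the same width (asserted in tests).

### MFIEM and CAMM

The multiscale module runs three parallel 3 × 3 convolutions at dilation
rates {1, 2, 3} with same-padding (a rate-r kernel spans 2r + 1 pixels),
concatenates to 3C channels and re-projects with a 3 × 3 convolution. Its
spatial gate is a single-channel 1 × 1 convolution + sigmoid multiplied
over all channels — one channel because the calibration is purely spatial.

The channel-attention module pools two directional descriptors: max over
width then mean over height, and mean over height then mean over width.
Each 1 × 1 × C descriptor passes an independent squeeze/restore pair of
1 × 1 convolutions (ratio 16, ReLU between), the two are summed, and a
sigmoid yields per-channel weights in (0, 1). Collapsing each branch's
remaining spatial axis by mean *before* the convolutions makes the module
a pure channel attention; a coordinate-attention-style broadcast add was
the plausible alternative, rejected because the module's output contract
is a per-channel reweighting.

### Decoder and fusion

Four decode blocks (1 × 1 reduce to C/4 → stride-2 transposed convolution
→ 1 × 1 project) take the semantic output through 14² × 384 → 28² × 192 →
56² × 96 → 112² × 48; detail skips are fused by elementwise addition at
the three matching resolutions (the decoder's designed output widths
mirror the detail branch's intermediate widths exactly, which is what
makes additive fusion the natural reading). A 3 × 3 convolution to
112² × 16 and a final transposed convolution produce 224² × 1 logits;
`sigmoid ≥ 0.5` (ties to foreground) binarizes them.

**Transposed-convolution kernel.** All ×2 upsamplers use kernel 4,
stride 2, padding 1. The kernel-3/output-padding-1 variant (also
implemented) covers output pixels with alternating numbers of kernel taps;
in controlled runs this checkerboard imbalance measurably slowed the
convergence of the Dice loss (final loss ≈ 0.22 vs ≈ 0.11 after 200
identical steps), so the uniform kernel-4 form is the default.

## Loss and metrics

Training minimizes the smoothed soft Dice loss
`1 − (2Σpg + ε)/(Σp + Σg + ε)` with ε = 1, computed on sigmoid
probabilities over the batch; the smoothing keeps the loss defined on
empty masks. Optimization is Adam (lr 0.001, β = (0.9, 0.999), ε = 1e−8),
constant learning rate, no augmentation by default, batch 32 for 50 epochs
in the full recipe, 7:1:2 seeded train/val/test split (floor for train and
val, remainder to test). The best checkpoint is selected by validation
MIOU.

MIOU, F1 and NICE2 are computed per image and averaged (a pooled-pixel
aggregation is available as an option); per-image averaging matches the
1/n Σ form of the MIOU definition. Degenerate conventions: an image with
empty ground truth and empty prediction scores IoU = F1 = 1; an empty rate
denominator contributes 0 to NICE2. These keep the statistics defined on
synthetic edge cases and preserve the monotonicity properties asserted in
tests (correcting any single mispredicted pixel never worsens a metric).

## Numerical backbone

Gradients come from a tape-based reverse-mode autodiff engine written on
numpy (`irisseg.autodiff`): batched matmul, im2col-based 2-D convolution
(stride/padding/dilation/groups) and its transpose, softmax, sigmoid/
ReLU6/GELU, reductions with broadcasting-aware backward, gather for the
bias table, and roll/pad/slice layout ops. Every primitive and the fully
assembled network are verified against central finite differences in
float64 (the engine preserves input dtype; training runs in float32).
Checkpoints are single `.npz` files containing weights, batch-norm running
statistics and the serialized model configuration.

## Synthetic data

The generator emulates the two acquisition regimes the segmentation task
must bridge: NIR-style grayscale close-ups (320 × 240) and visible-light
RGB captures (400 × 300). Each sample is a pure function of its parameter
spec and seed: sclera background, iris annulus textured by a band-limited
radial sinusoid plus a Gaussian-filtered random field, dark pupil,
parabolic upper/lower eyelid occluders (coverage parameter c moves the lid
chord linearly from the iris edge, curvature 0.35·r so that c = 0 occludes
nothing), eyelash strokes, specular highlights, additive Gaussian noise.
The ground-truth mask is the *visible annulus only* — pupil and
eyelid-occluded pixels are background; lashes and highlights overdraw the
image but not the mask, mimicking how real ground truths treat thin
occluders inconsistently. Default sampling ranges give masks occupying
roughly 2–20 % of the image (empirically 4–16 % over 60 draws).

What the generator does *not* emulate: real iris micro-texture statistics,
sensor noise models, off-axis gaze, motion blur, or annotation error.
Passing the synthetic suites therefore demonstrates that the architecture,
gradients, training loop and metrics are correctly wired and that the
model has the capacity to fit iris geometry — not that it reaches
state-of-the-art accuracy on licensed iris databases, which requires the
full 224-px/50-epoch recipe on real data.

## Desk-scale experiment sizes

CPU-friendly problem sizes used by the tests and the acceptance script:

* **Overfit run:** 16 synthetic images (half NIR, half visible, dataset
  seed 0), full-width architecture (15.5 M parameters) at 64 × 64 input,
  batch 2, 200 Adam steps at lr 0.001. Width is kept full because
  convergence speed within a fixed step budget depends on width far more
  than on input resolution (width/4 at 224 px and width/2 at 128 px both
  converge markedly slower than full width at 64 px). Typical outcome:
  final train-set Dice loss 0.09–0.19, train-set MIOU 0.92–0.95 across
  seeds.
* **Structural tests:** width/4 at 64 px or width/8 at 32 px variants of
  the same topology (`ModelConfig.scaled`).
* The full-size 224-px network is exercised by a single instrumented
  forward pass that audits all 22 designed layer shapes.

## Known limitations

* Batch normalization with batch size 2 gives noisy statistics; the full
  recipe's batch 32 is preferable whenever memory allows.
* The attention fallback for maps smaller than the window changes the
  effective receptive field in aggressively scaled configurations.
* CPU training of the full 224-px recipe is possible but slow (~5 s per
  step); the package is written for desk-scale experimentation and for
  studying the architecture, not for production training throughput.
* Only binary (iris vs background) segmentation is supported.
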