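# irisseg

Pixel-accurate iris segmentation for heterogeneous eye images — a hybrid
encoder-decoder that pairs a **windowed self-attention semantic branch**
(global context) with a **depthwise-separable CNN detail branch** (fine
texture), refined by multiscale dilated convolutions and spatial/channel
attention gates. The package is aimed at researchers working on iris
biometrics or ophthalmic image analysis who need a segmentation backbone
that transfers across acquisition conditions (near-infrared close-up
sensors vs. unconstrained visible-light cameras), plus everything required
to exercise it end to end without downloading licensed iris databases: a
deterministic synthetic eye-image generator, a Dice-loss training loop on a
self-contained numpy autodiff engine, and the field's standard evaluation
statistics.

## The model

The encoder runs two branches over a `224 × 224 × 3` input.

**Semantic branch.** The image is tokenized into 4 × 4 patches by a strided
convolution (48 kernels), lifted to 96 channels by a linear embedding, and
processed by three windowed-attention blocks interleaved with patch-merging
downsamplers (each halves H, W and doubles C), ending at `7 × 7 × 768`.
Attention inside a window of M × M patch tokens is

    Attention(Q, K, V) = softmax(Q Kᵀ / √d + B) V ,   Q, K, V ∈ ℝ^{M²×d}

with a learned relative-position bias `B`. Each block applies two pre-norm
residual stages

    z ← W-MSA(LN(z)) + z ;  z ← MLP(LN(z)) + z        (plain windows)
    z ← SW-MSA(LN(z)) + z ; z ← MLP(LN(z)) + z        (windows shifted by ⌊M/2⌋)

where the shifted stage cyclically rolls the map and masks attention
between token pairs carried across the image border, letting information
flow between windows.

**Detail branch.** Two stride-2 3 × 3 convolutions (224 → 56), then four
bottleneck feature-extraction modules (1 × 1 reduce → depthwise 3 × 3 →
depthwise 3 × 3 → 1 × 1 expand, residual shortcut when shapes match) down
to `14 × 14 × 384`. A multiscale module (parallel 3 × 3 convolutions at
dilation rates {1, 2, 3}, concatenated and re-projected, gated by a
single-channel spatial sigmoid map) and a channel-attention module (two
directional global-pooling branches → per-channel sigmoid weights) refine
the final map.

**Decoder.** Four decode blocks (1 × 1 reduce → stride-2 transposed
convolution → 1 × 1 project) upsample the semantic output `7 → 112`,
fusing the detail branch's skip features by elementwise addition at
`14 × 14 × 384`, `28 × 28 × 192` and `56 × 56 × 96`; a 3 × 3 convolution
and a final transposed convolution emit one logit per input pixel.
Training minimizes the smoothed soft Dice loss with Adam (lr 0.001, batch
32, 50 epochs in the full recipe).

**Evaluation.** For per-image pixel counts TP, FP, FN, TN:

    MIOU  = mean_i  TP / (TP + FP + FN)
    F1    = mean_i  2·TP / (2·TP + FP + FN)
    NICE2 = mean_i  ½ · ( FN/(FN+TP) + FP/(FP+TN) )      (lower is better)

## Worked example

`examples/train_and_evaluate.py` generates 16 synthetic eye images
(half NIR-style grayscale, half visible-light RGB), trains the full-width
network at 64 × 64 input for 200 Adam steps and evaluates on the training
set:

```text
model: 15,499,660 parameters at 64x64 input
steps   0- 39: mean dice loss 0.732
steps  40- 79: mean dice loss 0.582
steps  80-119: mean dice loss 0.391
steps 120-159: mean dice loss 0.232
steps 160-199: mean dice loss 0.139
final train-set dice loss: 0.104
train-set MIOU=0.946  F1=0.972  NICE2=0.013
```

The loss falls from the no-overlap regime (~0.8) to ~0.1 and the model
recovers ~95 % of the iris annulus pixels — evidence that the architecture,
loss and optimizer wiring are sound. The other examples narrate individual
capabilities: `architecture_walkthrough.py` (the 22-row shape audit of the
full-size network), `generate_fixtures.py` (the synthetic dataset and its
manifest), `metrics_walkthrough.py` (the statistics on a hand-checkable
confusion example).

A command-line interface covers the same workflow on real datasets
(images in `data/images`, same-stem masks in `data/masks`):

```bash
seg-synth --n 100 --mix 0.5 --out data --seed 0
seg-train --config run.yaml
seg-eval  --config run.yaml --checkpoint checkpoints/best.npz
seg-predict --checkpoint checkpoints/best.npz --image eye.png --out mask.png
```

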