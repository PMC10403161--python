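# Methods

## Problem and model

The package localizes the anterior cruciate ligament (ACL) tear region in
knee MR slices as a binary semantic-segmentation problem: each 128×128×3
input slice maps to a per-pixel probability of belonging to the
radiologist-delimited rectangular region of interest (ROI). The network,
MGACA (multi-scale guided-attention context aggregation), is a modified
DeepLabv3+: a VGG19-style convolutional encoder, an atrous spatial pyramid
pooling (ASPP) head whose dilated branches carry guided attention, channel
recalibration by squeeze-and-excite (SE) blocks, and a decoder that fuses a
projected copy of the encoder's feature-map layer before a spatial attention
gate and a sigmoid head.

Because no deep-learning framework is a dependency of this package, the
network runs on a compact reverse-mode automatic-differentiation engine
written on numpy (`mgaca.nn`): stride-1 "same"-padded dilated convolutions
via im2col, 2×2 max pooling, batch normalization (Keras-convention momentum
0.99, epsilon 1e-3), matrix-based bilinear/nearest resampling, and Adam.
Conventions mirror Keras (NHWC layout, (k,k,in,out) kernels, He-normal
initialization) so the architecture tables translate directly.

## The frozen architecture

Several structural details of the published description are underdetermined
(which encoder stage feeds the ASPP, which tensors enter the ASPP
concatenation, filter widths of the decoder, bias/normalization placement).
The published trainable-parameter total, 22,877,922, acts as an
architecture-fidelity oracle: we enumerated the design space consistent with
the printed block algorithms and kept the unique configuration that both
matches that total exactly and agrees with the block descriptions on every
decidable point. The frozen graph is:

- **Encoder** — VGG19 conv stages 1–3 (64/128/256 channels, 2/2/4 convs,
  each followed by 2×2 max pooling); the feature-map layer is the third
  pooling output (256 channels, stride 8). Encoder weights are trained from
  random initialization; requesting pretrained weights falls back to random
  initialization with a warning so builds are self-contained.
- **ASPP** (input 256 ch, output 256 ch) — four computation paths:
  image-level global average pooling → 1×1 conv (256) → bilinear upsample;
  1×1 conv (256) + BN + ReLU; 3×3 conv at dilation 6 (256) + BN + ReLU with
  a guided-attention block; 3×3 conv at dilation 18 (1024) + BN + ReLU with
  a guided-attention block. The concatenation carries the pooled branch, the
  1×1 branch, the *raw* dilation-18 tensor, and both attended tensors
  (256+256+1024+256+1024 = 2816 channels), then a 1×1 conv projects to 256.
  Carrying the raw dilation-6 tensor as well is available as a config switch
  (`aspp_include_raw`).
- **Guided attention block** — sigmoid weights from a full-channel 1×1 conv
  gate the dilated features; the gated tensor is concatenated with the
  block's input and fused by a 3×3 conv + BN + ReLU.
- **Decoder** — SE(256) on the ASPP output; the feature-map layer itself is
  projected by a bias-free 1×1 conv to 48 channels (+BN+ReLU) and
  concatenated (304 ch); SE(304); two bias-free 3×3 convs (512 then 256,
  each +BN+ReLU); SE(256); a 1-channel 1×1-conv sigmoid spatial gate
  multiplies the features; bilinear upsample ×8 to input resolution; 1×1
  conv head with sigmoid. SE blocks use reduction ratio 8 with two bias-free
  dense maps (2C²/8 parameters each).

The published description applies a softmax to the single-channel output,
which is identically one; the default is therefore a sigmoid head, with a
two-channel softmax mode (`output_activation="softmax2"`) retained for
fidelity experiments.

`width_multiplier` scales every channel width, rounding up to a multiple of
the SE ratio so all bottlenecks stay well-formed on the documented grid
(0.125, 0.25, 0.5, 1); multiplier 1 reproduces the published widths
exactly. Dropout (default off, rate 0.1 when enabled) sits after the two
decoder convolutions; it has no parameters, so parameter counts are
unaffected.

## Ablation surface

Seven named variants, each a single structural edit (all have strictly fewer
parameters than the full graph): `no_attention` (drop dilated-branch
attention, SE, and the spatial gate), `no_aspp` (replace the ASPP with a 1×1
conv + BN + ReLU), `spatial_only` / `channel_only` / `mixed_only` (keep
exactly one of the three attention mechanisms), `single_scale` (attention at
dilation 6 only), `no_guidance` (remove all sigmoid gating while keeping the
convolutions). When a dilated branch loses its attention block, its raw
tensor still enters the concatenation so multi-scale context is preserved.

## Losses and metrics

Evaluation uses micro-aggregated pixel confusion counts at threshold 0.5
over the evaluated split: accuracy, precision, recall, F1, IoU = TP/(TP+FP+FN)
and Dice = 2TP/(2TP+FP+FN), so Dice = 2·IoU/(1+IoU) identically. Degenerate
0/0 overlap ratios resolve to 1 (empty truth matched by empty prediction)
and 0/0 precision/recall to 0. The training objective is the unit-weight sum
of mean binary cross-entropy (probabilities clipped to [1e-7, 1−1e-7]) and
soft Dice loss 1 − (2Σtp+ε)/(Σt+Σp+ε) with ε = 1e-6; evaluation uses hard
counts, training the soft probabilities.

## Training protocol

75/25 train/validation split via `sklearn.train_test_split` at random state
42 (15,265 items split to 11,448/3,817); mini-batches of 32 pairs resized to
128×128 and scaled to [0,1] (bilinear for images, nearest for masks so they
stay binary); Adam at initial rate 0.001; reduce-on-plateau (factor 0.2,
patience 2 epochs, min-delta 0, floor 1e-5) and early stopping (patience 10)
both monitor validation loss with strict-improvement comparisons; maximum
100 epochs by default. Non-finite loss aborts with the last learning rate
and step index. Runs are seeded end to end (init, shuffling, dropout).
Data augmentation is not implemented.

## Synthetic fixtures

The generator reproduces only the statistical structure the pipeline
consumes: grayscale-in-RGB JPEG slices (quality 95) whose background is
blurred low-frequency noise around intensity 0.35, one brighter rectangle
per injured volume present exactly on the slices of its z-extent, balanced
contrast-free control volumes, the ROI metadata CSV, and lossless PNG
reference masks. The blurred rectangle is rescaled so the inside-outside
mean separation equals the configured contrast exactly before noise.
Defaults mirror the study conditions — 917 volumes of 320×320 slices,
control fraction 0.5, 3–30 slices per volume (≈15k slices in expectation),
ROI edges 60–180 px, contrast 0.35, noise SD 0.08 — with `easy()` (contrast
0.5, noise 0.03) and `hard()` (contrast 0.12, noise 0.15) presets. Control
masks are empty by default; a `healthy` mode marks the healthy-ACL box
instead. These fixtures contain no anatomy, so passing tests demonstrate the
mechanism (masks, losses, optimization, attention plumbing), not clinical
performance on real MRI.

## Statistics

For each of the six metrics, the nine models' (training, validation) score
pairs feed a two-sided paired t-test with df = 8 (`scipy.stats.ttest_rel`);
95% confidence intervals per metric and split are mean ± t₀.₉₇₅,₈·σ/√9. The
published interval bounds are reproduced only when σ is the population
(n-denominator) standard deviation; that reverse-engineered convention is
the default and the standard sample-sd interval is available via
`dispersion="sample"`. Scores stay on the percent scale as published, and no
multiple-comparison correction is applied. When every training score equals
its validation partner the t statistic is 0 by convention; constant nonzero
differences (zero variance) raise an explicit error.

## Desk-scale problem sizes

The tests exercise reduced problem sizes chosen as the package's own
defaults for desk-scale verification: gradient checks on ~6×6 tensors,
forward contracts at 32×32 with width multiplier 0.125, and the mechanism
check — overfitting 8 easy synthetic slices at 128×128 with a width-0.125
network for 220 Adam steps to a training Dice ≥ 0.9. Full-width training on
the real corpus is supported by the same code paths but is not part of the
test surface.

## Known limitations

- The numpy engine is single-threaded apart from BLAS matmuls; full-width
  training at scale is impractical compared to a GPU framework, though the
  full graph builds, runs forward, and counts parameters exactly.
- Pretrained encoder weights are not shipped; published headline scores
  depended on the real MRI corpus and fine-tuned pretrained features.
- JPEG mask storage is lossy by nature; the compatibility writer requires
  quality ≥ 95 and midpoint binarization on load so rectangles ≥ 2×2 survive
  round trips, but PNG is the default for exactness.
- Bilinear resampling uses half-pixel centers; other frameworks' alignment
  conventions may differ at the one-pixel level.
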