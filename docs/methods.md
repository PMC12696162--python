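# Methods

`leafdet` is a from-scratch implementation of a lightweight anchor-based
foliar-disease detector for Ginkgo leaves, together with the structured
pruning pipeline that compresses it for edge deployment. This note
documents the model, the numerical choices, and what the bundled
synthetic data can and cannot show.

## Differentiable core

The whole network, its training loop and its pruner run on a compact
reverse-mode automatic-differentiation engine over numpy float32 arrays
(`leafdet.tensor`). Convolution (im2col + GEMM, with a dedicated
depthwise path), batch normalization, max pooling and the binary
cross-entropy are fused primitives with hand-written adjoints; all other
operations compose from elementwise/reduction primitives. Every
primitive is validated against central finite differences in the test
suite. This keeps the package self-contained on a plain scientific
Python stack and makes single-CPU behaviour fully deterministic for a
given seed.

Consequences worth knowing:

* throughput is roughly one 16-image training step per 0.5–1.5 s at
  112–160 px input on one CPU core, which fixes the problem sizes used
  by the end-to-end tests (below);
* batch statistics dominate normalization at these step counts, so
  running BN statistics are re-estimated (cumulative average over a few
  forward passes, weights untouched) before any evaluation
  (`train.recalibrate_bn`); evaluation without recalibration under-reads
  mAP badly at desk scale.

## Architecture

**Backbone.** A ten-stage depthwise-separable cascade (stem: standard
3×3/2 convolution to 16 channels; then DepthSepConv blocks — depthwise
k×k → affine norm → H-Swish → pointwise 1×1 → affine norm → H-Swish,
k ∈ {3,5}) with taps after stages 5/7/9 at strides 8/16/32
(128/256/512 channels). Conventions that fix the parameter accounting
exactly: convolutions carry no bias; normalization holds 2 trainable
scalars per channel; running statistics are buffers. Closed forms:
stem `k²·Cin·Cout + 2·Cout`; DepthSepConv
`k²·Cin + 2·Cin + Cin·Cout + 2·Cout`. The default table totals 851,360
trainable parameters. No squeeze-excitation stages and no 1280-channel
classifier head are present (those belong to the classification variant
of this backbone family). A stage table row with a stride-1 block lists
the same output size as its input; one printed size in the source table
("64×160×6") is arithmetically impossible and is treated as 64×160×160.

**Attention.** ECA is the production choice: global average pool, one
shared 1-D convolution of adaptive odd kernel
`k = odd(floor(|log2 C + 1| / 2))` (γ=2, b=1) across the channel
descriptor, sigmoid gate. It costs k ≤ 7 parameters per site. SE (r=4)
and CBAM exist for ablation parity behind the same `attention` config
enum. ECA sites: after each backbone tap and inside every BiECAFusion
node.

**Neck.** SPPCSPC (stride-1 max-pool pyramid 5/9/13 with a CSP
shortcut) compresses P5 512→256, then one Bottleneck-Transformer block:
1×1 reduce → multi-head self-attention (4 heads, content + separable
relative-position logits, softmax over the ≤20×20 grid) → linear → GELU
→ linear projection → 1×1 expand, residual add. Attention is applied
only at stride 32 to bound the O((HW)²) cost. Fusion is bidirectional:
top-down (nearest ×2 upsampling) and bottom-up (stride-2 CBL) passes,
each cross-scale merge a BiECAFusion node — both inputs aligned to a
common width by 1×1 CBLs, an ECA gate over their concatenation split
into two per-channel weight vectors, reciprocal enhancement
a = x0′ + w1⊙x1′, b = x1′ + w0⊙x0′, merged by concat + 1×1 CBL (the
recombination step is unconstrained by the method description; concat
keeps both reciprocal terms at negligible cost, summation is the obvious
alternative). ELAN blocks refine after every fusion. Outputs:
64/128/256 channels at strides 8/16/32.

**Head.** The three neck outputs are projected to a common 64-channel
width, resampled to the median (stride-16) scale, and stacked into the
L×S×C head tensor. Each DyHead block applies, in order, a per-level
scalar gate (pooled descriptor → shared affine → hard-sigmoid), a
per-position gate (shared 3×3 conv → hard-sigmoid; a plain convolution
stands in for deformable sampling — portable, testable, and exposes the
same factorized-attention contract), and a per-channel gate (GAP →
bottleneck MLP → hard-sigmoid). Hard-sigmoid is used for all three
gates so that saturated weights reproduce the identity map *exactly*,
which is the block's defining algebraic property and is asserted in the
tests. Gate biases initialize at +2 (gate ≈ 0.83): a cascade of
half-open gates attenuates the head signal ~8× per block and measurably
starves the detect layers of gradient at the start of training. Two
blocks are stacked by default (`dyhead_blocks`). Each level ends in a
1×1 detect convolution with 3 anchors × (4 box + 1 objectness + 3
class) outputs; objectness biases start at −4 (background-heavy prior).

**Decoding.** Centers use sigmoid offsets within the source cell,
`cx = (gx + σ(tx))·stride`; extents use anchor-scaled exponentials,
`w = anchor_w·exp(tw)` with `tw` clipped to [−9, 4]. Confidence is
σ(obj)·σ(class) with a strict `>` threshold; NMS is class-wise greedy
at IoU 0.45. Anchors default to the standard 640-px nine-anchor set,
rescaled to the input resolution; the synthetic-data generator instead
calibrates anchors by k-means (k=9) on its own label statistics and
stores them in the dataset manifest.

## Loss

Shape-IoU box regression:

* directional weights `ww = 2·w_gt^s/(w_gt^s + h_gt^s)` (and `hh`
  symmetrically), so `ww + hh = 2` always and `scale = 0` gives unit
  weights;
* shape-weighted center distance `hh·Δx²/c² + ww·Δy²/c²`, where `c²` is
  the squared diagonal of the minimum enclosing box (the established
  normalization in this loss lineage). The cross pairing — `hh` on the
  x-term — is implemented exactly as the method states it, with a
  `swap_weights` flag to flip it;
* size penalty `Ω = Σ_{t∈{w,h}} (1 − e^{−ω_t})^4` with
  `ω_w = hh·|w−w_gt|/max(w, w_gt)`;
* total `L = 1 − IoU + distance + 0.5·Ω`.

`scale` defaults to 0 (near-isometric lesion boxes); `calibrate_scale`
offers a documented heuristic from the label w/h distribution and
`calibrate_scale_by_map` a direct validation-mAP grid search over
{0, 0.5, 1, 1.5, 2}.

The composite loss assigns targets by anchor/box wh-ratio < 4 with
neighboring-cell expansion. Because center decoding is confined to the
source cell, a neighbor cell can never regress the true center, so
neighbor matches supervise objectness only (with IoU-valued targets);
box and class terms use center-cell matches. Objectness is BCE over all
cells with matched cells upweighted ×10 — a handful of foreground cells
among thousands of background cells otherwise leaves the confidence
ranking uninformative at small training scales; with no targets the
term is the plain BCE mean (ln 2 at zero logits). Classification is
one-vs-all BCE on matched cells. Term weights default to 0.05/1.0/0.5
(box/obj/cls), and the optimized total scales with the batch size (the
convention those weights were calibrated for); reported per-term values
are batch-size free.

## Training

SGD with Nesterov momentum 0.937, weight decay 5e-4, linear warmup over
the first 3 epochs, then linear decay from `lr0` to `lr0·lrf`.
Reference settings: lr0 0.01, 300 epochs, batch 16, 640 px. The `desk`
profile (single CPU) shrinks to 160 px / 30 epochs. Post-pruning
fine-tuning uses lr0 0.001 (final 1e-5 = lr0·lrf), momentum 0.937,
weight decay 5e-4, warmup 3 epochs (warmup momentum 0.8, warmup bias lr
0.1), 200 epochs at reference scale.

## Pruning

Per-weight LAMP scores: after a stable descending-magnitude sort,
`score[i] = w[i]²/cumsum(w²)[i]` — equivalently each weight's squared
magnitude normalized by the total squared magnitude of same-layer
weights at least as large. Ties resolve so the earlier index takes the
smaller score. The largest weight of every layer scores exactly 1,
which is what makes the ranking layer-adaptive under a single global
threshold.

Structured removal operates on output-channel groups. The model builds
a dependency graph over channel axes (union-find for residual and
gate-split ties, concat parents with offset mapping for ELAN/SPPCSPC/
BiECAFusion merges, depthwise convolutions tying input to output), so
removing one channel propagates to every affected weight slice and the
pruned network stays forward-consistent — asserted by shape probes in
the tests. Group importance is the sum of LAMP scores over the
channel's weight slice; the globally least important channel is removed
(importances of touched layers recomputed) until
`FLOPs(base)/FLOPs(pruned) ≥ speed_up`. FLOPs are multiply-accumulates
of conv/linear layers at the probe resolution; normalization and
activation costs are ignored (consistent bookkeeping, not a hardware
model). Protected from removal: the stem, detect-layer outputs, MHSA
q/k/v widths (head-split and relative-position shapes), SE/CBAM sites,
and axes at the 2-channel floor. A target of exactly 1.0 leaves the
model bit-identical. `speed_up = 1.6` corresponds to a 37.5% = 1 − 1/1.6
computational reduction; the reference operating point is 2.2.

## Synthetic data

The generator (`leafdet.synthdata`) renders fan-shaped green leaf
silhouettes with wavy margins on low-frequency soil texture and paints
class-conditioned lesions: diffuse yellow patches (chlorosis, class 0),
clusters of small dark holes (insect pest, class 1), pale elongated
tears (physical damage, class 2). It emulates the statistical structure
of the field dataset it stands in for — class mix 1779:5260:2543,
lesion centroids uniform over the leaf, mostly near-isometric boxes
with an `anisotropy_fraction` (default 0.2) of elongated ones — and
writes YOLO-format labels where each box is the exact pixel bounding
box of the painted lesion. Splits are 8:1:1 assigned by a stable hash
of the image index, so extending a dataset never reassigns existing
images. Everything is a pure function of (config, seed). Default
photometric augmentation magnitudes: brightness/contrast ±25%, hue
±10°; a uniform rescale leaves normalized labels unchanged and
letterboxing re-projects them exactly (round-trip ~1e-6). Lesion/leaf
contrast is kept ≥ 30 gray levels — separable but not trivial.

What passing on this data does **not** show: robustness to real
canopies (occlusion, specular lighting, background clutter), real lesion
texture, annotation noise, or the class-confusion structure of field
imagery. The generator validates the pipeline's mechanics and learning
dynamics, not field accuracy; headline field metrics (e.g. ~94% mAP@0.5
after pruning at speed_up 2.2) require the original dataset and
full-scale training and are out of scope here.

## Problem sizes used by the end-to-end tests

The end-to-end smoke test trains the full detector on 200 synthetic
images at 128×128 (the nearest stride-32-compatible size to the desk
profile) for 30 epochs (batch 16, lr0 0.01, easy scene preset: 1–2 large
lesions per image, `lesion_scale` (0.16, 0.34), balanced class mix so
each class has enough validation instances for a stable AP), evaluates
mAP@0.5 on the held-out split, then LAMP-prunes at speed_up 1.5 and
fine-tunes for 10 epochs, checking ≥ 90% mAP retention. These sizes
are the package's chosen desk-scale operating point for a single CPU;
the thresholds (mAP ≥ 0.5; ≥ 90% retention) are the pass criteria.
The training seed, generator seed and anchor calibration are fixed
inside the test.

## Known limitations

* The spatial DyHead gate is a plain convolution mask, not deformable
  sampling; level resampling uses nearest/average 2× steps.
* MHSA internals (q/k/v widths) are pruning-protected; the pruner
  therefore cannot reach extreme speed-ups that would require shrinking
  attention head dimensions.
* The trainer is single-threaded and has no EMA, mosaic augmentation or
  multi-scale training; it is sized for correctness checks, not
  benchmark chasing.
* `calibrate_scale`'s area-quantile heuristic is a documented guess;
  the mAP grid search is the principled alternative.
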