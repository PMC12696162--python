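# leafdet

A lightweight, edge-oriented object detector for foliar diseases of
leaf-harvested *Ginkgo biloba*, built and tested end-to-end on plain
scientific Python (numpy/scipy/Pillow — the network, its training loop
and its pruner run on a small reverse-mode autodiff engine included in
the package).

Ginkgo plantations are monitored for three visually distinct lesion
types — **chlorosis** (fungal yellowing, class 0), **insect pest**
damage (class 1) and **physical damage** (hail/mechanical tears,
class 2) — and the deployment target is an embedded device in the
field, so the architecture trades accuracy for parameter and FLOP
budget at every stage:

* **Backbone** — a ten-stage depthwise-separable convolution cascade
  (3×3/5×5 kernels, H-Swish), 851,360 trainable parameters, with
  pyramid taps at strides 8/16/32.
* **Neck** — SPPCSPC pooling, a Bottleneck-Transformer block (multi-head
  self-attention with relative positions on the stride-32 grid), and
  bidirectional cross-scale fusion through **BiECAFusion** nodes:
  channel-aligned inputs exchange ECA-derived gates reciprocally,
  `a = x0' + w1⊙x1'`, `b = x1' + w0⊙x0'`.
* **Head** — DyHead factorized attention `W(F) = π_C(π_S(π_L(F)·F)·F)·F`
  over the (level, space, channel) tensor, then anchor-based detect
  layers.
* **Box loss** — Shape-IoU:
  `L = 1 − IoU + distance_shape + 0.5·Ω_shape`, where the center
  distance is weighted by the ground-truth shape
  (`ww = 2·w^s/(w^s+h^s)`, `ww + hh = 2`) and
  `Ω = Σ_t (1−e^{−ω_t})^4` penalizes size mismatch.
* **Compression** — LAMP (layer-adaptive magnitude) scores,
  `score(u) = w_u² / Σ_{|w_v|≥|w_u|} w_v²`, pooled globally and pruned
  as output-channel groups with full dependency propagation until a
  `speed_up` FLOPs ratio is reached (`speed_up = 1.6` ⇔ 37.5% fewer
  FLOPs), followed by a short SGD fine-tune (lr 0.001 → 1e-5).

Because no field dataset ships with the package, a deterministic
synthetic scene generator (`leafdet.synthdata`) renders fan-shaped
leaves with class-conditioned lesions and exact YOLO-format labels,
reproducing the field data's class mix (1779:5260:2543), uniform lesion
placement and mostly-isometric box geometry. It makes the entire
pipeline — train → prune → fine-tune → evaluate — testable on one CPU.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```sh
# 1. render a small synthetic dataset (anchors auto-calibrated, k-means)
leafdet synth --n 200 --img-size 128 --seed 7 --max-lesions 2 \
              --balanced --lesion-scale 0.16:0.34 --out data/

# 2. train the detector at desk scale
leafdet train --data data/ --out run/ --epochs 30 --img-size 128 --seed 7

# 3. prune to a 1.5x FLOPs speed-up and fine-tune
leafdet prune    --model run/model.pkl --out pruned/ --speed-up 1.5
leafdet finetune --model pruned/model_pruned.pkl --data data/ \
                 --out pruned/ --epochs 10
leafdet eval     --model pruned/model_finetuned.pkl --data data/ --split val
```

The `synth` step prints the dataset summary — `generated 200 images
under data/ (302 instances)`. `train` logs one JSON record per epoch
(total/box/objectness/class loss terms and the learning rate) and
finishes with the held-out score, `val mAP@0.5 = 0.648` — the mean over
the three lesion classes of average precision at an IoU-0.5 matching
threshold (about eight minutes on one CPU core). `prune` reports the plan:

```
"speed_up_target": 1.5,  "achieved_speed_up": 1.50009,
"reduction_percent": 33.3,  "params": 1845936,  "channels_removed": 2128
```

meaning the pruned network runs with one third fewer
multiply-accumulates while the detect layers, stem and attention widths
stay protected. After the 10-epoch fine-tune, `eval` prints the
per-class APs and `"map50": 0.609` — 94% of the pre-prune score at this
operating point.
A pruning ablation table over a range of targets:

```sh
leafdet prune --model run/model.pkl --out grid/ --grid 1.0:2.4:0.2
```

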