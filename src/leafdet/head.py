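"""Detection head: DyHead factorized attention and the anchor-based
detect layer with box decoding and NMS.

The head tensor view is F in R^(L x S x C): the three neck outputs are
projected to a common channel width, resampled to the median pyramid
scale, and refined by a cascade of attention blocks, each applying a
level gate (pi_L), a spatial gate (pi_S) and a channel gate (pi_C) in
that exact order — W(F) = pi_C(pi_S(pi_L(F) . F) . F) . F.  All gates
are hard-sigmoids, so saturated weights reproduce the identity map
exactly.  After refinement each level returns to its native scale and a
1x1 detect convolution emits 3 anchors x (4 box + 1 objectness +
n_classes) channels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .layers import CBL
from .modules import Conv2d, Linear, Module
from .tensor import Tensor

# YOLOv7-tiny COCO anchor convention (pixels at 640 input), stride 8/16/32
DEFAULT_ANCHORS = (
    ((10.0, 13.0), (16.0, 30.0), (33.0, 23.0)),
    ((30.0, 61.0), (62.0, 45.0), (59.0, 119.0)),
    ((116.0, 90.0), (156.0, 198.0), (373.0, 326.0)),
)
DEFAULT_STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class AnchorSet:
    """3 anchors per pyramid level as (w, h) pixel pairs at ``img_size``."""

    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple = DEFAULT_STRIDES
    img_size: int = 640

    def __post_init__(self):
        if len(self.anchors) != 3 or any(len(a) != 3 for a in self.anchors):
            raise ValueError("need 3 levels x 3 anchors")
        for level in self.anchors:
            for w, h in level:
                if w <= 0 or h <= 0:
                    raise ValueError("anchors must be positive")

    def scaled(self, img_size):
        """Rescale anchor pixels to a different input resolution."""
        f = img_size / self.img_size
        return AnchorSet(
            tuple(tuple((w * f, h * f) for w, h in lvl) for lvl in self.anchors),
            self.strides, img_size)


def kmeans_anchors(wh, img_size, k=9, iters=50, seed=0):
    """K-means (k=9) over label (w, h) pixel extents -> an AnchorSet.

    ``wh``: array of normalized (w, h) pairs; clusters are sorted by area
    and split 3/3/3 across the pyramid levels.
    """
    wh = np.asarray(wh, dtype=np.float64) * img_size
    rng = np.random.default_rng(seed)
    if len(wh) < k:
        wh = np.concatenate([wh] * int(np.ceil(k / max(len(wh), 1))))
    centers = wh[rng.choice(len(wh), k, replace=False)]
    for _ in range(iters):
        d = ((wh[:, None, :] - centers[None]) ** 2).sum(-1)
        lab = d.argmin(1)
        for j in range(k):
            if (lab == j).any():
                centers[j] = wh[lab == j].mean(0)
    centers = centers[np.argsort(centers.prod(1))]
    centers = np.maximum(centers, 2.0)
    lv = [tuple(map(tuple, centers[i * 3:(i + 1) * 3])) for i in range(3)]
    return AnchorSet(tuple(lv), DEFAULT_STRIDES, img_size)


@dataclass
class DetectionRecord:
    """A decoded prediction in pixel corner form (0-based, half-open)."""

    class_id: int
    confidence: float
    x1: float
    y1: float
    x2: float
    y2: float
    image_id: str = ""

    @property
    def box_xyxy(self):
        return (self.x1, self.y1, self.x2, self.y2)


# ---------------------------------------------------------------------------
# DyHead
# ---------------------------------------------------------------------------


class DyHeadBlock(Module):
    """One W(F) block: level, spatial and channel hard-sigmoid gates."""

    def __init__(self, channels, reduction=4):
        super().__init__()
        self.channels = channels
        # pi_L: shared scalar 1x1 transform of the level descriptor
        self.level_fc = Linear(1, 1, bias=True)
        # pi_S: shared 3x3 conv -> one mask per position per level
        self.spatial_conv = Conv2d(channels, 1, 3, padding=1, bias=True)
        # pi_C: GAP -> bottleneck -> per-channel gate
        hidden = max(channels // reduction, 4)
        self.ch_fc1 = Linear(channels, hidden, bias=True)
        self.ch_fc2 = Linear(hidden, channels, bias=True)
        # start with nearly-open gates (hard_sigmoid(2) ~ 0.83): a cascade of
        # half-closed gates would attenuate the head signal by ~8x per block
        # and starve the detect layers of gradient at the start of training
        self.level_fc.bias.data[:] = 2.0
        self.spatial_conv.bias.data[:] = 2.0
        self.ch_fc2.bias.data[:] = 2.0

    # F is a Tensor of shape (N, L, C, H, W) at the common median scale
    def level_attention(self, f):
        f = T.as_tensor(f)
        n, l, c, h, w = f.shape
        d = f.mean(axis=(2, 3, 4)).reshape(n, l, 1)   # (N, L, 1)
        gate = self.level_fc(d).hard_sigmoid().reshape(n, l, 1, 1, 1)
        return f * gate

    def spatial_attention(self, f):
        f = T.as_tensor(f)
        n, l, c, h, w = f.shape
        m = self.spatial_conv(f.reshape(n * l, c, h, w)).hard_sigmoid()
        return f * m.reshape(n, l, 1, h, w)

    def channel_attention(self, f):
        f = T.as_tensor(f)
        n, l, c, h, w = f.shape
        d = f.mean(axis=(1, 3, 4))                    # (N, C)
        gate = self.ch_fc2(self.ch_fc1(d).relu()).hard_sigmoid()
        return f * gate.reshape(n, 1, c, 1, 1)

    def forward(self, f):
        # composition order is exactly pi_L, then pi_S, then pi_C
        return self.channel_attention(self.spatial_attention(self.level_attention(f)))

    def force_identity(self):
        """Saturate every gate at exactly 1 (hard-sigmoid(x>=3) == 1)."""
        self.level_fc.weight.data[:] = 0.0
        self.level_fc.bias.data[:] = 6.0
        self.spatial_conv.weight.data[:] = 0.0
        self.spatial_conv.bias.data[:] = 6.0
        self.ch_fc2.weight.data[:] = 0.0
        self.ch_fc2.bias.data[:] = 6.0
        return self

    def register_prune(self, g, ax):
        g.attach(ax, self.spatial_conv, "in")
        g.attach(ax, self.ch_fc1, "in")
        hid = g.new_axis(self.ch_fc1.out_features)
        g.attach(hid, self.ch_fc1, "out")
        g.attach(hid, self.ch_fc2, "in")
        g.attach(ax, self.ch_fc2, "out")  # per-channel gate ties to the axis
        return ax


class DyHead(Module):
    """k stacked DyHead blocks (default 2) over the (L, S, C) tensor."""

    def __init__(self, channels, k_blocks=2):
        super().__init__()
        if k_blocks < 1:
            raise ValueError("k_blocks must be >= 1")
        self.blocks = [DyHeadBlock(channels) for _ in range(k_blocks)]

    def forward(self, f):
        for b in self.blocks:
            f = b(f)
        return f

    def force_identity(self):
        for b in self.blocks:
            b.force_identity()
        return self

    def register_prune(self, g, ax):
        for b in self.blocks:
            ax = b.register_prune(g, ax)
        return ax


def level_attention(block: DyHeadBlock, f):
    return block.level_attention(f)


def spatial_attention(block: DyHeadBlock, f):
    return block.spatial_attention(f)


def channel_attention(block: DyHeadBlock, f):
    return block.channel_attention(f)


def dyhead(f, k_blocks=1, channels=None, blocks=None):
    """Apply ``k_blocks`` W(.) transforms to the stacked head tensor."""
    if blocks is None:
        blocks = DyHead(channels if channels is not None else f.shape[2], k_blocks)
    return blocks(f)


# ---------------------------------------------------------------------------
# full head: projection + DyHead + detect layers
# ---------------------------------------------------------------------------


class Head(Module):
    def __init__(self, in_channels=(64, 128, 256), head_channels=64,
                 n_classes=3, k_blocks=2):
        super().__init__()
        self.n_classes = n_classes
        self.no = 5 + n_classes
        self.proj = [CBL(c, head_channels, 1) for c in in_channels]
        self.dyhead = DyHead(head_channels, k_blocks)
        self.detect = [Conv2d(head_channels, 3 * self.no, 1, padding=0, bias=True)
                       for _ in in_channels]
        for d in self.detect:
            # objectness prior: start background-heavy for stable early training
            b = d.bias.data.reshape(3, self.no)
            b[:, 4] = -4.0
            d.bias.data = b.reshape(-1)

    def forward(self, pyramid):
        p3, p4, p5 = pyramid
        x3 = self.proj[0](p3)
        x4 = self.proj[1](p4)
        x5 = self.proj[2](p5)
        # resample to the median (P4) scale and stack into (N, L, C, H, W)
        f = T.stack([T.avg_pool2d(x3, 2), x4, T.upsample_nearest2d(x5, 2)], axis=1)
        f = self.dyhead(f)
        # residual return to native scales: the nearest/average resampling
        # alone would hand P3's detect layer block-constant features (and
        # hence duplicate boxes in adjacent cells)
        y3 = x3 + T.upsample_nearest2d(f[:, 0], 2)
        y4 = x4 + f[:, 1]
        y5 = x5 + T.avg_pool2d(f[:, 2], 2)
        return [self.detect[0](y3), self.detect[1](y4), self.detect[2](y5)]

    def register_prune(self, g, ax3, ax4, ax5):
        heads = [self.proj[i].register_prune(g, ax)
                 for i, ax in enumerate((ax3, ax4, ax5))]
        ax = heads[0]
        for other in heads[1:]:
            g.union(ax, other)  # shared DyHead and detect weights tie the widths
        ax = self.dyhead.register_prune(g, ax)
        for d in self.detect:
            out = g.conv_node(ax, d)
            g.protect(out)  # per-anchor output layout is fixed
        return ax


# ---------------------------------------------------------------------------
# decoding and NMS
# ---------------------------------------------------------------------------


def decode_level(raw, anchors_level, stride):
    """Decode one raw grid (N, 3*(5+nc), H, W) -> numpy arrays.

    Centers use sigmoid offsets within the source cell, extents use
    anchor-scaled exponentials: cx = (gx + sigma(tx)) * stride,
    w = anchor_w * exp(tw).  Returns (boxes_xyxy, obj, cls) with shapes
    (N, 3, H, W, 4), (N, 3, H, W), (N, 3, H, W, nc).
    """
    data = raw.data if isinstance(raw, Tensor) else np.asarray(raw)
    n, ch, h, w = data.shape
    no = ch // 3
    p = data.reshape(n, 3, no, h, w).transpose(0, 1, 3, 4, 2)
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    aw = np.array([a[0] for a in anchors_level], dtype=np.float32).reshape(1, 3, 1, 1)
    ah = np.array([a[1] for a in anchors_level], dtype=np.float32).reshape(1, 3, 1, 1)
    sx = T.sigmoid(p[..., 0])
    sy = T.sigmoid(p[..., 1])
    cx = (gx[None, None] + sx) * stride
    cy = (gy[None, None] + sy) * stride
    bw = aw * np.exp(np.clip(p[..., 2], -9.0, 4.0))
    bh = ah * np.exp(np.clip(p[..., 3], -9.0, 4.0))
    boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1)
    obj = T.sigmoid(p[..., 4])
    cls = T.sigmoid(p[..., 5:])
    return boxes.astype(np.float32), obj.astype(np.float32), cls.astype(np.float32)


def _iou_xyxy_matrix(a, b):
    """Pairwise IoU of (M,4) x (K,4) corner boxes."""
    area_a = np.maximum(a[:, 2] - a[:, 0], 0) * np.maximum(a[:, 3] - a[:, 1], 0)
    area_b = np.maximum(b[:, 2] - b[:, 0], 0) * np.maximum(b[:, 3] - b[:, 1], 0)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.maximum(rb - lt, 0)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes, scores, iou_thr=0.45):
    """Greedy non-maximum suppression; returns kept indices (stable order
    for equal-confidence disjoint boxes)."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = _iou_xyxy_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious <= iou_thr]
    return keep


def detect_and_decode(outputs, anchors: AnchorSet, conf_thr=0.25, iou_thr=0.45,
                      image_ids=None):
    """Decode raw pyramid outputs into per-image DetectionRecord lists.

    Confidence is sigma(obj) * sigma(class); the threshold is strict
    (``>``); NMS is class-wise greedy at ``iou_thr``.
    """
    if not 0.0 <= conf_thr <= 1.0:
        raise ValueError("conf_thr must lie in [0, 1]")
    n = (outputs[0].data if isinstance(outputs[0], Tensor) else outputs[0]).shape[0]
    all_boxes = [[] for _ in range(n)]
    for raw, anc, stride in zip(outputs, anchors.anchors, anchors.strides):
        boxes, obj, cls = decode_level(raw, anc, stride)
        conf = obj[..., None] * cls                   # (N, 3, H, W, nc)
        best_c = conf.argmax(axis=-1)
        best = np.take_along_axis(conf, best_c[..., None], axis=-1)[..., 0]
        for b in range(n):
            mask = best[b] > conf_thr
            if mask.any():
                all_boxes[b].append((boxes[b][mask], best[b][mask], best_c[b][mask]))
    results = []
    for b in range(n):
        recs = []
        if all_boxes[b]:
            bx = np.concatenate([x[0] for x in all_boxes[b]])
            sc = np.concatenate([x[1] for x in all_boxes[b]])
            cl = np.concatenate([x[2] for x in all_boxes[b]])
            for c in np.unique(cl):
                sel = cl == c
                for i in nms(bx[sel], sc[sel], iou_thr):
                    recs.append(DetectionRecord(
                        int(c), float(sc[sel][i]), *map(float, bx[sel][i]),
                        image_id="" if image_ids is None else image_ids[b]))
        recs.sort(key=lambda r: -r.confidence)
        results.append(recs)
    return results


def write_detections_csv(path, records):
    """Flat CSV: image, class, conf, x1, y1, x2, y2 (pixels, half-open)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "class", "conf", "x1", "y1", "x2", "y2"])
        for r in records:
            w.writerow([r.image_id, r.class_id, f"{r.confidence:.6f}",
                        f"{r.x1:.2f}", f"{r.y1:.2f}", f"{r.x2:.2f}", f"{r.y2:.2f}"])


def detections_to_yolo_lines(records, img_w, img_h):
    """Detections as YOLO-format label lines (class cx cy w h, normalized)."""
    lines = []
    for r in records:
        cx = (r.x1 + r.x2) / 2 / img_w
        cy = (r.y1 + r.y2) / 2 / img_h
        w = (r.x2 - r.x1) / img_w
        h = (r.y2 - r.y1) / img_h
        lines.append(f"{r.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    return lines
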