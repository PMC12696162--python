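"""Detection evaluation: precision, recall, AP, mAP@0.5, confusion matrix.

Matching is greedy per class: detections sorted by descending confidence
each claim the highest-IoU unmatched ground truth with IoU >= threshold;
a ground truth matches at most once.  AP uses all-point interpolation
(the precision envelope made monotone non-increasing, integrated over
recall steps); classes absent from ground truth are excluded from the
mAP mean rather than counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .head import DetectionRecord, _iou_xyxy_matrix


@dataclass
class MatchResult:
    """Confidence-ordered TP/FP flags per detection plus the FN count."""

    tp_flags: np.ndarray      # bool per detection, confidence-descending
    confidences: np.ndarray
    n_gt: int

    @property
    def tp(self):
        return int(self.tp_flags.sum())

    @property
    def fp(self):
        return int((~self.tp_flags).sum())

    @property
    def fn(self):
        return self.n_gt - self.tp


def match_detections(dets, gts, iou_threshold=0.5):
    """Greedy same-class matching of one image's detections to ground truth.

    ``dets``: DetectionRecord list; ``gts``: (class_id, x1, y1, x2, y2)
    rows (array or list).  Returns a MatchResult over all classes.
    """
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
    order = np.argsort([-d.confidence for d in dets], kind="stable")
    flags = np.zeros(len(dets), dtype=bool)
    confs = np.array([dets[i].confidence for i in order], dtype=np.float64)
    used = np.zeros(len(gts), dtype=bool)
    for rank, di in enumerate(order):
        d = dets[di]
        cand = np.where((gts[:, 0] == d.class_id) & ~used)[0]
        if len(cand) == 0:
            continue
        ious = _iou_xyxy_matrix(
            np.array([[d.x1, d.y1, d.x2, d.y2]]), gts[cand, 1:])[0]
        j = int(ious.argmax())
        if ious[j] >= iou_threshold:
            used[cand[j]] = True
            flags[rank] = True
    return MatchResult(flags, confs, len(gts))


def precision_recall(tp, fp, fn):
    """P = TP/(TP+FP), R = TP/(TP+FN), with 0/0 defined as 0."""
    p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return p, r


def average_precision(flags, n_gt):
    """All-point interpolated AP from confidence-ordered TP/FP flags.

    Returns 0 when there is no ground truth (callers exclude such classes
    from the mAP mean).
    """
    flags = np.asarray(flags, dtype=bool)
    if n_gt <= 0 or len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def map50(per_class_ap):
    """Arithmetic mean of per-class APs (classes present in ground truth)."""
    aps = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    if not aps:
        raise ValueError("mAP needs at least one evaluable class")
    return float(np.mean(aps))


def evaluate_detections(dets_per_image, gts_per_image, n_classes=3,
                        iou_threshold=0.5):
    """Dataset-level evaluation.

    ``dets_per_image``: list (per image) of DetectionRecord lists;
    ``gts_per_image``: list of (class, x1, y1, x2, y2) arrays.
    Returns {"per_class": {cid: {"precision", "recall", "ap", "n_gt"}},
             "map50": float}; classes with no ground truth are skipped.
    """
    per_class = {}
    for c in range(n_classes):
        flags_all, confs_all, n_gt = [], [], 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
            cls_dets = [d for d in dets if d.class_id == c]
            cls_gts = gts[gts[:, 0] == c]
            n_gt += len(cls_gts)
            m = match_detections(cls_dets, cls_gts, iou_threshold)
            flags_all.append(m.tp_flags)
            confs_all.append(m.confidences)
        if n_gt == 0:
            continue
        flags = np.concatenate(flags_all) if flags_all else np.array([], bool)
        confs = np.concatenate(confs_all) if confs_all else np.array([])
        order = np.argsort(-confs, kind="stable")
        flags = flags[order]
        tp = int(flags.sum())
        fp = int((~flags).sum())
        p, r = precision_recall(tp, fp, n_gt - tp)
        per_class[c] = {"precision": p, "recall": r,
                        "ap": average_precision(flags, n_gt), "n_gt": n_gt}
    result = {"per_class": per_class}
    result["map50"] = map50({c: v["ap"] for c, v in per_class.items()}) \
        if per_class else 0.0
    return result


def confusion_matrix(dets_per_image, gts_per_image, n_classes=3,
                     conf_thr=0.25, iou_thr=0.45):
    """Row-normalized confusion matrix over the classes plus background.

    Rows are true classes (last row = background), columns predicted
    (last column = background).  Unmatched ground truths count as (true,
    background); unmatched detections as (background, predicted).  Rows
    with mass are normalized to sum to 1.
    """
    m = np.zeros((n_classes + 1, n_classes + 1), dtype=np.float64)
    for dets, gts in zip(dets_per_image, gts_per_image):
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
        dets = [d for d in dets if d.confidence > conf_thr]
        dets = sorted(dets, key=lambda d: -d.confidence)
        used = np.zeros(len(gts), dtype=bool)
        det_matched = np.zeros(len(dets), dtype=bool)
        for i, d in enumerate(dets):
            if len(gts) == 0:
                break
            ious = _iou_xyxy_matrix(
                np.array([[d.x1, d.y1, d.x2, d.y2]]), gts[:, 1:])[0]
            ious[used] = -1.0
            j = int(ious.argmax())
            if ious[j] >= iou_thr:
                used[j] = True
                det_matched[i] = True
                m[int(gts[j, 0]), d.class_id] += 1
        for j, u in enumerate(used):
            if not u:
                m[int(gts[j, 0]), n_classes] += 1  # missed gt -> background col
        for i, d in enumerate(dets):
            if not det_matched[i]:
                m[n_classes, d.class_id] += 1       # spurious det
    sums = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, m / sums, 0.0)
    return norm


def per_class_table(eval_result, class_names=None):
    """Plain-text per-class P/R/AP table from ``evaluate_detections`` output."""
    lines = [f"{'class':<16}{'n_gt':>6}{'P':>8}{'R':>8}{'AP@0.5':>9}"]
    for c, row in sorted(eval_result["per_class"].items()):
        name = class_names[c] if class_names else str(c)
        lines.append(f"{name:<16}{row['n_gt']:>6}{row['precision']:>8.3f}"
                     f"{row['recall']:>8.3f}{row['ap']:>9.3f}")
    lines.append(f"{'mAP@0.5':<16}{'':>6}{'':>8}{'':>8}{eval_result['map50']:>9.3f}")
    return "\n".join(lines)
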