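"""Generic YOLO-format dataset reader and batching for the trainer.

Reads a dataset manifest (``manifest.yaml`` written by the synthetic
generator, or any directory with ``images/`` + ``labels/`` and the same
layout), letterboxes every image to the training resolution and yields
(float32 NCHW in [0,1], per-image target arrays) batches.
"""

from __future__ import annotations

import os

import numpy as np
import yaml
from PIL import Image

from .synthdata import (LabelRecord, labels_to_letterbox, letterbox,
                        read_yolo_labels)


class DetectionDataset:
    def __init__(self, root, split="train", img_size=160, cache=True):
        self.root = str(root)
        with open(os.path.join(self.root, "manifest.yaml")) as fh:
            self.manifest = yaml.safe_load(fh)
        self.img_size = img_size
        self.n_classes = int(self.manifest["nc"])
        self.class_names = list(self.manifest["names"])
        self.stems = list(self.manifest["splits"][split])
        self.img_dir = os.path.join(self.root, self.manifest["image_dir"])
        self.lab_dir = os.path.join(self.root, self.manifest["label_dir"])
        self._cache = {} if cache else None

    def __len__(self):
        return len(self.stems)

    def load(self, i):
        """Returns (chw float32 image in [0,1], targets (K,5) class+cxcywh)."""
        if self._cache is not None and i in self._cache:
            return self._cache[i]
        stem = self.stems[i]
        img = np.array(Image.open(os.path.join(self.img_dir, stem + ".png"))
                       .convert("RGB"))
        labels = read_yolo_labels(os.path.join(self.lab_dir, stem + ".txt"),
                                  self.n_classes)
        boxed, scale, pad = letterbox(img, self.img_size)
        labels = labels_to_letterbox(labels, img.shape, self.img_size, scale, pad)
        x = boxed.astype(np.float32).transpose(2, 0, 1) / 255.0
        t = np.array([[r.class_id, r.cx, r.cy, r.w, r.h] for r in labels],
                     dtype=np.float32).reshape(-1, 5)
        if self._cache is not None:
            self._cache[i] = (x, t)
        return x, t

    def ground_truth_xyxy(self, i):
        """Letterboxed ground truth as (class, x1, y1, x2, y2) pixel rows."""
        _, t = self.load(i)
        s = self.img_size
        out = np.zeros((len(t), 5), dtype=np.float64)
        out[:, 0] = t[:, 0]
        out[:, 1] = (t[:, 1] - t[:, 3] / 2) * s
        out[:, 2] = (t[:, 2] - t[:, 4] / 2) * s
        out[:, 3] = (t[:, 1] + t[:, 3] / 2) * s
        out[:, 4] = (t[:, 2] + t[:, 4] / 2) * s
        return out

    def batches(self, batch_size, rng=None):
        """Yield (stacked images, list of target arrays); shuffled if rng."""
        order = np.arange(len(self))
        if rng is not None:
            rng.shuffle(order)
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            pairs = [self.load(int(i)) for i in idx]
            x = np.stack([p[0] for p in pairs])
            t = [p[1] for p in pairs]
            yield x, t

    def label_wh(self):
        """All normalized (w, h) pairs, for anchor calibration."""
        out = []
        for i in range(len(self)):
            _, t = self.load(i)
            out.extend(t[:, 3:5].tolist())
        return np.array(out).reshape(-1, 2)
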