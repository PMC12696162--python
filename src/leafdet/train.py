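"""SGD training loop with warmup, linear decay and mAP@0.5 evaluation."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .data import DetectionDataset
from .head import detect_and_decode
from .losses import LossWeights, ShapeIoUParams, detection_loss
from .metrics import evaluate_detections


class SGD:
    """Momentum SGD with decoupled-style weight decay (L2 on the gradient)."""

    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0005,
                 nesterov=True):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            upd = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * upd

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def linear_lr(epoch, epochs, lr0, lrf):
    """Linear decay from lr0 to lr0*lrf across the run."""
    frac = min(max(epoch / max(epochs, 1), 0.0), 1.0)
    return lr0 * (1.0 - frac) + lr0 * lrf * frac


class Trainer:
    def __init__(self, model, lr0=0.01, lrf=0.01, momentum=0.937,
                 weight_decay=0.0005, warmup_epochs=3.0, epochs=30,
                 batch_size=16, weights: LossWeights = LossWeights(),
                 shape_params: ShapeIoUParams = ShapeIoUParams(), seed=0):
        self.model = model
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0, self.lrf = lr0, lrf
        self.warmup_epochs = warmup_epochs
        self.weights = weights
        self.shape_params = shape_params
        self.opt = SGD(model.parameters(), lr=lr0, momentum=momentum,
                       weight_decay=weight_decay)
        self.rng = np.random.default_rng(seed)
        self.history = []

    def _set_lr(self, epoch, step, steps_per_epoch):
        warm_steps = self.warmup_epochs * steps_per_epoch
        t = epoch * steps_per_epoch + step
        if t < warm_steps:
            base = linear_lr(epoch, self.epochs, self.lr0, self.lrf)
            self.opt.lr = base * (t + 1) / warm_steps
        else:
            self.opt.lr = linear_lr(epoch, self.epochs, self.lr0, self.lrf)

    def train_epoch(self, dataset: DetectionDataset, epoch):
        self.model.train()
        losses = []
        steps = max(int(np.ceil(len(dataset) / self.batch_size)), 1)
        for step, (x, targets) in enumerate(dataset.batches(self.batch_size,
                                                            self.rng)):
            self._set_lr(epoch, step, steps)
            preds = self.model(x)
            total, box, obj, cls = detection_loss(
                preds, targets, self.model.anchors,
                n_classes=self.model.n_classes, weights=self.weights,
                shape_params=self.shape_params)
            self.opt.zero_grad()
            total.backward()
            self.opt.step()
            losses.append([total.item(), box.item(), obj.item(), cls.item()])
        return np.mean(losses, axis=0)

    def fit(self, train_ds, val_ds=None, eval_every=0, log=None):
        for epoch in range(self.epochs):
            loss = self.train_epoch(train_ds, epoch)
            row = {"epoch": epoch, "loss": float(loss[0]),
                   "box": float(loss[1]), "obj": float(loss[2]),
                   "cls": float(loss[3]), "lr": self.opt.lr}
            if val_ds is not None and eval_every and \
                    (epoch + 1) % eval_every == 0:
                recalibrate_bn(self.model, train_ds, self.batch_size)
                row.update(evaluate_model(self.model, val_ds))
            self.history.append(row)
            if log:
                log(row)
        return self.history


def recalibrate_bn(model, dataset: DetectionDataset, batch_size=16,
                   n_batches=8, rng=None):
    """Re-estimate BatchNorm running statistics on ``dataset``.

    Running statistics updated with a small momentum lag far behind the
    weights at desk-scale step counts; this replaces them with the plain
    average of batch statistics over a few forward passes (the weights
    are untouched).
    """
    from .modules import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    model.train()
    seen = 0
    with T.no_grad():
        for x, _ in dataset.batches(batch_size, rng):
            for bn in bns:
                bn.momentum = 1.0 / (seen + 1)  # cumulative average
            model(x)
            seen += 1
            if seen >= n_batches:
                break
    for bn in bns:
        bn.momentum = 0.03
    model.eval()
    return model


def evaluate_model(model, dataset: DetectionDataset, conf_thr=0.001,
                   nms_iou=0.45, map_iou=0.5, batch_size=16):
    """Run inference over a dataset split and compute P/R/AP/mAP@0.5."""
    model.eval()
    dets_all, gts_all = [], []
    i = 0
    for x, _ in dataset.batches(batch_size):
        ids = [dataset.stems[j] for j in range(i, i + x.shape[0])]
        dets = model.predict(x, conf_thr=conf_thr, iou_thr=nms_iou,
                             image_ids=ids)
        dets_all.extend(dets)
        for j in range(i, i + x.shape[0]):
            gts_all.append(dataset.ground_truth_xyxy(j))
        i += x.shape[0]
    res = evaluate_detections(dets_all, gts_all, n_classes=model.n_classes,
                              iou_threshold=map_iou)
    out = {"map50": res["map50"]}
    for c, row in res["per_class"].items():
        out[f"ap_{c}"] = row["ap"]
    return out
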