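"""Full detector assembly: backbone taps -> bidirectional neck -> DyHead.

``LeafDetector`` wires the depthwise-separable backbone, the
BiECAFusion/BoT neck and the DyHead detect layers into one module,
exposes the channel-dependency graph for structured pruning, and owns
the anchor set used for decoding and loss assignment.
"""

from __future__ import annotations

import pickle

import numpy as np

from .backbone import Backbone, BackboneTable
from .fusion import Neck
from .head import AnchorSet, Head, detect_and_decode
from .modules import Module, seed_init
from .pruning import PruneGraph


class LeafDetector(Module):
    def __init__(self, n_classes=3, attention="eca", head_channels=64,
                 dyhead_blocks=2, bot_heads=4, img_size=640,
                 anchors: AnchorSet = None, backbone_table: BackboneTable = None,
                 sppcspc_pools=(5, 9, 13), seed=0):
        super().__init__()
        seed_init(seed)
        self.n_classes = n_classes
        self.img_size = img_size
        base_anchors = anchors or AnchorSet()
        self.anchors = base_anchors if base_anchors.img_size == img_size \
            else base_anchors.scaled(img_size)
        table = backbone_table or BackboneTable()
        self.backbone = Backbone(table)
        tap_ch = tuple(table.stages[i][1].out_ch for i in table.tap_indices)
        grid = max(img_size // 32, 1)
        self.neck = Neck(in_channels=tap_ch, attention=attention,
                         bot_heads=bot_heads, grid=(grid, grid),
                         pool_kernels=tuple(sppcspc_pools))
        self.head = Head(in_channels=self.neck.out_channels,
                         head_channels=head_channels, n_classes=n_classes,
                         k_blocks=dyhead_blocks)

    def forward(self, x):
        taps = self.backbone(x)
        pyr = self.neck(taps)
        return self.head(pyr)

    def predict(self, x, conf_thr=0.25, iou_thr=0.45, image_ids=None):
        from . import tensor as T
        self.eval()
        with T.no_grad():
            outputs = self.forward(x)
        return detect_and_decode(outputs, self.anchors, conf_thr, iou_thr,
                                 image_ids=image_ids)

    def build_prune_graph(self):
        g = PruneGraph()
        ax_in = g.new_axis(3, protected=True)
        a3, a4, a5 = self.backbone.register_prune(g, ax_in)
        t3, t4, t5 = self.neck.register_prune(g, a3, a4, a5)
        self.head.register_prune(g, t3, t4, t5)
        return g

    def param_report(self):
        rows = [("backbone", self.backbone.count_parameters()),
                ("neck", self.neck.count_parameters()),
                ("head", self.head.count_parameters())]
        rows.append(("total", sum(c for _, c in rows)))
        return rows

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path):
        with open(path, "rb") as fh:
            return pickle.load(fh)
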