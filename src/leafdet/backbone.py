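"""Reconstructed PP-LCNet-style detection backbone.

The backbone is a stem convolution followed by a cascade of
depthwise-separable blocks (3x3 and 5x5 kernels, H-Swish activations)
with no squeeze-excitation stages and no classifier head; three taps at
strides 8/16/32 feed the neck.  ``DEFAULT_TABLE`` encodes the default
ten-stage layout; with a 640x640 input the taps emit 128x80x80,
256x40x40 and 512x20x20 maps.

Per-stage trainable-parameter closed forms (bias-free convs, 2 affine
scalars per normalized channel):

* stem (standard conv):      ``k^2*Cin*Cout + 2*Cout``
* depthwise-separable block: ``k^2*Cin + 2*Cin + Cin*Cout + 2*Cout``
"""

from __future__ import annotations

from dataclasses import dataclass

from .layers import CBL, ConvSpec
from .modules import BatchNorm2d, Conv2d, Module


@dataclass(frozen=True)
class DepthSepConvSpec:
    """Four-tuple (in, out, kernel, stride); padding is implied (k // 2)."""

    in_ch: int
    out_ch: int
    kernel: int
    stride: int

    def __post_init__(self):
        if self.in_ch <= 0 or self.out_ch <= 0:
            raise ValueError("channel counts must be positive")
        if self.kernel not in (3, 5):
            raise ValueError("DepthSepConv kernel must be 3 or 5")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


class DepthSepConv(Module):
    """Depthwise k x k conv -> norm -> H-Swish -> pointwise 1x1 -> norm -> H-Swish."""

    def __init__(self, spec: DepthSepConvSpec):
        super().__init__()
        if not isinstance(spec, DepthSepConvSpec):
            spec = DepthSepConvSpec(*spec)
        self.spec = spec
        c1, c2, k, s = spec.in_ch, spec.out_ch, spec.kernel, spec.stride
        self.dw = Conv2d(c1, c1, k, stride=s, padding=k // 2, groups=c1)
        self.bn1 = BatchNorm2d(c1)
        self.pw = Conv2d(c1, c2, 1, stride=1, padding=0)
        self.bn2 = BatchNorm2d(c2)

    def forward(self, x):
        x = self.bn1(self.dw(x)).hard_swish()
        return self.bn2(self.pw(x)).hard_swish()

    @property
    def param_count(self):
        return self.count_parameters()

    def register_prune(self, g, ax_in):
        g.attach(ax_in, self.dw, "both")
        g.attach_bn(ax_in, self.bn1)
        return g.conv_node(ax_in, self.pw, self.bn2)


def make_depth_sep_conv(spec) -> DepthSepConv:
    return DepthSepConv(spec)


# Default stage table: (repeat_n, spec).  A ConvSpec row is a standard
# convolution stage (the stem); DepthSepConvSpec rows are separable blocks.
DEFAULT_TABLE = (
    (1, ConvSpec(3, 16, 3, 2, 1)),
    (1, DepthSepConvSpec(16, 32, 3, 1)),
    (1, DepthSepConvSpec(32, 64, 3, 2)),
    (1, DepthSepConvSpec(64, 64, 3, 1)),
    (1, DepthSepConvSpec(64, 128, 3, 2)),
    (1, DepthSepConvSpec(128, 128, 3, 1)),
    (1, DepthSepConvSpec(128, 256, 3, 2)),
    (5, DepthSepConvSpec(256, 256, 5, 1)),
    (1, DepthSepConvSpec(256, 512, 5, 2)),
    (1, DepthSepConvSpec(512, 512, 5, 1)),
)

DEFAULT_TAPS = (5, 7, 9)  # stage indices exported as P3 / P4 / P5


@dataclass(frozen=True)
class BackboneTable:
    stages: tuple = DEFAULT_TABLE
    tap_indices: tuple = DEFAULT_TAPS

    def __post_init__(self):
        prev_out = None
        for n, spec in self.stages:
            if n < 1:
                raise ValueError("repeat factor must be >= 1")
            if prev_out is not None and spec.in_ch != prev_out:
                raise ValueError(
                    f"channel chaining mismatch: stage expects {spec.in_ch} "
                    f"inputs but previous stage emits {prev_out}"
                )
            if n > 1 and spec.in_ch != spec.out_ch:
                raise ValueError("repeated stages must preserve channel count")
            prev_out = spec.out_ch
        for t in self.tap_indices:
            if not 0 <= t < len(self.stages):
                raise ValueError("tap index out of range")


class _Stage(Module):
    def __init__(self, n, spec):
        super().__init__()
        if isinstance(spec, ConvSpec):
            self.blocks = [CBL(spec) for _ in range(n)]
        else:
            self.blocks = [DepthSepConv(spec) for _ in range(n)]
        self.spec = spec
        self.n = n

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x

    def register_prune(self, g, ax):
        for b in self.blocks:
            ax = b.register_prune(g, ax)
        return ax


class Backbone(Module):
    """Sequential stage composition exposing the three pyramid taps."""

    def __init__(self, table: BackboneTable = None):
        super().__init__()
        self.table = table or BackboneTable()
        self.stages = [_Stage(n, spec) for n, spec in self.table.stages]

    def forward(self, x):
        taps = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i in self.table.tap_indices:
                taps.append(x)
        if len(self.table.tap_indices) == 0:
            return x
        return tuple(taps) if len(taps) > 1 else taps[0]

    def param_report(self):
        """Per-stage trainable parameter counts, ``[(stage_index, count), ...]``."""
        return [(i, s.count_parameters()) for i, s in enumerate(self.stages)]

    def register_prune(self, g, ax_in, protect_stem=True):
        tap_axes = {}
        ax = ax_in
        for i, stage in enumerate(self.stages):
            ax = stage.register_prune(g, ax)
            if i == 0 and protect_stem:
                g.protect(ax)
            if i in self.table.tap_indices:
                tap_axes[i] = ax
        return [tap_axes[i] for i in self.table.tap_indices]


def build_backbone(table: BackboneTable = None) -> Backbone:
    return Backbone(table)


def backbone_param_report(backbone: Backbone):
    return backbone.param_report()
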