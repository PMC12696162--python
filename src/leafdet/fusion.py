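"""Neck construction: Bottleneck Transformer block, BiECAFusion nodes and
the bidirectional pyramid assembly.

The neck takes the three backbone taps (stride 8/16/32), compresses the
deepest map through SPPCSPC, models global spatial context with a
residual multi-head self-attention bottleneck on the 20x20 grid, and
then runs a top-down followed by a bottom-up pass.  Every cross-scale
merge is a BiECAFusion node: both inputs are channel-aligned by 1x1
convolutions, an ECA gate vector computed on their concatenation is
split in two, and each branch is enhanced with the *other* branch's
gated feature (x0' + w1*x1', x1' + w0*x0') before a 1x1 merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .attention import ECA, make_attention
from .layers import CBL, ELAN, SPPCSPC
from .modules import Conv2d, Module, Parameter


@dataclass
class FeaturePyramid:
    """The three pyramid maps; H and W halve from p3 to p4 to p5."""

    p3: object
    p4: object
    p5: object

    def __iter__(self):
        return iter((self.p3, self.p4, self.p5))

    def validate(self):
        shapes = [t.shape for t in self]
        for a, b in zip(shapes[:-1], shapes[1:]):
            if a[2] != 2 * b[2] or a[3] != 2 * b[3]:
                raise ValueError(
                    f"pyramid levels are not dyadic multiples: {shapes}"
                )
        return self


@dataclass(frozen=True)
class MhsaConfig:
    dim: int
    heads: int = 4
    height: int = 20
    width: int = 20

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")


class MHSA(Module):
    """Multi-head self-attention over a small spatial grid.

    Content logits (q . k) plus separable 2-D relative-position logits
    (q . (r_h + r_w)), softmax over all H*W key positions, followed by a
    nonlinear projection block (linear -> GELU -> linear, hidden = dim).
    ``height``/``width`` bound the largest attended grid; smaller inputs
    use the leading slice of the position embeddings.
    """

    def __init__(self, cfg: MhsaConfig):
        super().__init__()
        self.cfg = cfg
        d, h = cfg.dim, cfg.heads
        self.dh = d // h
        self.q = Conv2d(d, d, 1, padding=0)
        self.k = Conv2d(d, d, 1, padding=0)
        self.v = Conv2d(d, d, 1, padding=0)
        from . import modules as _m
        self.rel_h = Parameter(_m._init_rng.normal(
            0, self.dh ** -0.5, (h, self.dh, cfg.height, 1)))
        self.rel_w = Parameter(_m._init_rng.normal(
            0, self.dh ** -0.5, (h, self.dh, 1, cfg.width)))
        self.proj1 = Conv2d(d, d, 1, padding=0, bias=True)
        self.proj2 = Conv2d(d, d, 1, padding=0, bias=True)

    def attend(self, x):
        """Scaled dot-product attention with relative positions (no projection)."""
        x = T.as_tensor(x)
        n, c, hh, ww = x.shape
        if hh > self.cfg.height or ww > self.cfg.width:
            raise ValueError("input grid exceeds the attended grid bound")
        nh, dh = self.cfg.heads, self.dh
        s = hh * ww

        def split_heads(t):  # (N, C, H, W) -> (N, heads, S, dh)
            return t.reshape(n, nh, dh, s).transpose(0, 1, 3, 2)

        q = split_heads(self.q(x))
        k = split_heads(self.k(x))
        v = split_heads(self.v(x))
        # separable relative position embedding, sliced to the input grid
        r = (self.rel_h[:, :, :hh, :] + self.rel_w[:, :, :, :ww]).reshape(nh, dh, s)
        content = q @ k.transpose(0, 1, 3, 2)          # (N, heads, S, S)
        position = q @ r                                # broadcast over N
        attn = ((content + position) * (dh ** -0.5)).softmax(axis=-1)
        out = attn @ v                                  # (N, heads, S, dh)
        return out.transpose(0, 1, 3, 2).reshape(n, c, hh, ww)

    def forward(self, x):
        y = self.attend(x)
        return self.proj2(self.proj1(y).gelu())

    def register_prune(self, g, ax):
        for conv in (self.q, self.k, self.v):
            a = g.conv_node(ax, conv)
            g.protect(a)  # head split and rel-pos embeddings tie to these widths
        a = g.new_axis(self.cfg.dim)
        g.protect(a)
        g.attach(a, self.proj1, "in")
        ah = g.new_axis(self.proj1.out_channels)
        g.attach(ah, self.proj1, "out")
        g.attach(ah, self.proj2, "in")
        out = g.new_axis(self.proj2.out_channels)
        g.attach(out, self.proj2, "out")
        g.union(out, ax)  # output channels carry the same meaning as the input
        return ax


def make_mhsa(cfg: MhsaConfig) -> MHSA:
    return MHSA(cfg)


class BoTBlock(Module):
    """Residual bottleneck whose 3x3 conv is replaced by MHSA.

    1x1 reduce -> MHSA (+ nonlinear projection) -> 1x1 expand, residual
    add.  Applied on the stride-32 path only, where the grid is small.
    """

    def __init__(self, in_ch, heads=4, grid=(20, 20)):
        super().__init__()
        h = max(in_ch // 2, heads)
        self.cv1 = CBL(in_ch, h, 1)
        self.mhsa = MHSA(MhsaConfig(h, heads, grid[0], grid[1]))
        self.cv2 = CBL(h, in_ch, 1)

    def forward(self, x):
        x = T.as_tensor(x)
        return x + self.cv2(self.mhsa(self.cv1(x)))

    def register_prune(self, g, ax):
        a = self.cv1.register_prune(g, ax)
        g.protect(a)
        a = self.mhsa.register_prune(g, a)
        out = self.cv2.register_prune(g, a)
        g.union(out, ax)  # residual ties output to input channels
        return ax


def make_bot_block(in_ch, heads=4, grid=(20, 20)) -> BoTBlock:
    return BoTBlock(in_ch, heads, grid)


class BiECAFusion(Module):
    """Bidirectional ECA-gated fusion of two same-resolution maps.

    (1) 1x1 CBL aligns both inputs to ``out_ch``; (2) their concatenation
    drives an ECA gate vector over 2*out_ch channels, split into w0/w1;
    (3) reciprocal enhancement a = x0' + w1*x1', b = x1' + w0*x0';
    (4) a and b merge by concat + 1x1 CBL back to ``out_ch``.
    """

    def __init__(self, in0, in1, out_ch):
        super().__init__()
        if out_ch <= 0:
            raise ValueError("out_ch must be positive")
        self.align0 = CBL(in0, out_ch, 1)
        self.align1 = CBL(in1, out_ch, 1)
        self.eca = ECA(2 * out_ch)
        self.merge = CBL(2 * out_ch, out_ch, 1)
        self.out_ch = out_ch

    def fuse(self, x0, x1):
        """The two reciprocal branches (a, b) before the merge CBL."""
        x0 = T.as_tensor(x0)
        x1 = T.as_tensor(x1)
        if x0.shape[2:] != x1.shape[2:]:
            raise ValueError(
                f"spatial mismatch: {x0.shape[2:]} vs {x1.shape[2:]}"
            )
        a0 = self.align0(x0)
        a1 = self.align1(x1)
        g = self.eca.gates(T.concat([a0, a1], axis=1))  # (N, 2*out_ch)
        c = a0.shape[1]
        w0 = g[:, :c].reshape(g.shape[0], c, 1, 1)
        w1 = g[:, c:].reshape(g.shape[0], c, 1, 1)
        return a0 + w1 * a1, a1 + w0 * a0

    def forward(self, x0, x1):
        a, b = self.fuse(x0, x1)
        return self.merge(T.concat([a, b], axis=1))

    def register_prune(self, g, ax0, ax1):
        a0 = self.align0.register_prune(g, ax0)
        a1 = self.align1.register_prune(g, ax1)
        g.union(a0, a1)  # the split of the gate vector ties both widths
        return self.merge.register_prune(g, g.concat_node([a0, a1]))


class Neck(Module):
    """SPPCSPC + BoT on P5, then top-down and bottom-up BiECAFusion passes
    with ELAN refinement, emitting 64/128/256-channel P3/P4/P5 by default."""

    def __init__(self, in_channels=(128, 256, 512), out_channels=(64, 128, 256),
                 attention="eca", bot_heads=4, grid=(20, 20),
                 pool_kernels=(5, 9, 13)):
        super().__init__()
        c3, c4, c5 = in_channels
        o3, o4, o5 = out_channels
        self.tap_att = [make_attention(attention, c) or _Passthrough()
                        for c in in_channels]
        self.spp = SPPCSPC(c5, o5, pool_kernels)
        self.bot = BoTBlock(o5, heads=bot_heads, grid=grid)
        # top-down
        self.fuse_td4 = BiECAFusion(c4, o5, o4)
        self.elan_td4 = ELAN(o4, o4)
        self.fuse_td3 = BiECAFusion(c3, o4, o3)
        self.elan_td3 = ELAN(o3, o3)
        # bottom-up
        self.down3 = CBL(o3, o4, 3, stride=2)
        self.fuse_bu4 = BiECAFusion(o4, o4, o4)
        self.elan_bu4 = ELAN(o4, o4)
        self.down4 = CBL(o4, o5, 3, stride=2)
        self.fuse_bu5 = BiECAFusion(o5, o5, o5)
        self.elan_bu5 = ELAN(o5, o5)
        self.out_channels = out_channels

    def forward(self, pyramid):
        if not isinstance(pyramid, FeaturePyramid):
            pyramid = FeaturePyramid(*pyramid)
        pyramid.validate()
        p3 = self.tap_att[0](pyramid.p3)
        p4 = self.tap_att[1](pyramid.p4)
        p5 = self.tap_att[2](pyramid.p5)

        n5 = self.bot(self.spp(p5))
        t4 = self.elan_td4(self.fuse_td4(p4, T.upsample_nearest2d(n5)))
        t3 = self.elan_td3(self.fuse_td3(p3, T.upsample_nearest2d(t4)))

        b4 = self.elan_bu4(self.fuse_bu4(self.down3(t3), t4))
        b5 = self.elan_bu5(self.fuse_bu5(self.down4(b4), n5))
        return FeaturePyramid(t3, b4, b5)

    def register_prune(self, g, ax3, ax4, ax5):
        for att, ax in zip(self.tap_att, (ax3, ax4, ax5)):
            if hasattr(att, "register_prune"):
                ax = att.register_prune(g, ax)
        a5 = self.spp.register_prune(g, ax5)
        a5 = self.bot.register_prune(g, a5)
        t4 = self.fuse_td4.register_prune(g, ax4, a5)
        t4 = self.elan_td4.register_prune(g, t4)
        t3 = self.fuse_td3.register_prune(g, ax3, t4)
        t3 = self.elan_td3.register_prune(g, t3)
        d3 = self.down3.register_prune(g, t3)
        b4 = self.fuse_bu4.register_prune(g, d3, t4)
        b4 = self.elan_bu4.register_prune(g, b4)
        d4 = self.down4.register_prune(g, b4)
        b5 = self.fuse_bu5.register_prune(g, d4, a5)
        b5 = self.elan_bu5.register_prune(g, b5)
        return t3, b4, b5


class _Passthrough(Module):
    def forward(self, x):
        return x


def build_neck(in_channels=(128, 256, 512), out_channels=(64, 128, 256),
               attention="eca", bot_heads=4, grid=(20, 20),
               pool_kernels=(5, 9, 13)) -> Neck:
    return Neck(in_channels, out_channels, attention, bot_heads, grid,
                pool_kernels)
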