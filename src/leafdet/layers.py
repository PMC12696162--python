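"""Shared convolutional building blocks: H-Swish, CBL, ELAN, SPPCSPC.

Conventions fixed across the whole network (they are what make the
backbone parameter table reproduce exactly):

* convolutions carry no bias;
* normalization contributes exactly 2 trainable scalars per channel
  (scale + shift); running statistics are buffers, not parameters;
* a CBL therefore counts ``k^2 * Cin * Cout + 2 * Cout`` trainables;
* LeakyReLU negative slope is 0.1;
* stride-1 blocks preserve spatial size, stride-2 blocks halve it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .modules import BatchNorm2d, Conv2d, Module
from .tensor import Tensor


def hard_swish(x):
    """H-Swish activation: ``x * clamp(x + 3, 0, 6) / 6`` elementwise.

    Accepts scalars, ndarrays or Tensors (differentiable on Tensors).
    """
    if isinstance(x, Tensor):
        return x.hard_swish()
    x = np.asarray(x, dtype=np.float64)
    out = x * np.clip(x + 3.0, 0.0, 6.0) / 6.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConvSpec:
    """Standard-convolution five-tuple (in, out, kernel, stride, padding)."""

    in_ch: int
    out_ch: int
    kernel: int
    stride: int
    padding: int = None  # defaults to kernel // 2

    def __post_init__(self):
        if self.in_ch <= 0 or self.out_ch <= 0:
            raise ValueError("channel counts must be positive")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.padding is None:
            object.__setattr__(self, "padding", self.kernel // 2)


class CBL(Module):
    """Conv (bias-free) -> per-channel affine normalization -> LeakyReLU(0.1)."""

    LEAKY_SLOPE = 0.1

    def __init__(self, spec_or_in, out_ch=None, kernel=1, stride=1, padding=None):
        super().__init__()
        if isinstance(spec_or_in, ConvSpec):
            spec = spec_or_in
        else:
            spec = ConvSpec(spec_or_in, out_ch, kernel, stride, padding)
        self.spec = spec
        self.conv = Conv2d(spec.in_ch, spec.out_ch, spec.kernel,
                           stride=spec.stride, padding=spec.padding)
        self.bn = BatchNorm2d(spec.out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).leaky_relu(self.LEAKY_SLOPE)

    @property
    def param_count(self):
        return self.count_parameters()

    def register_prune(self, g, ax_in):
        return g.conv_node(ax_in, self.conv, self.bn)


def make_cbl(spec: ConvSpec) -> CBL:
    """Build a CBL block; ``param_count`` = k^2*Cin*Cout + 2*Cout."""
    return CBL(spec)


class ELAN(Module):
    """YOLOv7-tiny efficient layer aggregation block.

    Two parallel 1x1 halvings of the input, a chain of two 3x3 convs on
    the second branch, concatenation of the four intermediate maps, and a
    final 1x1 projection to ``out_ch``.  Spatial size is preserved.
    """

    def __init__(self, in_ch, out_ch):
        super().__init__()
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        if out_ch % 2:
            raise ValueError("ELAN out_ch must be even (hidden split halves it)")
        h = out_ch // 2
        self.cv1 = CBL(in_ch, h, 1)
        self.cv2 = CBL(in_ch, h, 1)
        self.cv3 = CBL(h, h, 3)
        self.cv4 = CBL(h, h, 3)
        self.cv5 = CBL(4 * h, out_ch, 1)

    def forward(self, x):
        y1 = self.cv1(x)
        y2 = self.cv2(x)
        y3 = self.cv3(y2)
        y4 = self.cv4(y3)
        return self.cv5(T.concat([y4, y3, y2, y1], axis=1))

    @property
    def param_count(self):
        return self.count_parameters()

    def register_prune(self, g, ax_in):
        a1 = self.cv1.register_prune(g, ax_in)
        a2 = self.cv2.register_prune(g, ax_in)
        a3 = self.cv3.register_prune(g, a2)
        a4 = self.cv4.register_prune(g, a3)
        cat = g.concat_node([a4, a3, a2, a1])
        return self.cv5.register_prune(g, cat)


def make_elan(in_ch, out_ch) -> ELAN:
    return ELAN(in_ch, out_ch)


class SPPCSPC(Module):
    """Spatial-pyramid-pooling block with a cross-stage partial shortcut.

    One pathway applies a direct CBL; the other runs a CBL stack, branches
    into an identity map plus three stride-1 max-poolings with distinct
    odd kernels (default 5/9/13, padding k//2 so size is preserved),
    concatenates, refines, and the two pathways merge through a final 1x1
    CBL to ``out_ch``.
    """

    def __init__(self, in_ch, out_ch, pool_kernels=(5, 9, 13)):
        super().__init__()
        pool_kernels = tuple(pool_kernels)
        if len(pool_kernels) != 3 or len(set(pool_kernels)) != 3:
            raise ValueError("pool_kernels must be three distinct integers")
        if any(k % 2 == 0 or k < 3 for k in pool_kernels):
            raise ValueError("pool kernels must be odd and >= 3")
        h = out_ch // 2 if out_ch > 1 else out_ch
        self.pool_kernels = pool_kernels
        self.cv1 = CBL(in_ch, h, 1)
        self.cv3 = CBL(h, h, 3)
        self.cv4 = CBL(h, h, 1)
        self.cv5 = CBL(4 * h, h, 1)
        self.cv6 = CBL(h, h, 3)
        self.cv2 = CBL(in_ch, h, 1)  # direct pathway
        self.cv7 = CBL(2 * h, out_ch, 1)

    def forward(self, x):
        y = self.cv4(self.cv3(self.cv1(x)))
        pools = [y] + [T.max_pool2d(y, k, stride=1, padding=k // 2)
                       for k in self.pool_kernels]
        y = self.cv6(self.cv5(T.concat(pools, axis=1)))
        shortcut = self.cv2(x)
        return self.cv7(T.concat([y, shortcut], axis=1))

    @property
    def param_count(self):
        return self.count_parameters()

    def register_prune(self, g, ax_in):
        a = self.cv1.register_prune(g, ax_in)
        a = self.cv3.register_prune(g, a)
        a = self.cv4.register_prune(g, a)
        cat = g.concat_node([a, a, a, a])  # identity + three pools share the axis
        b = self.cv5.register_prune(g, cat)
        b = self.cv6.register_prune(g, b)
        c = self.cv2.register_prune(g, ax_in)
        return self.cv7.register_prune(g, g.concat_node([b, c]))


def make_sppcspc(in_ch, out_ch, pool_kernels=(5, 9, 13)) -> SPPCSPC:
    return SPPCSPC(in_ch, out_ch, pool_kernels)


def count_parameters(block) -> int:
    """Exact count of trainable scalars in a block (0 for ``None``)."""
    if block is None:
        return 0
    if isinstance(block, Module):
        return block.count_parameters()
    raise TypeError(f"cannot count parameters of {type(block)!r}")
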