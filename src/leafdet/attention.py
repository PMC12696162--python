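"""Channel attention operators: ECA (core), plus SE and CBAM for parity.

ECA gates channels with a single shared 1-D convolution over the
globally averaged channel descriptor — no fully connected layers, so the
cost per insertion site is just the (adaptive, odd) kernel length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .modules import Conv2d, Linear, Module, Parameter
from .tensor import Tensor


@dataclass(frozen=True)
class EcaConfig:
    channels: int
    gamma: int = 2
    b: int = 1

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.gamma <= 0 or self.b < 0:
            raise ValueError("gamma must be positive and b non-negative")


def eca_kernel_size(cfg: EcaConfig) -> int:
    """Adaptive 1-D kernel: ``t = floor(|log2(C)/gamma + b/gamma|)``, rounded
    up to the nearest odd integer, minimum 1."""
    t = int(abs(np.log2(cfg.channels) / cfg.gamma + cfg.b / cfg.gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


class ECA(Module):
    """Efficient channel attention: GAP -> 1-D conv across channels -> sigmoid gate."""

    def __init__(self, channels, gamma=2, b=1):
        super().__init__()
        self.cfg = EcaConfig(channels, gamma, b)
        k = eca_kernel_size(self.cfg)
        self.kernel_size = k
        # single shared filter, no bias: exactly k trainable scalars
        self.filter = Parameter(np.zeros(k))
        self.filter.data[k // 2] = 1.0  # near-identity start: gate ~ sigmoid(mean)

    def gates(self, x):
        """Per-channel sigmoid gates in (0,1), shape (N, C)."""
        x = T.as_tensor(x)
        d = T.global_avg_pool(x)  # (N, C)
        d4 = d.reshape(d.shape[0], 1, 1, d.shape[1])
        w4 = self.filter.reshape(1, 1, 1, self.kernel_size)
        g = T.conv2d(d4, w4, padding=(0, self.kernel_size // 2))
        return g.reshape(d.shape).sigmoid()

    def forward(self, x):
        x = T.as_tensor(x)
        g = self.gates(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1, 1)

    def register_prune(self, g, ax):
        return ax  # parameter count is channel-agnostic


def make_eca(cfg: EcaConfig) -> ECA:
    return ECA(cfg.channels, cfg.gamma, cfg.b)


class SE(Module):
    """Squeeze-and-excitation: GAP -> C/r bottleneck -> sigmoid gate."""

    def __init__(self, channels, reduction=4):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by reduction")
        self.fc1 = Linear(channels, channels // reduction, bias=False)
        self.fc2 = Linear(channels // reduction, channels, bias=False)

    def gates(self, x):
        x = T.as_tensor(x)
        d = T.global_avg_pool(x)
        return self.fc2(self.fc1(d).relu()).sigmoid()

    def forward(self, x):
        x = T.as_tensor(x)
        g = self.gates(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1, 1)

    def register_prune(self, g, ax):
        g.protect(ax)  # FC widths are tied to the exact channel count
        return ax


def make_se(channels, reduction=4) -> SE:
    return SE(channels, reduction)


class CBAM(Module):
    """Channel-then-spatial attention; both gates in (0,1), shape preserved."""

    def __init__(self, channels, reduction=4, spatial_kernel=7):
        super().__init__()
        r = reduction if channels % reduction == 0 else 1
        self.fc1 = Linear(channels, max(channels // r, 1), bias=False)
        self.fc2 = Linear(max(channels // r, 1), channels, bias=False)
        self.spatial = Conv2d(2, 1, spatial_kernel, padding=spatial_kernel // 2)

    def forward(self, x):
        x = T.as_tensor(x)
        avg = T.global_avg_pool(x)
        mx = x.reshape(x.shape[0], x.shape[1], -1).max(axis=2)
        cg = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * cg.reshape(cg.shape[0], cg.shape[1], 1, 1)
        return x * self.spatial_gate(x)

    def spatial_gate(self, x):
        x = T.as_tensor(x)
        savg = x.mean(axis=1, keepdims=True)
        smax = x.max(axis=1, keepdims=True)
        return self.spatial(T.concat([savg, smax], axis=1)).sigmoid()

    def register_prune(self, g, ax):
        g.protect(ax)
        return ax


def make_cbam(channels) -> CBAM:
    return CBAM(channels)


def make_attention(kind, channels):
    """Factory for the config enum: "eca" | "se" | "cbam" | "none"."""
    if kind == "eca":
        return ECA(channels)
    if kind == "se":
        return SE(channels)
    if kind == "cbam":
        return CBAM(channels)
    if kind in (None, "none"):
        return None
    raise ValueError(f"unknown attention kind: {kind!r}")
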