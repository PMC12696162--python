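"""Parameterized layer abstractions on top of :mod:`leafdet.tensor`.

Mirrors the familiar Module/Parameter idiom: a :class:`Module` owns
parameters and sub-modules discovered by attribute reflection, supports
train/eval switching, exact trainable-parameter counting, and state-dict
(de)serialization.  Conv/norm/linear layers additionally expose channel
surgery (``drop_out_channels`` / ``drop_in_channels``) used by the
structured pruner.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

# RNG used for weight initialization; seeded by model constructors so a
# given (config, seed) pair always builds bit-identical weights.
_init_rng = np.random.default_rng(0)


def seed_init(seed):
    global _init_rng
    _init_rng = np.random.default_rng(int(seed))


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- reflection ------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def count_parameters(self):
        """Exact count of trainable scalars (running statistics excluded)."""
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[name + ".running_mean"] = m.running_mean.copy()
                state[name + ".running_var"] = m.running_var.copy()
        return state

    def _named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for cname, child in self._children():
            yield from child._named_modules(prefix + cname + ".")

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(np.float32).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                if name + ".running_mean" in state:
                    m.running_mean = state[name + ".running_mean"].astype(np.float32).copy()
                    m.running_var = state[name + ".running_var"].astype(np.float32).copy()


class Conv2d(Module):
    """Bias-free by default, matching the backbone parameter accounting."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=None, groups=1, bias=False):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = in_channels // groups * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _init_rng.normal(0.0, std, (out_channels, in_channels // groups, k, k))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)

    @property
    def depthwise(self):
        return self.groups == self.in_channels and self.groups > 1

    def drop_out_channels(self, idx):
        self.weight.data = np.delete(self.weight.data, idx, axis=0)
        if self.bias is not None:
            self.bias.data = np.delete(self.bias.data, idx, axis=0)
        self.out_channels = self.weight.data.shape[0]
        if self.depthwise or self.groups == self.in_channels:
            self.in_channels = self.out_channels
            self.groups = self.out_channels

    def drop_in_channels(self, idx):
        if self.groups == 1:
            self.weight.data = np.delete(self.weight.data, idx, axis=1)
            self.in_channels = self.weight.data.shape[1]
        else:  # depthwise: in == out == groups, handled by drop_out_channels
            self.drop_out_channels(idx)


class BatchNorm2d(Module):
    """Per-channel normalization: 2 trainable scalars per channel.

    Running statistics are buffers, not parameters, so the closed-form
    parameter accounting (k^2*Cin*Cout + 2*Cout for a CBL) holds exactly.
    """

    def __init__(self, channels, momentum=0.03, eps=1e-3):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              momentum=self.momentum, eps=self.eps)

    def drop_channels(self, idx):
        self.gamma.data = np.delete(self.gamma.data, idx, axis=0)
        self.beta.data = np.delete(self.beta.data, idx, axis=0)
        self.running_mean = np.delete(self.running_mean, idx, axis=0)
        self.running_var = np.delete(self.running_var, idx, axis=0)
        self.channels = self.gamma.data.shape[0]


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(
            _init_rng.uniform(-bound, bound, (out_features, in_features))
        )
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)

    def drop_out_channels(self, idx):
        self.weight.data = np.delete(self.weight.data, idx, axis=0)
        if self.bias is not None:
            self.bias.data = np.delete(self.bias.data, idx, axis=0)
        self.out_features = self.weight.data.shape[0]

    def drop_in_channels(self, idx):
        self.weight.data = np.delete(self.weight.data, idx, axis=1)
        self.in_features = self.weight.data.shape[1]


class Sequential(Module):
    def __init__(self, *blocks):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)

    def __getitem__(self, i):
        return self.blocks[i]


class Identity(Module):
    def forward(self, x):
        return x
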