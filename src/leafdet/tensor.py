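"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized for desk-scale training of the detector:
every value is a :class:`Tensor` wrapping a float32 ``numpy`` array, and
each primitive records a closure that propagates the cotangent to its
parents.  Convolution, batch normalization, pooling and the binary
cross-entropy are fused primitives (single GEMM / single pass) because
they dominate the run time; everything else is composed from elementwise
ops and reductions.

The module-level helpers (:func:`exp`, :func:`clip`, ...) dispatch on
either plain arrays or Tensors so numeric formulas (IoU, Shape-IoU, box
decoding) can be written once and reused for both evaluation and
training.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

# When not None, conv2d/linear append their multiply-accumulate counts
# (per batch element) here; used by the pruning module's FLOPs probe.
_FLOP_RECORDER = None


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextmanager
def record_flops(units):
    """Accumulate per-weight spatial output units into the dict ``units``
    (keyed by ``id(weight)``); MACs follow from the weight shapes."""
    global _FLOP_RECORDER
    prev = _FLOP_RECORDER
    _FLOP_RECORDER = units
    try:
        yield
    finally:
        _FLOP_RECORDER = prev


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _as_array(x):
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad and id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior cotangents to bound memory
                if not node._is_leaf():
                    node.grad = None
            node._parents = ()
            node._backward = None

    def _is_leaf(self):
        return self._backward is None

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data - other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out_data = self.data ** p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    # -- unary -----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = _sigmoid_np(self.data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo, hi):
        out_data = np.clip(self.data, lo, hi)
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float32)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.maximum(self.data, other.data)
        take_self = (self.data >= other.data).astype(np.float32)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (1.0 - take_self), other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.minimum(self.data, other.data)
        take_self = (self.data <= other.data).astype(np.float32)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (1.0 - take_self), other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def leaky_relu(self, slope=0.1):
        factor = np.where(self.data > 0, 1.0, slope).astype(np.float32)

        def bwd(g):
            self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), bwd)

    def relu(self):
        return self.leaky_relu(0.0)

    def hard_swish(self):
        x = self.data
        inner = np.clip(x + 3.0, 0.0, 6.0)
        out_data = x * inner / 6.0
        deriv = np.where(
            x >= 3.0, 1.0, np.where(x <= -3.0, 0.0, (2.0 * x + 3.0) / 6.0)
        ).astype(np.float32)

        def bwd(g):
            self._accum(g * deriv)

        return Tensor._make(out_data, (self,), bwd)

    def hard_sigmoid(self):
        # x/6 + 1/2 clipped to [0, 1]; saturates exactly, unlike sigmoid
        out_data = np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)
        mask = ((self.data > -3.0) & (self.data < 3.0)).astype(np.float32) / 6.0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def gelu(self):
        # tanh approximation
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        u = c * (x + 0.044715 * x ** 3)
        t = np.tanh(u)
        out_data = 0.5 * x * (1.0 + t)
        du = c * (1.0 + 3 * 0.044715 * x ** 2)
        deriv = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du

        def bwd(g):
            self._accum(g * deriv.astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        return Tensor._make(out_data, (self,), bwd)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)  # ties share the cotangent

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return Tensor._make(
            out_data if keepdims else np.squeeze(out_data, axis=axis), (self,), bwd
        )

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(
            np.ascontiguousarray(self.data.transpose(axes)), (self,), bwd
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(np.ascontiguousarray(out_data), (self,), bwd)

    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bwd)


def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(out_data, tuple(tensors), bwd)


def stack(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(np.take(g, i, axis=axis)))

    return Tensor._make(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# fused NN primitives
# ---------------------------------------------------------------------------


def _sigmoid_np(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _pad_hw(x, ph, pw):
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _im2col(x, kh, kw, sh, sw):
    """(N,C,H,W) -> (N, OH, OW, C*kh*kw) patch matrix (copies)."""
    n, c, h, w = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # N,C,OH,OW,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n, oh, ow, c * kh * kw), oh, ow


def _col2im(gcols, x_shape, kh, kw, sh, sw):
    """Scatter-add patch gradients back; gcols is (N, OH, OW, C, kh, kw)."""
    n, c, h, w = x_shape
    oh = gcols.shape[1]
    ow = gcols.shape[2]
    gx = np.zeros(x_shape, dtype=np.float32)
    for i in range(kh):
        hi = i + sh * oh
        for j in range(kw):
            wj = j + sw * ow
            gx[:, :, i:hi:sh, j:wj:sw] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return gx


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1):
    """2-D cross-correlation. ``weight``: (Cout, Cin/groups, kh, kw).

    groups=1 and depthwise (groups == Cin, Cin/groups == 1) are the fast
    paths; generic grouped convolution falls back to a per-group loop.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    cout, cin_g, kh, kw = weight.data.shape
    n, cin, h, w = x.data.shape
    if cin != cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight expects {cin_g * groups}"
        )
    xp = _pad_hw(x.data, ph, pw)

    if groups == 1:
        cols, oh, ow = _im2col(xp, kh, kw, sh, sw)
        wmat = weight.data.reshape(cout, cin_g * kh * kw)
        out = cols.reshape(-1, cols.shape[-1]) @ wmat.T
        out = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
        out = np.ascontiguousarray(out)
    elif groups == cin and cin_g == 1:
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::sh, ::sw]  # N,C,OH,OW,kh,kw
        oh, ow = win.shape[2], win.shape[3]
        out = np.einsum("nchwij,cij->nchw", win, weight.data[:, 0], optimize=True)
        out = np.ascontiguousarray(out, dtype=np.float32)
        cols = win  # kept for backward
    else:
        outs = []
        xs = np.split(xp, groups, axis=1)
        ws = np.split(weight.data, groups, axis=0)
        for xg, wg in zip(xs, ws):
            cg, _ = wg.shape[0], wg.shape[1]
            colg, oh, ow = _im2col(xg, kh, kw, sh, sw)
            og = colg.reshape(-1, colg.shape[-1]) @ wg.reshape(cg, -1).T
            outs.append(og.reshape(n, oh, ow, cg).transpose(0, 3, 1, 2))
        out = np.ascontiguousarray(np.concatenate(outs, axis=1))
        cols = None

    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    if _FLOP_RECORDER is not None:
        key = id(weight)
        _FLOP_RECORDER[key] = _FLOP_RECORDER.get(key, 0) + int(
            out.shape[2] * out.shape[3])

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            gout = g.transpose(0, 2, 3, 1).reshape(-1, cout)
            if weight.requires_grad:
                gw = gout.T @ cols.reshape(-1, cols.shape[-1])
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = gout @ weight.data.reshape(cout, -1)
                oh_, ow_ = g.shape[2], g.shape[3]
                gcols = gcols.reshape(n, oh_, ow_, cin, kh, kw)
                gxp = _col2im(gcols, xp.shape, kh, kw, sh, sw)
                x._accum(gxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else gxp)
        elif groups == cin and cin_g == 1:
            if weight.requires_grad:
                gw = np.einsum("nchw,nchwij->cij", g, cols, optimize=True)
                weight._accum(gw[:, None].astype(np.float32))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                oh_, ow_ = g.shape[2], g.shape[3]
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + sh * oh_ : sh, j : j + sw * ow_ : sw] += (
                            g * weight.data[None, :, 0, i, j, None, None]
                        )
                x._accum(gxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else gxp)
        else:  # pragma: no cover - generic grouped path unused by the model
            raise NotImplementedError("backward for generic grouped conv")

    return Tensor._make(out, parents, bwd)


def linear(x, weight, bias=None):
    """x: (..., in), weight: (out, in)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data
    if _FLOP_RECORDER is not None:
        key = id(weight)
        _FLOP_RECORDER[key] = _FLOP_RECORDER.get(key, 0) + 1
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if weight.requires_grad:
            g2 = g.reshape(-1, g.shape[-1])
            x2 = x.data.reshape(-1, x.data.shape[-1])
            weight._accum(g2.T @ x2)
        if x.requires_grad:
            x._accum((g @ weight.data).reshape(x.data.shape))

    return Tensor._make(out, parents, bwd)


def batch_norm2d(x, gamma, beta, running_mean, running_var, training,
                 momentum=0.03, eps=1e-3):
    """Per-channel batch normalization on NCHW maps.

    ``running_mean``/``running_var`` are plain ndarrays updated in place in
    training mode (not part of the autodiff graph, not trainable).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        m = n * h * w
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx_hat = g * gamma.data[None, :, None, None]
            if training:
                m = n * h * w
                sum_g = gx_hat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gx_hat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv[None, :, None, None] / m) * (
                    m * gx_hat - sum_g - xhat * sum_gx
                )
            else:
                gx = gx_hat * inv[None, :, None, None]
            x._accum(gx.astype(np.float32))

    return Tensor._make(out.astype(np.float32), (x, gamma, beta), bwd)


def max_pool2d(x, kernel, stride=None, padding=None):
    x = x if isinstance(x, Tensor) else Tensor(x)
    k = kernel
    s = stride if stride is not None else k
    p = padding if padding is not None else 0
    n, c, h, w = x.data.shape
    xp = x.data
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]
    oh, ow = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, oh, ow, k * k)
    arg = flat.argmax(axis=-1)
    out = np.ascontiguousarray(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0])

    def bwd(g):
        if not x.requires_grad:
            return
        gxp = np.zeros(xp.shape, dtype=np.float32)
        ii, jj = np.unravel_index(arg, (k, k))
        oy = np.arange(oh)[None, None, :, None] * s
        ox = np.arange(ow)[None, None, None, :] * s
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci, oy + ii, ox + jj), g)
        x._accum(gxp[:, :, p : p + h, p : p + w] if p else gxp)

    return Tensor._make(out, (x,), bwd)


def upsample_nearest2d(x, factor=2):
    x = x if isinstance(x, Tensor) else Tensor(x)
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def bwd(g):
        n, c, h, w = x.data.shape
        gr = g.reshape(n, c, h, f, w, f).sum(axis=(3, 5))
        x._accum(gr)

    return Tensor._make(np.ascontiguousarray(out), (x,), bwd)


def avg_pool2d(x, factor=2):
    """Non-overlapping average pooling by an integer factor."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    f = int(factor)
    n, c, h, w = x.data.shape
    out = x.data.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def bwd(g):
        gx = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
        x._accum(gx.astype(np.float32))

    return Tensor._make(np.ascontiguousarray(out), (x,), bwd)


def global_avg_pool(x):
    """NCHW -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def bce_with_logits(logits, targets, reduction="mean", weight=None):
    """Numerically stable binary cross-entropy on raw logits.

    ``weight`` (elementwise, optional) computes the weighted mean
    ``sum(w * bce) / sum(w)``; with all-unit weights this is the plain
    mean."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    t = _as_array(targets)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        w = np.asarray(weight, dtype=np.float32)
        wsum = w.sum()
        out_data = (loss * w).sum() / wsum
        scale = w / wsum
    elif reduction == "mean":
        out_data = loss.mean()
        scale = 1.0 / loss.size
    elif reduction == "sum":
        out_data = loss.sum()
        scale = 1.0
    else:
        raise ValueError(reduction)

    def bwd(g):
        logits._accum((g * scale) * (_sigmoid_np(z) - t))

    return Tensor._make(np.float32(out_data), (logits,), bwd)


# ---------------------------------------------------------------------------
# dual-dispatch helpers: work on plain ndarrays/scalars and on Tensors
# ---------------------------------------------------------------------------


def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def absolute(x):
    return x.abs() if isinstance(x, Tensor) else np.abs(x)


def sigmoid(x):
    return x.sigmoid() if isinstance(x, Tensor) else _sigmoid_np(np.asarray(x, dtype=np.float64))


def clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def maximum(a, b):
    if isinstance(a, Tensor):
        return a.maximum(b)
    if isinstance(b, Tensor):
        return b.maximum(a)
    return np.maximum(a, b)


def minimum(a, b):
    if isinstance(a, Tensor):
        return a.minimum(b)
    if isinstance(b, Tensor):
        return b.minimum(a)
    return np.minimum(a, b)
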