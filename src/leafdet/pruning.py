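"""LAMP scoring and global structured channel pruning to a speed-up target.

LAMP (layer-adaptive magnitude pruning) scores each weight by its squared
magnitude normalized against the aggregate squared magnitude of the
weights in the same layer that are at least as large: after a stable
descending sort, ``score[i] = w[i]^2 / cumsum(w^2)[i]``, so the largest
weight of every layer scores exactly 1 and scores are layer-adaptive
without any per-layer ratio tuning.

Structured pruning removes output-channel groups: a dependency graph
built by the model (union-find over channel axes, with concat parents)
propagates every removal through residual additions, concatenations,
depthwise convolutions and shared heads so the pruned network stays
forward-consistent.  Groups are ranked by the sum of LAMP scores over
each channel slice, and the globally least important channel is removed
until FLOPs(base)/FLOPs(pruned) reaches the ``speed_up`` target.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .modules import BatchNorm2d, Conv2d, Linear, Module


@dataclass
class LayerWeights:
    """Flat weight magnitudes of one prunable layer."""

    layer_id: str
    magnitudes: np.ndarray


def lamp_scores(w):
    """Per-weight LAMP scores in (0, 1]; ties broken by stable index order
    (the earlier of two equal weights takes the smaller score).
    All-zero layers score 0 everywhere (fully prunable)."""
    w = np.asarray(w, dtype=np.float64).ravel()
    sq = w ** 2
    if not sq.any():
        return np.zeros_like(sq)
    # descending magnitude; among ties the later index comes first, so the
    # earlier of two equal weights accumulates the larger denominator
    order = np.argsort(np.abs(w), kind="stable")[::-1]
    denom = np.cumsum(sq[order])
    scores = np.empty_like(sq)
    scores[order] = sq[order] / denom
    return scores


def lamp_score_table(layers):
    """Rows (layer_id, index, score) for a {layer_id: weights} mapping."""
    rows = []
    for lid, w in layers.items():
        for i, s in enumerate(lamp_scores(np.asarray(w).ravel())):
            rows.append((lid, i, float(s)))
    return rows


def channel_importance(conv_layer):
    """Per-output-channel importance: sum of LAMP scores over each
    output-channel slice of the layer's weight tensor."""
    w = conv_layer.weight.data
    scores = lamp_scores(w).reshape(w.shape)
    return scores.reshape(w.shape[0], -1).sum(axis=1)


# ---------------------------------------------------------------------------
# dependency graph
# ---------------------------------------------------------------------------


class _Axis:
    __slots__ = ("size", "layers", "concat_children", "concat_parents",
                 "protected", "_uf", "id")
    _next_id = 0

    def __init__(self, size):
        self.size = size
        self.layers = []            # (layer, kind) kind in {in,out,both,bn}
        self.concat_children = None  # ordered list of child axes (for parents)
        self.concat_parents = []     # parent axes this axis is concatenated into
        self.protected = False
        self._uf = self
        self.id = _Axis._next_id
        _Axis._next_id += 1


class PruneGraph:
    """Channel-axis dependency graph over a model's conv/norm/linear layers."""

    def __init__(self):
        self.axes = []

    # -- construction ----------------------------------------------------
    def new_axis(self, size, protected=False):
        ax = _Axis(size)
        ax.protected = protected
        self.axes.append(ax)
        return ax

    def find(self, ax):
        while ax._uf is not ax:
            ax._uf = ax._uf._uf
            ax = ax._uf
        return ax

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra is rb:
            return ra
        if ra.size != rb.size:
            raise ValueError(f"cannot tie axes of size {ra.size} and {rb.size}")
        rb._uf = ra
        ra.layers.extend(rb.layers)
        ra.concat_parents.extend(rb.concat_parents)
        if rb.concat_children is not None:
            if ra.concat_children is not None:
                raise ValueError("cannot union two concat parents")
            ra.concat_children = rb.concat_children
        ra.protected = ra.protected or rb.protected
        return ra

    def protect(self, ax):
        self.find(ax).protected = True

    def attach(self, ax, layer, kind):
        self.find(ax).layers.append((layer, kind))

    def attach_bn(self, ax, bn):
        self.attach(ax, bn, "bn")

    def conv_node(self, ax_in, conv, bn=None):
        """Standard conv consuming ax_in, producing a fresh out axis."""
        self.attach(ax_in, conv, "in")
        out = self.new_axis(conv.out_channels)
        self.attach(out, conv, "out")
        if bn is not None:
            self.attach_bn(out, bn)
        return out

    def concat_node(self, children):
        parent = self.new_axis(sum(self.find(c).size for c in children))
        parent.concat_children = list(children)
        seen = set()
        for c in children:
            r = self.find(c)
            if id(r) not in seen:  # register once even for repeated children
                seen.add(id(r))
                r.concat_parents.append(parent)
        return parent

    # -- surgery ---------------------------------------------------------
    def drop(self, ax, idx, _touched=None):
        """Remove channel indices ``idx`` from axis ``ax`` and propagate.

        Returns the set of layers whose weights changed."""
        touched = _touched if _touched is not None else set()
        ax = self.find(ax)
        idx = np.atleast_1d(np.asarray(idx, dtype=np.intp))
        # map into concat parents BEFORE sizes change (each parent once)
        parent_jobs = []
        seen_parents = set()
        for parent in list(ax.concat_parents):
            p = self.find(parent)
            if id(p) in seen_parents:
                continue
            seen_parents.add(id(p))
            offset = 0
            mapped = []
            for child in p.concat_children:
                c = self.find(child)
                if c is ax:
                    mapped.extend(offset + idx)
                offset += c.size
            parent_jobs.append((p, np.array(sorted(mapped), dtype=np.intp)))
        for layer, kind in ax.layers:
            if kind == "in":
                layer.drop_in_channels(idx)
            elif kind in ("out", "both"):
                layer.drop_out_channels(idx)
            elif kind == "bn":
                layer.drop_channels(idx)
            touched.add(id(layer))
        ax.size -= len(idx)
        for p, mapped in parent_jobs:
            self.drop(p, mapped, touched)
        return touched

    def prunable_roots(self):
        seen, roots = set(), []
        for ax in self.axes:
            r = self.find(ax)
            if id(r) in seen:
                continue
            seen.add(id(r))
            if r.protected or r.concat_children is not None:
                continue
            if any(kind in ("out", "both") for _, kind in r.layers):
                roots.append(r)
        return roots


# ---------------------------------------------------------------------------
# FLOPs accounting
# ---------------------------------------------------------------------------


class FlopsProbe:
    """Records, per conv/linear parameter tensor, the spatial output units
    of one forward pass; FLOPs then follow analytically from the current
    weight shapes (channel pruning never changes spatial sizes)."""

    def __init__(self, model, input_size=640):
        self.model = model
        self.units = {}
        rec = {}
        x = np.zeros((1, 3, input_size, input_size), dtype=np.float32)
        was_training = next(iter(model.modules())).training
        model.eval()
        with T.no_grad(), T.record_flops(rec):
            model(x)
        if was_training:
            model.train()
        self.units = rec  # id(weight) -> summed spatial units across calls

    def flops(self):
        total = 0
        for m in self.model.modules():
            if isinstance(m, Conv2d):
                u = self.units.get(id(m.weight), 0)
                cout, cin_g, kh, kw = m.weight.data.shape
                total += u * cout * cin_g * kh * kw
            elif isinstance(m, Linear):
                u = self.units.get(id(m.weight), 0)
                total += u * m.weight.data.shape[0] * m.weight.data.shape[1]
        return int(total)


def count_flops(model, input_size=640):
    """Multiply-accumulate count of conv/linear layers for one image."""
    return FlopsProbe(model, input_size).flops()


def speedup_reduction_percent(speed_up):
    """Computational reduction implied by a speed-up ratio: (1 - 1/s) * 100."""
    if speed_up < 1:
        raise ValueError("speed_up must be >= 1")
    return (1.0 - 1.0 / speed_up) * 100.0


# ---------------------------------------------------------------------------
# global structured pruning
# ---------------------------------------------------------------------------


@dataclass
class PruningPlan:
    speed_up_target: float
    removed: list = field(default_factory=list)  # (axis_id, channel_index)
    achieved_speed_up: float = 1.0
    base_flops: int = 0
    pruned_flops: int = 0

    @property
    def parameter_counts(self):
        return getattr(self, "_param_counts", None)


def prune_to_speedup(model, target, input_size=640, min_channels=2,
                     protected_layers=()):
    """Iteratively remove the globally least-important channel group until
    FLOPs(base)/FLOPs(pruned) >= target.

    The detect-layer outputs, the stem and attention gate widths are
    protected by the model's own graph; extra modules can be passed via
    ``protected_layers``.  If the target is unreachable without emptying a
    protected or floor-limited group, pruning stops and the achieved
    ratio is reported.
    """
    if target < 1.0:
        raise ValueError("speed_up target must be >= 1")
    graph = model.build_prune_graph()
    probe = FlopsProbe(model, input_size)
    base = probe.flops()
    plan = PruningPlan(speed_up_target=float(target), base_flops=base)
    if target == 1.0:
        plan.pruned_flops = base
        plan.achieved_speed_up = 1.0
        return plan, model

    for m in protected_layers:
        for ax in graph.axes:
            r = graph.find(ax)
            if any(layer is m for layer, _ in r.layers):
                r.protected = True

    roots = graph.prunable_roots()
    imp = {}

    def axis_importance(ax):
        vec = np.zeros(ax.size)
        for layer, kind in ax.layers:
            if kind in ("out", "both") and isinstance(layer, (Conv2d, Linear)):
                vec += channel_importance(layer)
        return vec

    for ax in roots:
        imp[id(ax)] = axis_importance(ax)

    current = base
    while base / current < target:
        best_ax, best_c, best_v = None, None, np.inf
        for ax in roots:
            if ax.size <= min_channels:
                continue
            vec = imp[id(ax)]
            c = int(vec.argmin())
            if vec[c] < best_v:
                best_ax, best_c, best_v = ax, c, vec[c]
        if best_ax is None:
            break  # target unreachable under the protection constraints
        touched = graph.drop(best_ax, [best_c])
        plan.removed.append((best_ax.id, best_c))
        for ax in roots:
            if any(id(layer) in touched for layer, kind in ax.layers
                   if kind in ("out", "both")):
                imp[id(ax)] = axis_importance(ax)
        current = probe.flops()

    plan.pruned_flops = current
    plan.achieved_speed_up = base / current
    return plan, model


def speedup_grid_report(model_factory, grid, input_size=640, eval_fn=None):
    """Prune fresh model copies over a grid of speed-up targets.

    Returns rows ``{speed_up, achieved, params, memory_mb, map50}`` (mAP
    only when ``eval_fn`` is given), mirroring a pruning ablation table.
    """
    rows = []
    for s in grid:
        model = model_factory()
        plan, pruned = prune_to_speedup(model, s, input_size=input_size)
        n_params = pruned.count_parameters()
        row = {
            "speed_up": float(s),
            "achieved_speed_up": round(plan.achieved_speed_up, 4),
            "reduction_percent": round(speedup_reduction_percent(max(s, 1.0)), 2),
            "params": int(n_params),
            "memory_mb": round(n_params * 4 / 1e6, 3),
        }
        if eval_fn is not None:
            row["map50"] = float(eval_fn(pruned))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# fine-tune schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FinetuneSchedule:
    """Post-pruning fine-tuning hyperparameters (SGD)."""

    lr0: float = 0.001
    lrf: float = 0.01           # final lr = lr0 * lrf
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    warmup_bias_lr: float = 0.1
    epochs: int = 200

    def lr_at(self, epoch):
        """Linear decay from lr0 (epoch 0) to lr0*lrf (final epoch)."""
        frac = min(max(epoch / self.epochs, 0.0), 1.0)
        return self.lr0 * (1.0 - frac) + self.lr0 * self.lrf * frac


def finetune_schedule(**overrides) -> FinetuneSchedule:
    return FinetuneSchedule(**overrides)
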