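"""LAMP scores against brute-force oracles; structured pruning invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafdet.tensor as T
from leafdet.modules import BatchNorm2d, Conv2d, Module
from leafdet.pruning import (FinetuneSchedule, PruneGraph, channel_importance,
                             count_flops, finetune_schedule, lamp_score_table,
                             lamp_scores, prune_to_speedup,
                             speedup_reduction_percent)


def brute_force_lamp(w):
    """O(n^2) reference: score(u) = w_u^2 / sum of w_v^2 over weights at
    least as large; among equal magnitudes the earlier index counts the
    later ones in its denominator (so it scores lower)."""
    w = np.asarray(w, dtype=np.float64)
    out = np.zeros_like(w)
    for u in range(len(w)):
        denom = 0.0
        for v in range(len(w)):
            if abs(w[v]) > abs(w[u]) or (abs(w[v]) == abs(w[u]) and v >= u):
                denom += w[v] ** 2
        out[u] = w[u] ** 2 / denom if denom else 0.0
    return out


class TestLampScores:
    def test_hand_worked_example(self):
        scores = lamp_scores([1.0, 2.0, 3.0])
        np.testing.assert_allclose(scores, [1 / 14, 4 / 13, 1.0])

    def test_single_weight(self):
        np.testing.assert_allclose(lamp_scores([5.0]), [1.0])

    def test_tie_rule_stable_order(self):
        np.testing.assert_allclose(lamp_scores([2.0, 2.0]), [0.5, 1.0])

    def test_all_zero_layer_fully_prunable(self):
        np.testing.assert_array_equal(lamp_scores([0.0, 0.0]), [0.0, 0.0])

    @given(st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False)
                    .filter(lambda v: v == 0 or abs(v) > 1e-3),
                    min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_and_max_is_one(self, weights):
        w = np.asarray(weights)
        got = lamp_scores(w)
        np.testing.assert_allclose(got, brute_force_lamp(w), atol=1e-12)
        if np.abs(w).max() > 0:
            assert got.max() == pytest.approx(1.0)
            # scores are non-increasing along descending magnitude order
            # (ties ordered later-index-first, matching the scoring rule)
            order = np.argsort(np.abs(w), kind="stable")[::-1]
            assert np.all(np.diff(got[order]) <= 1e-12)

    def test_score_table_rows(self):
        rows = lamp_score_table({"a": [3.0], "b": [1.0, 2.0]})
        assert ("a", 0, 1.0) in rows
        assert len(rows) == 3


class TestChannelImportance:
    def _conv(self, weights):
        conv = Conv2d(1, len(weights), 1, padding=0)
        conv.weight.data = np.asarray(weights, np.float32).reshape(-1, 1, 1, 1)
        return conv

    def test_zero_channel_scores_zero(self):
        imp = channel_importance(self._conv([0.0, 1.0, 2.0]))
        assert imp[0] == 0.0 and imp.argmin() == 0

    def test_permutation_equivariance(self):
        imp = channel_importance(self._conv([1.0, 3.0, 2.0]))
        imp_perm = channel_importance(self._conv([3.0, 2.0, 1.0]))
        np.testing.assert_allclose(sorted(imp), sorted(imp_perm))

    def test_duplicating_a_channel_recomputes_scores(self):
        # magnitudes [2, 1] -> importances [1, 1/5]; duplicating the large
        # channel: stable tie order gives [1, 1/2, 1/9]
        base = channel_importance(self._conv([2.0, 1.0]))
        np.testing.assert_allclose(base, [1.0, 0.2])
        dup = channel_importance(self._conv([2.0, 2.0, 1.0]))
        np.testing.assert_allclose(dup, [0.5, 1.0, 1 / 9])


class ToyNet(Module):
    """3 -> 6 -> 4 conv chain with one prunable hidden axis."""

    def __init__(self):
        super().__init__()
        self.conv1 = Conv2d(3, 6, 3)
        self.bn1 = BatchNorm2d(6)
        self.conv2 = Conv2d(6, 4, 3)

    def forward(self, x):
        return self.conv2(self.bn1(self.conv1(x)).leaky_relu(0.1))

    def build_prune_graph(self):
        g = PruneGraph()
        ax_in = g.new_axis(3, protected=True)
        hidden = g.conv_node(ax_in, self.conv1, self.bn1)
        out = g.conv_node(hidden, self.conv2)
        g.protect(out)
        return g


class TestStructuredPruning:
    def test_target_one_is_bit_identical(self):
        net = ToyNet()
        before = {k: v.copy() for k, v in net.state_dict().items()}
        plan, _ = prune_to_speedup(net, 1.0, input_size=16)
        assert plan.achieved_speed_up == 1.0
        after = net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_achieves_target_and_forward_consistent(self):
        net = ToyNet()
        plan, pruned = prune_to_speedup(net, 1.3, input_size=16,
                                        min_channels=1)
        assert plan.achieved_speed_up >= 1.3
        x = np.zeros((1, 3, 16, 16), np.float32)
        with T.no_grad():
            y = pruned.eval()(x)
        assert y.shape[1] == 4  # protected output width intact
        assert pruned.conv1.out_channels < 6

    def test_global_order_matches_exhaustive_oracle(self):
        net = ToyNet()
        # hand-set weights so hidden-channel importances are distinct
        w1 = np.zeros((6, 3, 3, 3), np.float32)
        mags = [0.6, 0.1, 0.9, 0.3, 1.2, 0.05]
        for c, m in enumerate(mags):
            w1[c] = m
        net.conv1.weight.data = w1
        net.conv2.weight.data = np.full((4, 6, 3, 3), 0.5, np.float32)

        removed_order = []
        ref = ToyNet()
        ref.conv1.weight.data = w1.copy()
        ref.conv2.weight.data = net.conv2.weight.data.copy()
        # oracle: repeatedly drop the channel with the smallest summed LAMP
        # score (brute-force recomputed after each removal)
        remaining = list(range(6))
        for _ in range(4):
            w = ref.conv1.weight.data
            scores = brute_force_lamp(w.ravel()).reshape(w.shape)
            per_channel = scores.reshape(w.shape[0], -1).sum(1)
            w2 = ref.conv2.weight.data
            s2 = brute_force_lamp(w2.ravel()).reshape(w2.shape)
            per_channel = per_channel + s2.sum(axis=(0, 2, 3)) * 0  # in-axis
            c = int(per_channel.argmin())
            removed_order.append(remaining.pop(c))
            ref.conv1.weight.data = np.delete(w, c, axis=0)
            ref.conv2.weight.data = np.delete(ref.conv2.weight.data, c, axis=1)
            ref.bn1.drop_channels([c])
            ref.conv1.out_channels -= 1

        plan, _ = prune_to_speedup(net, 2.5, input_size=16, min_channels=2)
        got_order = []
        remaining = list(range(6))
        for _, c in plan.removed:
            got_order.append(remaining.pop(c))
        assert got_order == removed_order[: len(got_order)]
        assert len(got_order) >= 2

    def test_unreachable_target_reports_achieved(self):
        net = ToyNet()
        plan, _ = prune_to_speedup(net, 50.0, input_size=16, min_channels=2)
        assert 1.0 < plan.achieved_speed_up < 50.0

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            prune_to_speedup(ToyNet(), 0.5)


class TestSpeedupArithmetic:
    def test_reduction_percent_examples(self):
        assert speedup_reduction_percent(1.6) == pytest.approx(37.5)
        assert speedup_reduction_percent(1.0) == 0.0
        assert speedup_reduction_percent(2.0) == pytest.approx(50.0)

    def test_flops_positive_and_monotone(self):
        net = ToyNet()
        f32 = count_flops(net, 32)
        f16 = count_flops(net, 16)
        assert f32 > f16 > 0


class TestFinetuneSchedule:
    def test_reference_hyperparameters(self):
        s = finetune_schedule()
        assert s.lr0 == 0.001 and s.lrf == 0.01
        assert s.momentum == 0.937 and s.weight_decay == 0.0005
        assert s.warmup_epochs == 3.0 and s.warmup_momentum == 0.8
        assert s.warmup_bias_lr == 0.1 and s.epochs == 200

    def test_linear_decay_endpoints(self):
        s = FinetuneSchedule()
        assert s.lr_at(0) == pytest.approx(0.001)
        assert s.lr_at(s.epochs) == pytest.approx(1e-5)
        assert s.lr_at(s.epochs // 2) == pytest.approx((0.001 + 1e-5) / 2)
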