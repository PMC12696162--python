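"""Neck components: MHSA oracle checks, BoT residual, BiECAFusion gating."""

import numpy as np
import pytest

import leafdet.tensor as T
from leafdet.fusion import (BiECAFusion, BoTBlock, FeaturePyramid, MHSA,
                            MhsaConfig, Neck, make_bot_block, make_mhsa)


class TestMHSA:
    def test_uniform_logits_mean_pool_on_2x2(self, rng):
        """Zero q/k and zero position embeddings -> softmax is uniform and
        each output position is the mean of the value vectors."""
        mhsa = make_mhsa(MhsaConfig(dim=8, heads=2, height=2, width=2))
        mhsa.q.weight.data[:] = 0.0
        mhsa.k.weight.data[:] = 0.0
        mhsa.rel_h.data[:] = 0.0
        mhsa.rel_w.data[:] = 0.0
        x = rng.normal(size=(3, 8, 2, 2)).astype(np.float32)
        with T.no_grad():
            out = mhsa.attend(x)
            v = T.conv2d(x, mhsa.v.weight)
        expect = v.data.mean(axis=(2, 3), keepdims=True) * np.ones((1, 1, 2, 2))
        np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_single_token_is_identity_on_value(self, rng):
        mhsa = make_mhsa(MhsaConfig(dim=8, heads=4, height=4, width=4))
        x = rng.normal(size=(2, 8, 1, 1)).astype(np.float32)
        with T.no_grad():
            out = mhsa.attend(x)
            v = T.conv2d(x, mhsa.v.weight)
        np.testing.assert_allclose(out.data, v.data, atol=1e-5)

    def test_shape_preserved_and_grid_bound(self, rng):
        mhsa = make_mhsa(MhsaConfig(dim=8, heads=2, height=3, width=3))
        x = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
        with T.no_grad():
            assert mhsa(x).shape == x.shape
        with pytest.raises(ValueError, match="grid"):
            mhsa.attend(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))

    def test_rejects_indivisible_heads(self):
        with pytest.raises(ValueError):
            MhsaConfig(dim=10, heads=4)


class TestBoTBlock:
    def test_zero_expansion_is_identity(self, rng):
        bot = make_bot_block(16, heads=4, grid=(4, 4))
        bot.cv2.conv.weight.data[:] = 0.0   # BN of zeros stays zero
        x = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
        with T.no_grad():
            y = bot.eval()(x)
        np.testing.assert_allclose(y.data, x, atol=1e-6)

    def test_stacking_preserves_shape(self, rng):
        blocks = [make_bot_block(8, heads=2, grid=(4, 4)) for _ in range(3)]
        x = T.Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        with T.no_grad():
            for b in blocks:
                x = b.eval()(x)
        assert x.shape == (1, 8, 4, 4)


class TestBiECAFusion:
    def test_identical_inputs_symmetric_weights_equal_branches(self, rng):
        f = BiECAFusion(8, 8, 8).eval()
        # mirror align1 onto align0 so the two pathways are exchangeable
        f.align1.conv.weight.data = f.align0.conv.weight.data.copy()
        f.align1.bn.gamma.data = f.align0.bn.gamma.data.copy()
        f.align1.bn.beta.data = f.align0.bn.beta.data.copy()
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        with T.no_grad():
            a, b = f.fuse(x, x)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_zero_second_input(self, rng):
        f = BiECAFusion(8, 8, 8).eval()
        x0 = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        x1 = np.zeros_like(x0)
        with T.no_grad():
            a, b = f.fuse(x0, x1)
            a0 = f.align0.eval()(x0)
            g = f.eca.gates(T.concat([a0, T.Tensor(np.zeros_like(a0.data))],
                                     axis=1))
        w0 = g.data[:, :8].reshape(1, 8, 1, 1)
        np.testing.assert_allclose(a.data, a0.data, atol=1e-6)   # x1' == 0
        np.testing.assert_allclose(b.data, w0 * a0.data, atol=1e-6)

    def test_zero_eca_filter_gives_half_gates(self, rng):
        f = BiECAFusion(8, 8, 8).eval()
        f.eca.filter.data[:] = 0.0
        x0 = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        x1 = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        with T.no_grad():
            a, b = f.fuse(x0, x1)
            a0 = f.align0(x0)
            a1 = f.align1(x1)
        np.testing.assert_allclose(a.data, a0.data + 0.5 * a1.data, atol=1e-6)
        np.testing.assert_allclose(b.data, a1.data + 0.5 * a0.data, atol=1e-6)

    def test_output_shape_and_spatial_mismatch(self, rng):
        f = BiECAFusion(4, 6, 10).eval()
        x0 = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        x1 = rng.normal(size=(1, 6, 6, 6)).astype(np.float32)
        with T.no_grad():
            assert f(x0, x1).shape == (1, 10, 6, 6)
        with pytest.raises(ValueError, match="spatial"):
            f.fuse(x0, rng.normal(size=(1, 6, 3, 3)).astype(np.float32))


class TestNeck:
    def test_output_strides_and_determinism(self, rng):
        neck = Neck(grid=(2, 2)).eval()
        p3 = rng.normal(size=(1, 128, 8, 8)).astype(np.float32)
        p4 = rng.normal(size=(1, 256, 4, 4)).astype(np.float32)
        p5 = rng.normal(size=(1, 512, 2, 2)).astype(np.float32)
        with T.no_grad():
            out1 = neck((p3, p4, p5))
            out2 = neck((p3, p4, p5))
        assert out1.p3.shape == (1, 64, 8, 8)
        assert out1.p4.shape == (1, 128, 4, 4)
        assert out1.p5.shape == (1, 256, 2, 2)
        np.testing.assert_array_equal(out1.p3.data, out2.p3.data)

    def test_rejects_non_dyadic_pyramid(self, rng):
        neck = Neck(grid=(3, 3))
        p3 = rng.normal(size=(1, 128, 9, 9)).astype(np.float32)
        p4 = rng.normal(size=(1, 256, 5, 5)).astype(np.float32)
        p5 = rng.normal(size=(1, 512, 3, 3)).astype(np.float32)
        with pytest.raises(ValueError, match="dyadic"):
            with T.no_grad():
                neck((p3, p4, p5))

    def test_both_passes_execute(self):
        """Bottom-up fusion nodes are part of the graph (not a plain FPN)."""
        neck = Neck(grid=(2, 2))
        names = [type(m).__name__ for m in neck.modules()]
        assert names.count("BiECAFusion") == 4  # two top-down + two bottom-up
        assert hasattr(neck, "down3") and hasattr(neck, "down4")
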