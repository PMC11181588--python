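import numpy as np
import pytest

from strgcn.autograd import Tensor
from strgcn.graph import build_graph_spec
from strgcn.model import (CausalConv1d, ChannelAttention, LayerNorm,
                          ModelConfig, STConvBlock, build_variant)

from conftest import random_connected_weights


def small_cfg(variant="STRGCN", **kw):
    defaults = dict(n_nodes=5, window_len=64,
                    temporal_kernel=(4, 4, 3, 2),
                    temporal_stride=(2, 2, 2, 2),
                    block_feature_sizes=((1, 4, 4, 4), (4, 4, 4, 4)),
                    attention_reduction=2, variant=variant, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def batch_inputs(rng, b=3, n=5, t=64, c=1):
    X = rng.standard_normal((b, n, t, c))
    P = np.stack([build_graph_spec(random_connected_weights(rng, n)).P
                  for _ in range(b)])
    return X, P


class TestCausalConv:
    def test_identity_kernel(self, rng):
        conv = CausalConv1d(1, 1, kernel=1, rng=rng)
        conv.weight.data[:] = 1.0
        conv.bias.data[:] = 0.0
        x = np.abs(rng.standard_normal((2, 3, 16, 1)))
        np.testing.assert_allclose(conv(x).data, x, atol=1e-12)

    def test_impulse_response_is_causal(self, rng):
        conv = CausalConv1d(1, 1, kernel=3, rng=rng)
        conv.weight.data[:] = 1.0
        conv.bias.data[:] = 0.0
        x = np.zeros((1, 1, 16, 1))
        x[0, 0, 5, 0] = 1.0
        out = conv(x).data[0, 0, :, 0]
        assert set(np.flatnonzero(out)) == {5, 6, 7}

    def test_perturbation_after_t_never_leaks_backward(self, rng):
        conv = CausalConv1d(2, 3, kernel=5, rng=rng)
        x = rng.standard_normal((1, 4, 32, 2))
        base = conv(x).data
        x2 = x.copy()
        x2[0, :, 20:, :] += rng.standard_normal(x2[0, :, 20:, :].shape)
        out2 = conv(x2).data
        np.testing.assert_array_equal(base[:, :, :20], out2[:, :, :20])

    def test_kernel_wider_than_window(self, rng):
        conv = CausalConv1d(1, 1, kernel=20, rng=rng)
        with pytest.raises(ValueError):
            conv(np.zeros((1, 2, 8, 1)))

    def test_stride_shrinks_time(self, rng):
        conv = CausalConv1d(1, 2, kernel=4, stride=4, rng=rng)
        out = conv(np.zeros((2, 3, 64, 1)))
        assert out.shape == (2, 3, 16, 2)


class TestChannelAttention:
    def test_neutral_gate_at_init(self, rng):
        att = ChannelAttention(4, reduction=2, rng=rng)
        x = rng.standard_normal((2, 3, 8, 4))
        w = att.weights(x).data
        np.testing.assert_allclose(w, 0.5)  # zero-init output layer
        np.testing.assert_allclose(att(x).data, x / 2)

    def test_gates_in_unit_interval(self, rng):
        att = ChannelAttention(4, reduction=2, rng=rng)
        att.w2.data[:] = rng.standard_normal(att.w2.data.shape)
        att.b2.data[:] = rng.standard_normal(4)
        w = att.weights(rng.standard_normal((2, 3, 8, 4))).data
        assert np.all((w > 0) & (w < 1))

    def test_identical_features_get_identical_gates(self, rng):
        att = ChannelAttention(2, reduction=1, rng=rng)
        # symmetric MLP weights so symmetric inputs map symmetrically
        att.w1.data[:] = 0.3
        att.b1.data[:] = 0.1
        att.w2.data[:] = 0.2
        att.b2.data[:] = 0.0
        base = rng.standard_normal((1, 3, 8, 1))
        x = np.concatenate([base, base], axis=3)
        w = att.weights(x).data
        assert w[0, 0] == pytest.approx(w[0, 1])

    def test_sigma_of_sum_convention(self, rng):
        """Gate = sigmoid(MLP(avgpool) + MLP(maxpool))."""
        att = ChannelAttention(3, reduction=1, rng=rng)
        att.w2.data[:] = rng.standard_normal(att.w2.data.shape)
        x = rng.standard_normal((2, 4, 8, 3))
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=(1, 2))

        def mlp(d):
            h = np.maximum(d @ att.w1.data + att.b1.data, 0)
            return h @ att.w2.data + att.b2.data

        expected = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        np.testing.assert_allclose(att.weights(x).data, expected,
                                   rtol=1e-10)


class TestLayerNorm:
    def test_normalized_moments(self, rng):
        ln = LayerNorm(6)
        x = rng.standard_normal((3, 4, 8, 6)) * 5 + 2
        out = ln(x).data
        flat = out.reshape(3, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0.0, atol=1e-4)
        np.testing.assert_allclose(flat.var(axis=1), 1.0, atol=1e-4)


class TestSTConvBlock:
    def test_matches_staged_composition(self, rng):
        cfg = small_cfg()
        block = STConvBlock(cfg.block_feature_sizes[0], cfg, 0,
                            np.random.default_rng(0))
        X, P = batch_inputs(rng)
        full = block(Tensor(X), Tensor(P)).data
        h = block.t1(Tensor(X))
        h = block.gc(h, Tensor(P))
        h = block.att(h)
        h = block.t2(h)
        h = block.ln(h)
        np.testing.assert_allclose(full, h.data, atol=1e-12)

    def test_output_shape_contract(self, rng):
        cfg = small_cfg(temporal_stride=1, temporal_kernel=3)
        block = STConvBlock(cfg.block_feature_sizes[0], cfg, 0,
                            np.random.default_rng(0))
        X, P = batch_inputs(rng)
        out = block(Tensor(X), Tensor(P))
        assert out.shape == (3, 5, 64, 4)

    def test_zero_weights_zero_preactivation(self, rng):
        cfg = small_cfg()
        block = STConvBlock(cfg.block_feature_sizes[0], cfg, 0,
                            np.random.default_rng(0))
        for p in block.parameters():
            p.data[:] = 0.0
        X, P = batch_inputs(rng)
        h = block.t2(block.att(block.gc(block.t1(Tensor(X)), Tensor(P))))
        assert np.all(h.data == 0)


class TestSTRGCNForward:
    def test_probabilities_normalized(self, rng):
        model = build_variant(small_cfg())
        X, P = batch_inputs(rng)
        probs = model.predict_proba(X, P)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_residual_shortcut_passes_information(self, rng):
        model = build_variant(small_cfg())
        for blk in model.blocks:
            for p in blk.block.parameters():
                p.data[:] = 0.0
        X1, P = batch_inputs(rng)
        X2 = X1 + rng.standard_normal(X1.shape)
        out1 = model.logits(X1, P).data
        out2 = model.logits(X2, P).data
        assert not np.allclose(out1, out2)

    def test_parameter_count_closed_form(self):
        cfg = small_cfg()
        model = build_variant(cfg)

        def conv_params(cin, cout, k):
            return k * cin * cout + cout

        def att_params(c, red):
            h = max(1, c // red)
            return c * h + h + h * c + c

        def gc_params(cin, cout):
            return cin * cout + cout

        expected = 0
        ks = cfg.kernels()
        for b, (ci, ct, cg, co) in enumerate(cfg.block_feature_sizes):
            expected += conv_params(ci, ct, ks[2 * b])       # t1
            expected += gc_params(ct, cg)                    # graph stage
            expected += att_params(cg, cfg.attention_reduction)
            expected += conv_params(cg, co, ks[2 * b + 1])   # t2
            expected += 2 * co                               # layer norm
            if ci != co:
                expected += ci * co                          # shortcut projection
        # head: one weight matrix per block over pooled node x feature maps
        for (ci, ct, cg, co) in cfg.block_feature_sizes:
            expected += cfg.n_nodes * co * cfg.n_classes
        expected += cfg.n_classes
        assert model.n_parameters() == expected

    def test_forward_deterministic(self, rng):
        X, P = batch_inputs(rng)
        m1 = build_variant(small_cfg())
        m2 = build_variant(small_cfg())
        np.testing.assert_array_equal(m1.logits(X, P).data,
                                      m2.logits(X, P).data)

    def test_node_permutation_equivariance(self, rng):
        cfg = small_cfg()
        model = build_variant(cfg)
        X, P = batch_inputs(rng)
        perm = np.random.default_rng(5).permutation(5)
        Xp = X[:, perm]
        Pp = P[:, perm][:, :, perm]
        feats = model.features(X, P)
        feats_p = model.features(Xp, Pp)
        for f, fp in zip(feats, feats_p):
            np.testing.assert_allclose(fp.data, f.data[:, perm],
                                       atol=1e-10)

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_variant(small_cfg())
        X, P = batch_inputs(rng)
        ref = model.predict_proba(X, P)
        path = tmp_path / "weights.npz"
        model.save(path)
        from strgcn.model import STRGCN
        back = STRGCN.load(path)
        np.testing.assert_array_equal(back.predict_proba(X, P), ref)


class TestVariants:
    def test_trcn_has_no_graph_parameters(self):
        model = build_variant(small_cfg("TRCN"))
        from strgcn.model import GraphConv, Identity
        for blk in model.blocks:
            assert isinstance(blk.block.gc, Identity)

    def test_srgcn_has_no_temporal_parameters(self):
        model = build_variant(small_cfg("SRGCN"))
        from strgcn.model import Identity
        for blk in model.blocks:
            assert isinstance(blk.block.t1, Identity)
            assert isinstance(blk.block.t2, Identity)

    def test_full_model_has_most_parameters(self):
        # equal feature sizes so the comparison is parameter-for-parameter
        kw = dict(block_feature_sizes=((1, 4, 4, 4), (4, 4, 4, 4)))
        counts = {v: build_variant(small_cfg(v, **kw)).n_parameters()
                  for v in ("STRGCN", "TRCN", "SRGCN")}
        assert counts["STRGCN"] > max(counts["TRCN"], counts["SRGCN"])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            small_cfg("SPGCN")

    def test_causality_through_temporal_and_spatial_stages(self, rng):
        """The temporal convolutions and the per-timestep graph stage are
        jointly causal: perturbing the future leaves the past unchanged.
        (The attention gate pools over the whole window by construction, so
        strict causality applies up to that stage.)"""
        cfg = small_cfg(temporal_stride=1, temporal_kernel=3)
        block = STConvBlock(cfg.block_feature_sizes[0], cfg, 0,
                            np.random.default_rng(0))
        X, P = batch_inputs(rng)
        stages = lambda x: block.t2(block.gc(block.t1(Tensor(x)),
                                             Tensor(P)))
        base = stages(X).data
        cut = 40
        X2 = X.copy()
        X2[:, :, cut:, :] += rng.standard_normal(X2[:, :, cut:, :].shape)
        pert = stages(X2).data
        np.testing.assert_array_equal(base[:, :, :cut], pert[:, :, :cut])
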