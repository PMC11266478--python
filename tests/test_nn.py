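"""The SHCFTT architecture: shape ledger, convolution stack, CBAM,
tokenizer, transformer encoder and classification head."""

import numpy as np
import pytest

from canopyhsi.autodiff import Tensor
from canopyhsi.nn import (CBAM, CNN1DBaseline, CNN3DBaseline, ModelConfig,
                          MultiHeadSelfAttention, SHCFTT, Tokenizer,
                          TransformerBlock, shape_ledger, tokenize)

TINY = dict(s=7, b=9, n_classes=3, conv3d_channels=(2, 3, 4),
            conv3d_kernels=((3, 3, 3), (1, 1, 3), (1, 1, 3)), conv2d_channels=6,
            cbam_reduction=2, cbam_spatial_kernel=3, n_tokens=2, n_heads=2,
            d_k=3, mlp_dim=8, dropout=0.0)


class TestShapeLedger:
    def test_default_ledger(self):
        ledger = shape_ledger(ModelConfig())
        assert ledger == [("input", 13, 30, 1), ("conv3d_1", 11, 24, 8),
                          ("conv3d_2", 9, 20, 16), ("conv3d_3", 7, 18, 32),
                          ("conv2d", 5, 1, 64)]

    def test_default_kernel_progression(self):
        config = ModelConfig()
        depths = [k[2] for k in config.conv3d_kernels]
        assert depths == sorted(depths, reverse=True) and len(set(depths)) == 3
        assert list(config.conv3d_channels) == [8, 16, 32]  # doubling rule

    def test_underflow_names_layer(self):
        with pytest.raises(ValueError, match="conv3d layer 1"):
            shape_ledger(ModelConfig(s=2))
        with pytest.raises(ValueError, match="conv3d layer 2"):
            shape_ledger(ModelConfig(b=8))


class TestConvStack:
    def test_zero_weights_zero_output(self):
        model = SHCFTT(ModelConfig(**TINY), seed=0)
        for name, p in model.parameters().items():
            p.data = np.zeros_like(p.data)
        rng = np.random.default_rng(0)
        logits = model.forward(rng.random((2, 7, 7, 9)).astype(np.float32))
        np.testing.assert_allclose(logits.data, 0.0, atol=1e-7)

    def test_single_kernel_hand_convolution(self):
        """A 3x3x7 kernel of ones over a constant patch of value c gives
        interior pre-activation 63c + bias (the quadruple sum by hand)."""
        from canopyhsi.autodiff import conv_nd

        c = 0.37
        patch = np.full((1, 1, 13, 13, 30), c, dtype=np.float32)
        w = Tensor(np.ones((1, 1, 3, 3, 7), dtype=np.float32))
        b = Tensor(np.array([0.25], dtype=np.float32), requires_grad=True)
        out = conv_nd(Tensor(patch), w, b)
        assert out.shape == (1, 1, 11, 11, 24)
        np.testing.assert_allclose(out.data, 63 * c + 0.25, rtol=1e-5)

    def test_feature_map_dimensions_default(self):
        model = SHCFTT(ModelConfig(), seed=0)
        g = model.feature_map(np.random.default_rng(0).random((2, 13, 13, 30)))
        assert g.shape == (2, 25, 64)  # u*v = 5*5 positions, z = 64 channels


class TestCBAM:
    def test_identity_gates_preserve_input(self):
        rng = np.random.default_rng(1)
        cbam = CBAM(8, rng, reduction=2, spatial_kernel=3)
        x = Tensor(rng.standard_normal((2, 8, 5, 5)).astype(np.float32))
        np.testing.assert_array_equal(cbam(x, identity=True).data, x.data)

    def test_gated_output_bounded_by_input(self):
        rng = np.random.default_rng(2)
        cbam = CBAM(8, rng, reduction=2, spatial_kernel=3)
        x = Tensor(rng.standard_normal((3, 8, 5, 5)).astype(np.float32))
        out = cbam(x).data
        assert np.all(np.abs(out) <= np.abs(x.data) + 1e-6)


class TestTokenizer:
    def test_identical_rows_fixed_point(self):
        rng = np.random.default_rng(3)
        row = rng.standard_normal(6).astype(np.float32)
        g = Tensor(np.tile(row, (2, 10, 1)))
        wa = Tensor(rng.standard_normal((6, 4)).astype(np.float32))
        tokens = tokenize(g, wa)
        np.testing.assert_allclose(tokens.data, np.tile(row, (2, 4, 1)), rtol=1e-5)

    def test_hand_two_by_two(self):
        """T = softmax_positions(G Wa)^T G evaluated by hand on a 2x2 G."""
        g = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
        wa = np.eye(2, dtype=np.float32)
        tokens = tokenize(Tensor(g), Tensor(wa)).data[0]
        e = np.exp(1.0)
        a = np.array([[e / (e + 1), 1 / (e + 1)],
                      [1 / (e + 1), e / (e + 1)]])  # softmax over positions per token
        expected = a.T @ g[0]
        np.testing.assert_allclose(tokens, expected, rtol=1e-5)

    def test_attention_columns_sum_to_one(self):
        rng = np.random.default_rng(4)
        tok = Tokenizer(6, 3, rng)
        g = Tensor(rng.standard_normal((2, 9, 6)).astype(np.float32))
        tok(g)
        sums = tok.last_attention.sum(axis=1)  # over spatial positions
        np.testing.assert_allclose(sums, 1.0, rtol=1e-5)

    def test_tokens_in_convex_hull(self):
        """Each token solves the convex-combination membership LP."""
        from scipy.optimize import linprog

        rng = np.random.default_rng(5)
        tok = Tokenizer(4, 2, rng)
        g = rng.standard_normal((1, 6, 4)).astype(np.float32)
        tokens = tok(Tensor(g)).data[0]
        rows = g[0].astype(float)
        for token in tokens.astype(float):
            res = linprog(c=np.zeros(6),
                          A_eq=np.vstack([rows.T, np.ones(6)]),
                          b_eq=np.concatenate([token, [1.0]]),
                          bounds=[(0, 1)] * 6, method="highs")
            assert res.success


class TestTransformer:
    def test_single_token_single_head_identity(self):
        """With one token, attention weight is softmax of a scalar = 1, so
        the MSA output is exactly the value projection of the input."""
        rng = np.random.default_rng(6)
        attn = MultiHeadSelfAttention(4, heads=1, d_k=4, rng=rng)
        attn.wv.data = np.eye(4, dtype=np.float32)
        attn.wo.data = np.eye(4, dtype=np.float32)
        x = Tensor(rng.standard_normal((1, 1, 4)).astype(np.float32))
        out = attn(x)
        np.testing.assert_allclose(out.data, x.data, rtol=1e-5)
        np.testing.assert_allclose(attn.last_attention, 1.0)

    def test_two_token_hand_attention(self):
        """softmax(Q K^T / sqrt(d_k)) V against a manual evaluation."""
        rng = np.random.default_rng(7)
        attn = MultiHeadSelfAttention(3, heads=1, d_k=3, rng=rng)
        x = rng.standard_normal((1, 2, 3)).astype(np.float32)
        out = attn(Tensor(x)).data
        q = x[0] @ attn.wq.data
        k = x[0] @ attn.wk.data
        v = x[0] @ attn.wv.data
        scores = q @ k.T / np.sqrt(3)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expected = (a @ v) @ attn.wo.data
        np.testing.assert_allclose(out[0], expected, rtol=1e-4, atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        attn = MultiHeadSelfAttention(8, heads=2, d_k=4, rng=rng)
        attn(Tensor(rng.standard_normal((3, 5, 8)).astype(np.float32)))
        np.testing.assert_allclose(attn.last_attention.sum(axis=-1), 1.0, rtol=1e-5)

    def test_encoder_preserves_shape(self):
        rng = np.random.default_rng(9)
        block = TransformerBlock(8, heads=2, d_k=4, mlp_dim=16, rng=rng)
        x = Tensor(rng.standard_normal((3, 5, 8)).astype(np.float32))
        assert block(x).shape == x.shape


class TestClassificationHead:
    def test_zero_head_uniform_probabilities(self):
        model = SHCFTT(ModelConfig(**TINY), seed=0)
        head = model._children["head"]
        head.w.data = np.zeros_like(head.w.data)
        head.b.data = np.zeros_like(head.b.data)
        probs = model.predict_proba(np.random.default_rng(0).random((2, 7, 7, 9)))
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-7)

    def test_probabilities_sum_to_one(self):
        model = SHCFTT(ModelConfig(**TINY), seed=1)
        probs = model.predict_proba(np.random.default_rng(1).random((5, 7, 7, 9)))
        assert probs.shape == (5, 3)  # a full per-class probability vector
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)


class TestEndToEndGradients:
    def test_finite_difference_full_model(self):
        """Backprop through the whole network (convs + CBAM + tokenizer +
        encoder) matches central differences on a tiny configuration."""
        model = SHCFTT(ModelConfig(**TINY), seed=2)
        rng = np.random.default_rng(2)
        for p in model.parameters().values():  # float64 for FD precision
            p.data = p.data.astype(np.float64)
        x = rng.random((3, 7, 7, 9))
        y = np.array([0, 1, 2])
        loss = model.loss(x, y)
        loss.backward()
        checked = 0
        for name, p in model.parameters().items():
            coord = tuple(rng.integers(0, s) for s in p.data.shape)
            eps = 1e-5  # float64 graph: fine steps avoid curvature bias
            old = p.data[coord]
            p.data[coord] = old + eps
            up = float(model.loss(x, y).data)
            p.data[coord] = old - eps
            down = float(model.loss(x, y).data)
            p.data[coord] = old
            fd = (up - down) / (2 * eps)
            assert p.grad[coord] == pytest.approx(fd, rel=3e-2, abs=2e-4), name
            checked += 1
        assert checked >= 30  # every parameter tensor was sampled

    def test_ablation_variants_forward(self):
        rng = np.random.default_rng(3)
        x = rng.random((2, 7, 7, 9)).astype(np.float32)
        for flags in [dict(use_cbam=False), dict(use_tokenizer_te=False),
                      dict(use_cnn=False), dict(use_cnn=False, use_tokenizer_te=False)]:
            model = SHCFTT(ModelConfig(**{**TINY, **flags}), seed=0)
            logits = model.forward(x)
            assert logits.shape == (2, 3)


class TestBaselineArchitectures:
    def test_cnn1d_shapes(self):
        model = CNN1DBaseline(50, 5, seed=0)
        probs = model.predict_proba(np.random.default_rng(0).random((4, 50)))
        assert probs.shape == (4, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)

    def test_cnn3d_heads(self):
        rng = np.random.default_rng(1)
        x = rng.random((3, 7, 7, 9)).astype(np.float32)
        for head in ("gap", "flatten"):
            model = CNN3DBaseline(ModelConfig(**TINY), seed=0, head=head)
            assert model.forward(x).shape == (3, 3)
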