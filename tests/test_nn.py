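"""The autodiff core and neural layers: gradients, attention, pooling."""

import numpy as np
import pytest

from atcpred.model import ModelConfig, PairClassifier, scaled_dot_attention
from atcpred.nn import (
    Adam,
    Conv1dTokenizer,
    MultiHeadSelfAttention,
    Tensor,
    TransformerBlock,
    bce_with_logits,
    concat,
    n_tokens,
)
from atcpred.errors import ValidationError


class TestScaledDotAttention:
    def test_single_token_returns_v(self):
        rng = np.random.default_rng(0)
        q, k, v = rng.random((1, 4)), rng.random((1, 4)), rng.random((1, 4))
        assert np.allclose(scaled_dot_attention(q, k, v, 4), v)

    def test_saturation_selects_aligned_row(self):
        k = np.eye(3)
        v = np.arange(9.0).reshape(3, 3)
        q = np.zeros((1, 3))
        q[0, 1] = 1e4  # extreme scale -> softmax saturates on K row 1
        out = scaled_dot_attention(q, k, v, 3)
        assert np.allclose(out, v[1], atol=1e-8)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        q, k, v = rng.random((3, 5)), rng.random((3, 5)), rng.random((3, 5))
        scores = q @ k.T / np.sqrt(5)
        weights = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        assert np.allclose(scaled_dot_attention(q, k, v, 5), weights @ v, atol=1e-6)

    def test_rows_are_convex_combinations(self):
        rng = np.random.default_rng(2)
        q, k = rng.random((4, 3)), rng.random((6, 3))
        v = rng.random((6, 2))
        out = scaled_dot_attention(q, k, v, 3)
        assert out.shape == (4, 2)
        assert (out >= v.min(axis=0) - 1e-12).all() and (out <= v.max(axis=0) + 1e-12).all()

    def test_shape_validation(self):
        with pytest.raises(ValidationError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 4)), 3)
        with pytest.raises(ValidationError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 3)), np.ones((2, 3)), 0)


class TestAutodiffGradients:
    def _numeric_check(self, model, X, y, rng, tol=1e-5):
        loss = bce_with_logits(model.logits(X), y)
        loss.backward()
        for p in model.parameters():
            flat = p.data.ravel()
            grads = p.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                if abs(grads[i]) < 1e-4:
                    continue
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                lp = float(bce_with_logits(model.logits(X), y).data)
                flat[i] = orig - eps
                lm = float(bce_with_logits(model.logits(X), y).data)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[i]) / max(abs(num), abs(grads[i])) < tol

    def test_full_model_gradient_matches_central_differences(self):
        rng = np.random.default_rng(3)
        cfg = ModelConfig(conv_kernel=4, conv_stride=2, model_width=8, n_heads=2,
                          ffn_hidden=8, n_blocks=2, dropout=0.0, seed=3)
        model = PairClassifier(cfg, ("CS", "DDI"))
        X = {"CS": rng.random((3, 2, 11)), "DDI": rng.random((3, 2, 11))}
        y = np.array([1.0, 0.0, 1.0])
        self._numeric_check(model, X, y, rng)

    def test_broadcast_add_and_concat_grads(self):
        a = Tensor(np.ones((2, 3)), requires_grad=True)
        b = Tensor(np.ones(3), requires_grad=True)
        out = concat([a + b, a * 2.0], axis=-1).sum()
        out.backward()
        assert np.array_equal(a.grad, np.full((2, 3), 3.0))
        assert np.array_equal(b.grad, np.full(3, 2.0))


class TestLayers:
    def test_token_count_arithmetic(self):
        assert n_tokens(5, 2, 1) == 4
        assert n_tokens(212, 16, 8) == 25
        with pytest.raises(ValueError):
            n_tokens(3, 4, 1)

    def test_attention_rows_sum_to_one_every_head(self):
        rng = np.random.default_rng(4)
        attn = MultiHeadSelfAttention(rng, width=8, n_heads=4)
        weights = attn.attention_weights(Tensor(rng.random((2, 5, 8))))
        assert weights.shape == (2, 4, 5, 5)
        assert np.allclose(weights.sum(axis=-1), 1.0)
        assert (weights >= 0).all()

    def test_layer_attention_matches_reference_kernel_per_head(self):
        rng = np.random.default_rng(5)
        attn = MultiHeadSelfAttention(rng, width=6, n_heads=2)
        x = rng.random((1, 4, 6))
        xt = Tensor(x)
        q = (x @ attn.wq.weight.data + attn.wq.bias.data).reshape(1, 4, 2, 3).transpose(0, 2, 1, 3)
        k = (x @ attn.wk.weight.data + attn.wk.bias.data).reshape(1, 4, 2, 3).transpose(0, 2, 1, 3)
        v = (x @ attn.wv.weight.data + attn.wv.bias.data).reshape(1, 4, 2, 3).transpose(0, 2, 1, 3)
        per_head = scaled_dot_attention(q[0], k[0], v[0], 3)  # (heads, L, d_k)
        z = per_head.transpose(1, 0, 2).reshape(1, 4, 6)
        expected = z @ attn.wo.weight.data + attn.wo.bias.data
        assert np.allclose(attn(xt).data, expected, atol=1e-10)

    def test_conv_patches_slide_with_stride(self):
        rng = np.random.default_rng(6)
        conv = Conv1dTokenizer(rng, kernel=3, stride=2, width=4)
        x = np.arange(2 * 7, dtype=float).reshape(1, 2, 7)
        patches = conv.patches(x)
        assert patches.shape == (1, 3, 6)
        assert patches[0, 1].tolist() == [2, 3, 4, 9, 10, 11]  # window at offset 2, both rows

    def test_adam_minimises_a_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestEncoderReductions:
    def test_identity_conv_no_blocks_pooling_equals_window_mean(self):
        # with conv weights set to averaging and no transformer blocks, the
        # embedding reduces to the mean over sliding-window means
        cfg = ModelConfig(conv_kernel=4, conv_stride=4, model_width=3, n_heads=1,
                          ffn_hidden=4, n_blocks=0, dropout=0.0,
                          positional_encoding="none", seed=0)
        from atcpred.model import CTEncoder

        enc = CTEncoder(cfg, np.random.default_rng(0))
        enc.conv.proj.weight.data[:] = 1.0 / 8  # mean over the 2x4 window
        enc.conv.proj.bias.data[:] = 0.0
        rng = np.random.default_rng(1)
        x = rng.random((2, 2, 12))
        out = enc(x).data
        window_means = x.reshape(2, 2, 3, 4).mean(axis=(1, 3))  # (B, 3 windows)
        expected = window_means.mean(axis=1)
        assert np.allclose(out, expected[:, None].repeat(3, axis=1), atol=1e-12)

    def test_evaluation_mode_is_deterministic_despite_dropout_config(self):
        cfg = ModelConfig(conv_kernel=4, conv_stride=2, model_width=8, n_heads=2,
                          ffn_hidden=8, n_blocks=2, dropout=0.5, seed=9)
        model = PairClassifier(cfg, ("CS",))
        x = {"CS": np.random.default_rng(2).random((2, 2, 10))}
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_embedding_invariant_to_batch_composition(self):
        cfg = ModelConfig(conv_kernel=4, conv_stride=2, model_width=8, n_heads=2,
                          ffn_hidden=8, n_blocks=1, dropout=0.0, seed=10)
        from atcpred.model import CTEncoder

        enc = CTEncoder(cfg, np.random.default_rng(10))
        rng = np.random.default_rng(11)
        batch = rng.random((4, 2, 10))
        full = enc(batch).data
        alone = enc(batch[2:3]).data
        assert np.allclose(full[2], alone[0], atol=1e-12)

    def test_short_input_rejected(self):
        cfg = ModelConfig(conv_kernel=16, conv_stride=8, model_width=8, n_heads=2,
                          ffn_hidden=8, n_blocks=1, seed=0)
        model = PairClassifier(cfg, ("CS",))
        with pytest.raises(ValidationError):
            model.predict_proba({"CS": np.zeros((1, 2, 10))})
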