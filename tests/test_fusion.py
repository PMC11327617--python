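"""Cross-attention fusion: attention algebra, sequence plumbing, pooling."""

import numpy as np
import pytest

from gliosurv.autodiff import Tensor
from gliosurv.fusion import (
    AttentionPool,
    ClinicalEncoder,
    CrossAttentionBlock,
    FusionConfig,
    SurvivalTransformer,
)
from gliosurv.nn import MultiHeadAttention


def _rng():
    return np.random.default_rng(42)


class TestCrossAttention:
    def test_single_key_returns_its_value(self):
        """With one key/value token the softmax is trivially 1, so every
        query row receives that token's value projection."""
        rng = _rng()
        attn = MultiHeadAttention(8, 2, rng)
        alpha = Tensor(rng.normal(size=(3, 8)))
        beta = Tensor(rng.normal(size=(1, 8)))
        out = attn(alpha, beta)
        expected = attn.w_o(attn.w_v(beta)).data
        np.testing.assert_allclose(out.data, np.tile(expected, (3, 1)), atol=1e-10)

    def test_identical_keys_give_mean_of_values(self):
        rng = _rng()
        attn = MultiHeadAttention(8, 2, rng)
        alpha = Tensor(rng.normal(size=(2, 8)))
        beta_row = rng.normal(size=8)
        beta = Tensor(np.tile(beta_row, (5, 1)))
        out = attn(alpha, beta)
        expected = attn.w_o(attn.w_v(Tensor(beta_row[None]))).data
        np.testing.assert_allclose(out.data, np.tile(expected, (2, 1)), atol=1e-10)

    def test_hand_computed_two_by_two_instance(self):
        """Single-head attention with hand-set 2x2 projections matches a
        step-by-step evaluation of Q, K, V, softmax, and the weighted sum."""
        attn = MultiHeadAttention(2, 1, _rng())
        wq = np.array([[1.0, 0.0], [0.0, 1.0]])
        wk = np.array([[0.5, -0.5], [1.0, 0.5]])
        wv = np.array([[2.0, 0.0], [0.0, -1.0]])
        attn.w_q.weight.data = wq
        attn.w_k.weight.data = wk
        attn.w_v.weight.data = wv
        attn.w_o.weight.data = np.eye(2)
        alpha = np.array([[1.0, 2.0], [0.0, -1.0]])
        beta = np.array([[1.0, 0.0], [2.0, 1.0]])
        # independent recomputation
        Q, K, V = alpha @ wq, beta @ wk, beta @ wv
        scores = Q @ K.T / np.sqrt(2)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        expected = w @ V
        out = attn(Tensor(alpha), Tensor(beta))
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        rng = _rng()
        attn = MultiHeadAttention(8, 4, rng)
        w = attn.attention_weights(Tensor(rng.normal(size=(5, 8))), Tensor(rng.normal(size=(7, 8))))
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


class TestBidirectionalFusion:
    @pytest.fixture
    def model(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=3, img_dim=8, n_img_tokens=6)
        return SurvivalTransformer(cfg, d_clin=5, seed=0)

    def test_output_lengths_follow_queries(self, model):
        rng = _rng()
        img = Tensor(rng.normal(size=(2, 6, 8)))
        clin = Tensor(rng.normal(size=(2, 3, 8)))
        img_hat, clin_hat = model.bidirectional_fusion(img, clin)
        assert img_hat.shape == (2, 6, 8)
        assert clin_hat.shape == (2, 3, 8)

    def test_query_permutation_equivariance(self, model):
        """No positional term inside the block: permuting the query tokens
        permutes the enriched rows identically."""
        rng = _rng()
        img = rng.normal(size=(1, 6, 8))
        clin = Tensor(rng.normal(size=(1, 3, 8)))
        perm = np.array([3, 0, 5, 1, 4, 2])
        out = model.cross_img(Tensor(img), clin).data
        out_p = model.cross_img(Tensor(img[:, perm]), clin).data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)

    def test_directions_use_disjoint_parameters(self, model):
        rng = _rng()
        img = Tensor(rng.normal(size=(1, 6, 8)))
        clin = Tensor(rng.normal(size=(1, 3, 8)))
        _, clin_hat_before = model.bidirectional_fusion(img, clin)
        for p in model.cross_img.parameters():
            p.data = np.zeros_like(p.data)
        _, clin_hat_after = model.bidirectional_fusion(img, clin)
        np.testing.assert_array_equal(clin_hat_before.data, clin_hat_after.data)


class TestFinalAttention:
    def test_concatenation_length(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=3, img_dim=8, n_img_tokens=6)
        model = SurvivalTransformer(cfg, d_clin=5, seed=0)
        rng = _rng()
        img_hat = Tensor(rng.normal(size=(1, 6, 8)))
        clin_hat = Tensor(rng.normal(size=(1, 3, 8)))
        kv = Tensor.concatenate([img_hat, clin_hat], axis=-2)
        assert kv.shape == (1, 9, 8)
        out = model.final_attention(img_hat, clin_hat, Tensor(rng.normal(size=(1, 3, 8))))
        assert out.shape == (1, 3, 8)

    def test_key_order_invariance(self):
        """Attention is a weighted sum over keys: concatenating the two
        enriched sequences in either order yields the same output."""
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=3, img_dim=8, n_img_tokens=6)
        model = SurvivalTransformer(cfg, d_clin=5, seed=0)
        rng = _rng()
        img_hat = Tensor(rng.normal(size=(1, 6, 8)))
        clin_hat = Tensor(rng.normal(size=(1, 3, 8)))
        q = Tensor(rng.normal(size=(1, 3, 8)))
        a = model.final_attn(q, Tensor.concatenate([img_hat, clin_hat], axis=-2))
        b = model.final_attn(q, Tensor.concatenate([clin_hat, img_hat], axis=-2))
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)


class TestAttentionPool:
    def test_single_token_returns_its_value(self):
        rng = _rng()
        pool = AttentionPool(8, rng)
        seq = Tensor(rng.normal(size=(1, 8)))
        out = pool(seq)
        np.testing.assert_allclose(out.data, pool.w_v(seq).data[0], atol=1e-12)

    def test_identical_tokens_return_common_value(self):
        rng = _rng()
        pool = AttentionPool(8, rng)
        row = rng.normal(size=8)
        seq = Tensor(np.tile(row, (6, 1)))
        out = pool(seq)
        np.testing.assert_allclose(out.data, pool.w_v(Tensor(row[None])).data[0], atol=1e-10)

    def test_output_in_convex_hull_of_values(self):
        """Pooling weights are a softmax, so each output coordinate is
        bounded by the min/max of the value rows."""
        rng = _rng()
        pool = AttentionPool(8, rng)
        for _ in range(10):
            seq = Tensor(rng.normal(size=(5, 8)))
            v = pool.w_v(seq).data
            out = pool(seq).data
            assert np.all(out >= v.min(axis=0) - 1e-10)
            assert np.all(out <= v.max(axis=0) + 1e-10)

    def test_empty_sequence_raises(self):
        pool = AttentionPool(8, _rng())
        with pytest.raises(ValueError, match="empty"):
            pool(Tensor(np.zeros((0, 8))))


class TestSurvivalTransformer:
    def test_logit_width_is_bins_plus_beyond(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=2, img_dim=8,
                           n_img_tokens=4, n_bins=5, modality="clinical")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        out = model.predict(None, np.zeros((2, 3)))
        assert out.shape == (2, 6)

    def test_deterministic_given_parameters(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=2, img_dim=8,
                           n_img_tokens=4, modality="multimodal")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        rng = _rng()
        img = rng.normal(size=(2, 4, 8))
        x = rng.normal(size=(2, 3))
        np.testing.assert_array_equal(model.predict(img, x), model.predict(img, x))

    def test_extreme_inputs_stay_finite(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=2, img_dim=8,
                           n_img_tokens=4, modality="clinical")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        out = model.predict(None, np.full((1, 3), 1e3))
        assert np.all(np.isfinite(out))

    def test_nan_covariates_raise(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=2, img_dim=8,
                           n_img_tokens=4, modality="clinical")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        with pytest.raises(ValueError, match="finite"):
            model.predict(None, np.array([[np.nan, 0.0, 0.0]]))

    def test_clinical_only_forward_is_self_attention_composition(self):
        """The nonimaging model is the same machinery with alpha = beta: the
        forward pass decomposes exactly into self-attention of the clinical
        sequence followed by the final attention, pooling and head."""
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=3, img_dim=8,
                           n_img_tokens=4, modality="clinical")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        rng = _rng()
        x = rng.normal(size=(2, 3))
        clin_seq = model.clinical_encoder(Tensor(x))
        clin_hat = model.cross_clin(clin_seq, clin_seq)
        fused = model.final_attn(clin_seq, clin_hat)
        expected = model.predict_logits(model.pool(fused)).data
        np.testing.assert_allclose(model.predict(None, x), expected, atol=1e-12)

    def test_clinical_only_model_needs_no_imaging(self):
        cfg = FusionConfig(embed_dim=8, n_heads=2, clin_tokens=2, img_dim=8,
                           n_img_tokens=4, modality="clinical")
        model = SurvivalTransformer(cfg, d_clin=3, seed=0)
        out = model.predict(None, np.zeros((4, 3)))
        assert out.shape == (4, 6)

    def test_zero_weight_clinical_encoder_ignores_input(self):
        rng = _rng()
        enc = ClinicalEncoder(5, 3, 8, rng)
        for p in enc.parameters():
            p.data = np.zeros_like(p.data)
        a = enc(Tensor(rng.normal(size=(2, 5)))).data
        b = enc(Tensor(rng.normal(size=(2, 5)))).data
        np.testing.assert_array_equal(a, 0.0)
        np.testing.assert_array_equal(a, b)
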