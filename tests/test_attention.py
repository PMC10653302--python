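"""Sparse masks, masked multi-head attention, encoder layers and FLOPs."""

import numpy as np
import pytest

from harnet import (AttentionMask, Encoder, EncoderConfig, EncoderLayer,
                    ProjectionSet, attention_flops, har_mask,
                    masked_multihead_attention, random_mask, slide_mask)
from harnet.attention import MultiHeadSelfAttention, full_mask, save_mask_txt
from harnet.autodiff import Tensor


def dense_attention_oracle(X, proj: ProjectionSet):
    """Literal unmasked multi-head attention: per-head Q/K/V projections,
    softmax(QKᵀ/√d′)V, concatenation, output projection. Written
    independently of the library's code path."""
    nh, d, dp = proj.w_q.shape
    t = X.shape[0]
    head_outputs = []
    for h in range(nh):
        Q, K, V = X @ proj.w_q[h], X @ proj.w_k[h], X @ proj.w_v[h]
        A = np.empty((t, t))
        for q in range(t):
            scores = np.array([Q[q] @ K[k] / np.sqrt(dp) for k in range(t)])
            e = np.exp(scores - scores.max())
            A[q] = e / e.sum()
        head_outputs.append(A @ V)
    return np.concatenate(head_outputs, axis=1) @ proj.w_out


def random_projections(d, nh, rng):
    dp = d // nh
    return ProjectionSet(rng.standard_normal((nh, d, dp)),
                         rng.standard_normal((nh, d, dp)),
                         rng.standard_normal((nh, d, dp)),
                         rng.standard_normal((d, d)))


class TestSlideMask:
    def test_tridiagonal_count(self):
        assert slide_mask(6, 1).allowed.sum() == 16    # 3t − 2

    def test_radius_covering_everything(self):
        for t in (1, 4, 7):
            assert slide_mask(t, t - 1).allowed.all()

    def test_zero_radius_is_identity(self):
        m = slide_mask(5, 0)
        np.testing.assert_array_equal(m.allowed, np.eye(5, dtype=bool))

    def test_band_structure_matches_definition(self):
        t, w = 30, 4
        m = slide_mask(t, w)
        for q in range(t):
            for k in range(t):
                assert m.allowed[q, k] == (abs(q - k) <= w)


class TestRandomMask:
    def test_zero_random_keys_is_identity(self):
        m = random_mask(7, 0, seed=0)
        np.testing.assert_array_equal(m.allowed, np.eye(7, dtype=bool))

    def test_full_random_keys_is_all_true(self):
        assert random_mask(7, 7, seed=0).allowed.all()

    def test_row_sums_between_r_and_r_plus_one(self):
        m = random_mask(8, 2, seed=3)
        sums = m.allowed.sum(axis=1)
        assert np.all(sums >= 2) and np.all(sums <= 3)
        assert m.allowed.diagonal().all()

    def test_deterministic_given_seed(self):
        a = random_mask(20, 5, seed=9).allowed
        b = random_mask(20, 5, seed=9).allowed
        assert np.array_equal(a, b)


class TestHarMask:
    def test_degenerate_union_is_identity(self):
        cfg = EncoderConfig(slide_radius=0, mask_fraction=1.0)
        m = har_mask(10, cfg, seed=0)
        np.testing.assert_array_equal(m.allowed, np.eye(10, dtype=bool))

    def test_union_keeps_all_band_entries(self):
        cfg = EncoderConfig(slide_radius=3, mask_fraction=0.7)
        m = har_mask(50, cfg, seed=4)
        band = slide_mask(50, 3)
        assert np.all(m.allowed[band.allowed])

    def test_density_near_target_over_seeds(self):
        cfg = EncoderConfig(slide_radius=5, mask_fraction=0.7)
        densities = [har_mask(100, cfg, seed=s).density for s in range(20)]
        assert all(0.25 <= d <= 0.35 for d in densities)

    def test_keep_fraction_reading(self):
        cfg = EncoderConfig(slide_radius=5, mask_fraction=0.7,
                            mask_is_keep_fraction=True)
        assert 0.6 <= har_mask(100, cfg, seed=0).density <= 0.8

    def test_band_exceeding_budget_logs_warning(self, caplog):
        cfg = EncoderConfig(slide_radius=20, mask_fraction=0.9)
        with caplog.at_level("WARNING"):
            m = har_mask(50, cfg, seed=0)
        assert "band" in caplog.text
        np.testing.assert_array_equal(m.allowed, slide_mask(50, 20).allowed)

    def test_reproducible_density(self):
        cfg = EncoderConfig(slide_radius=5, mask_fraction=0.7)
        assert har_mask(100, cfg, 7).density == har_mask(100, cfg, 7).density


class TestMaskInvariants:
    def test_diagonal_required(self):
        bad = np.ones((4, 4), dtype=bool)
        bad[2, 2] = False
        with pytest.raises(ValueError, match="itself"):
            AttentionMask(bad)

    def test_text_export_roundtrip(self, tmp_path):
        m = har_mask(20, EncoderConfig(slide_radius=2, mask_fraction=0.5), 1)
        path = tmp_path / "mask.txt"
        save_mask_txt(path, m)
        back = np.loadtxt(path).astype(bool)
        assert np.array_equal(back, m.allowed)


class TestMaskedAttention:
    @pytest.mark.parametrize("t,d,nh", [(8, 8, 2), (12, 16, 4), (16, 8, 1)])
    def test_full_mask_matches_dense_oracle(self, t, d, nh, rng):
        X = rng.standard_normal((t, d))
        proj = random_projections(d, nh, rng)
        got = masked_multihead_attention(X, proj, full_mask(t))
        expected = dense_attention_oracle(X, proj)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_identity_mask_returns_projected_values(self, rng):
        t, d, nh = 6, 8, 2
        X = rng.standard_normal((t, d))
        proj = random_projections(d, nh, rng)
        got = masked_multihead_attention(X, proj, slide_mask(t, 0))
        # softmax over a single allowed key is 1, so each row is its own V row
        per_head_v = np.concatenate([X @ proj.w_v[h] for h in range(nh)], axis=1)
        np.testing.assert_allclose(got, per_head_v @ proj.w_out, atol=1e-10)

    def test_single_token_sequence(self, rng):
        d, nh = 8, 2
        X = rng.standard_normal((1, d))
        proj = random_projections(d, nh, rng)
        got = masked_multihead_attention(X, proj, full_mask(1))
        per_head_v = np.concatenate([X @ proj.w_v[h] for h in range(nh)], axis=1)
        np.testing.assert_allclose(got, per_head_v @ proj.w_out, atol=1e-10)

    def test_trainable_module_matches_functional_path(self, rng):
        """The autodiff attention and the numpy reference path agree."""
        cfg = EncoderConfig(d_model=16, n_heads=4, slide_radius=2,
                            mask_fraction=0.5, dropout=0.0)
        attn = MultiHeadSelfAttention(cfg, np.random.default_rng(0))
        for lin in (attn.q_proj, attn.k_proj, attn.v_proj, attn.out_proj):
            lin.bias.data = np.zeros_like(lin.bias.data)
        mask = har_mask(10, cfg, seed=2)
        X = rng.standard_normal((10, 16))
        module_out = attn(Tensor(X[None]), mask).data[0]
        functional_out = masked_multihead_attention(X, attn.projection_set(), mask)
        np.testing.assert_allclose(module_out, functional_out, atol=1e-8)

    def test_softmax_rows_sum_to_one_over_allowed(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2)
        attn = MultiHeadSelfAttention(cfg, np.random.default_rng(0))
        mask = har_mask(12, cfg, seed=0)
        X = Tensor(rng.standard_normal((1, 12, 8)))
        from harnet.autodiff import softmax as sm
        B, t, d = X.shape
        q = attn.q_proj(X).reshape(1, t, 2, 4).transpose(0, 2, 1, 3)
        k = attn.k_proj(X).reshape(1, t, 2, 4).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * 0.5 + Tensor(mask.bias())
        weights = sm(scores).data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
        # no weight leaks onto masked entries
        assert np.all(weights[..., ~mask.allowed] < 1e-12)

    def test_permutation_consistency(self, rng):
        """Permuting positions of input and mask permutes the output rows."""
        t, d, nh = 9, 8, 2
        X = rng.standard_normal((t, d))
        proj = random_projections(d, nh, rng)
        mask = har_mask(t, EncoderConfig(d_model=d, n_heads=nh, slide_radius=1,
                                         mask_fraction=0.5), seed=5)
        perm = rng.permutation(t)
        base = masked_multihead_attention(X, proj, mask)
        permuted_mask = AttentionMask(mask.allowed[np.ix_(perm, perm)])
        permuted = masked_multihead_attention(X[perm], proj, permuted_mask)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-8)


class TestEncoderLayer:
    def test_shape_preserved(self, rng):
        cfg = EncoderConfig(d_model=16, n_heads=2, dropout=0.0)
        layer = EncoderLayer(cfg, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((3, 10, 16)))
        out = layer(x, full_mask(10))
        assert out.shape == (3, 10, 16)

    def test_zero_weights_reduce_to_residual_normalisation(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, dropout=0.0)
        layer = EncoderLayer(cfg, np.random.default_rng(0))
        for _, p in layer.named_parameters():
            if p.data.ndim >= 1 and not np.all(p.data == 1.0):  # keep LN gamma
                p.data = np.zeros_like(p.data)
        layer.norm1.gamma.data = np.ones(8)
        layer.norm2.gamma.data = np.ones(8)
        x = rng.standard_normal((1, 6, 8))
        out = layer(Tensor(x), full_mask(6)).data[0]
        mu = x[0].mean(axis=-1, keepdims=True)
        sd = np.sqrt(x[0].var(axis=-1, keepdims=True) + 1e-5)
        once = (x[0] - mu) / sd
        mu2 = once.mean(axis=-1, keepdims=True)
        sd2 = np.sqrt(once.var(axis=-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(out, (once - mu2) / sd2, atol=1e-6)

    def test_stack_composes_single_layers(self, rng):
        cfg = EncoderConfig(d_model=8, n_heads=2, n_layers=2, dropout=0.0)
        enc = Encoder(cfg, np.random.default_rng(7))
        x = Tensor(rng.standard_normal((2, 5, 8)))
        mask = full_mask(5)
        stacked = enc(x, mask).data
        manual = enc.layers[1](enc.layers[0](x, mask), mask).data
        np.testing.assert_allclose(stacked, manual, atol=1e-10)


class TestFlops:
    def test_full_density_ratio_one(self):
        cfg = EncoderConfig()
        out = attention_flops(50, 64, cfg, mask=full_mask(50))
        assert out["ratio"] == 1.0 and out["sparse"] == out["dense"]

    def test_diagonal_mask_ratio_one_over_t(self):
        cfg = EncoderConfig()
        t = 25
        out = attention_flops(t, 64, cfg, mask=slide_mask(t, 0))
        assert out["ratio"] == pytest.approx(1 / t)

    def test_ratio_equals_measured_density(self):
        cfg = EncoderConfig(slide_radius=5, mask_fraction=0.7)
        mask = har_mask(100, cfg, seed=11)
        out = attention_flops(100, 64, cfg, mask=mask)
        assert out["ratio"] == mask.density
        assert out["sparse"] < out["dense"]


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        EncoderConfig(d_model=10, n_heads=4)
    with pytest.raises(ValueError, match="mask_fraction"):
        EncoderConfig(mask_fraction=1.5)
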