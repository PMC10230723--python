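"""Layer norm, attention, residual blocks and the classifier head against
independent step-by-step oracles."""

import numpy as np
import pytest

import rbpattn as rb
from rbpattn import nn
from rbpattn.seq_transformer import (ClassifierHead, LayerNormParams,
                                     TransformerEncoder, classify, layer_norm,
                                     multi_head_attention, postnorm_block,
                                     prenorm_block)


def scalar_layer_norm_oracle(z, gamma, beta, eps):
    """Direct per-element computation of the closed form."""
    M = len(z)
    mu = sum(z) / M
    var = sum((zi - mu) ** 2 for zi in z) / M
    return np.array([(zi - mu) / np.sqrt(var + eps) * g + b
                     for zi, g, b in zip(z, gamma, beta)])


class TestLayerNorm:
    def test_constant_input_maps_to_beta(self):
        params = LayerNormParams(np.ones(5), np.full(5, 0.7))
        np.testing.assert_allclose(layer_norm(np.full(5, 3.2), params),
                                   np.full(5, 0.7), atol=1e-9)

    def test_zero_gain_returns_beta(self, rng):
        beta = rng.standard_normal(6)
        params = LayerNormParams(np.zeros(6), beta)
        np.testing.assert_array_equal(layer_norm(rng.standard_normal(6), params),
                                      beta)

    def test_three_point_closed_form(self):
        params = LayerNormParams(np.ones(3), np.zeros(3), eps=1e-300)
        out = layer_norm(np.array([1.0, 2.0, 3.0]), params)
        np.testing.assert_allclose(out, [-1.2247448714, 0.0, 1.2247448714],
                                   atol=1e-9)

    def test_matches_scalar_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            M = int(rng.integers(2, 12))
            z = rng.standard_normal(M)
            gamma = rng.standard_normal(M)
            beta = rng.standard_normal(M)
            params = LayerNormParams(gamma, beta, eps=1e-5)
            np.testing.assert_allclose(
                layer_norm(z, params),
                scalar_layer_norm_oracle(z, gamma, beta, 1e-5), atol=1e-10)

    def test_standardizes_mean_and_variance(self, rng):
        params = LayerNormParams(np.ones(32), np.zeros(32))
        out = layer_norm(rng.standard_normal((4, 32)) * 5 + 2, params)
        np.testing.assert_allclose(out.mean(axis=-1), 0, atol=1e-12)
        np.testing.assert_allclose(out.var(axis=-1), 1, atol=1e-4)


def attention_oracle(x, attn):
    """Explicit O(L^2) double-loop re-computation of multi-head attention."""
    L, d = x.shape
    h, dh = attn.heads, attn.d_head
    q = x @ attn.Wq.W.data + attn.Wq.b.data
    k = x @ attn.Wk.W.data + attn.Wk.b.data
    v = x @ attn.Wv.W.data + attn.Wv.b.data
    heads = []
    for i in range(h):
        sl = slice(i * dh, (i + 1) * dh)
        qi, ki, vi = q[:, sl], k[:, sl], v[:, sl]
        out = np.zeros((L, dh))
        for a in range(L):
            scores = np.array([qi[a] @ ki[b] / attn.scale for b in range(L)])
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            for b in range(L):
                out[a] += w[b] * vi[b]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ attn.Wo.W.data + attn.Wo.b.data


class TestMultiHeadAttention:
    @pytest.mark.parametrize("h", [1, 2, 4])
    def test_matches_double_loop_oracle(self, rng, h):
        for _ in range(15):
            L = int(rng.integers(1, 9))
            d = int(h * rng.integers(1, 17 // h + 1))
            attn = nn.MultiHeadAttention(d, h, rng=rng, dtype=np.float64)
            x = rng.standard_normal((L, d))
            got = multi_head_attention(x, attn)
            np.testing.assert_allclose(got, attention_oracle(x, attn), atol=1e-6)

    def test_single_position_head_output_is_value(self, rng):
        attn = nn.MultiHeadAttention(4, 1, rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 4))
        weights = attn.attention_weights(x[None])
        np.testing.assert_array_equal(weights, np.ones((1, 1, 1, 1)))

    def test_identical_positions_uniform_weights(self, rng):
        attn = nn.MultiHeadAttention(6, 2, rng=rng, dtype=np.float64)
        x = np.tile(rng.standard_normal(6), (5, 1))
        w = attn.attention_weights(x[None])
        np.testing.assert_allclose(w, 1 / 5, atol=1e-12)
        out = multi_head_attention(x, attn)
        np.testing.assert_allclose(out, np.tile(out[0], (5, 1)), atol=1e-12)

    def test_rows_sum_to_one_and_convex_hull(self, rng):
        attn = nn.MultiHeadAttention(8, 2, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 6, 8))
        mask = np.ones((2, 6), bool)
        mask[0, 4:] = False
        w = attn.attention_weights(x, mask)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)
        assert not w[0, :, :, 4:].any()  # masked keys get zero weight

    def test_permutation_equivariance(self, rng):
        attn = nn.MultiHeadAttention(8, 4, rng=rng, dtype=np.float64)
        x = rng.standard_normal((7, 8))
        perm = rng.permutation(7)
        out = multi_head_attention(x, attn)
        out_p = multi_head_attention(x[perm], attn)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12, rtol=0)

    def test_all_masked_rejected(self, rng):
        attn = nn.MultiHeadAttention(4, 1, rng=rng, dtype=np.float64)
        with pytest.raises(ValueError, match="masked"):
            attn.forward(rng.standard_normal((1, 3, 4)), np.zeros((1, 3), bool))


def make_block(style, rng, d=6, h=2, dff=12):
    return nn.TransformerBlock(d, h, dff, style, 0.0, rng=rng, dtype=np.float64)


class TestBlocks:
    def test_prenorm_zero_init_is_identity(self, rng):
        blk = make_block("pre", rng)
        blk.zero_init_sublayer_outputs()
        x = rng.standard_normal((3, 5, 6))
        np.testing.assert_array_equal(prenorm_block(x, blk), x)

    def test_twelve_zero_init_prenorm_blocks_identity(self, rng):
        enc = TransformerEncoder(6, 2, 12, 12, "pre", 0.0, rng=rng,
                                 dtype=np.float64, final_norm=False)
        enc.zero_init_sublayer_outputs()
        x = rng.standard_normal((2, 4, 6))
        np.testing.assert_array_equal(enc.forward(x), x)

    def test_postnorm_zero_init_is_layernorm_not_identity(self, rng):
        blk = make_block("post", rng)
        blk.zero_init_sublayer_outputs()
        x = rng.standard_normal((2, 4, 6)) * 3 + 1
        out = postnorm_block(x, blk)
        assert not np.allclose(out, x, atol=1e-3)
        # equals LN applied twice (both sub-layers contribute zero)
        p1 = LayerNormParams(blk.ln1.gamma.data, blk.ln1.beta.data, blk.ln1.eps)
        p2 = LayerNormParams(blk.ln2.gamma.data, blk.ln2.beta.data, blk.ln2.eps)
        np.testing.assert_allclose(out, layer_norm(layer_norm(x, p1), p2),
                                   atol=1e-12)

    def test_postnorm_ln_fixed_point(self, rng):
        blk = make_block("post", rng, d=8)
        blk.zero_init_sublayer_outputs()
        x = rng.standard_normal((1, 3, 8))
        x = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)
        np.testing.assert_allclose(postnorm_block(x, blk), x, atol=1e-4)

    def test_prenorm_generic_equals_stepwise_oracle(self, rng):
        blk = make_block("pre", rng)
        x = rng.standard_normal((2, 3, 6))
        p1 = LayerNormParams(blk.ln1.gamma.data, blk.ln1.beta.data, blk.ln1.eps)
        p2 = LayerNormParams(blk.ln2.gamma.data, blk.ln2.beta.data, blk.ln2.eps)
        p = x + np.stack([attention_oracle(layer_norm(xi, p1), blk.attn)
                          for xi in x])
        ln_p = layer_norm(p, p2)
        ffn = np.maximum(ln_p @ blk.ffn.lin1.W.data + blk.ffn.lin1.b.data, 0)
        z_s = p + ffn @ blk.ffn.lin2.W.data + blk.ffn.lin2.b.data
        got = prenorm_block(x, blk)
        assert not np.allclose(got, x)
        np.testing.assert_allclose(got, z_s, atol=1e-6)

    def test_postnorm_generic_equals_stepwise_oracle(self, rng):
        blk = make_block("post", rng)
        x = rng.standard_normal((2, 3, 6))
        p1 = LayerNormParams(blk.ln1.gamma.data, blk.ln1.beta.data, blk.ln1.eps)
        p2 = LayerNormParams(blk.ln2.gamma.data, blk.ln2.beta.data, blk.ln2.eps)
        y = layer_norm(x + np.stack([attention_oracle(xi, blk.attn) for xi in x]),
                       p1)
        ffn = np.maximum(y @ blk.ffn.lin1.W.data + blk.ffn.lin1.b.data, 0)
        out = layer_norm(y + ffn @ blk.ffn.lin2.W.data + blk.ffn.lin2.b.data, p2)
        np.testing.assert_allclose(postnorm_block(x, blk), out, atol=1e-6)


class TestClassifierHead:
    def test_zero_logits_give_half_half(self, rng):
        head = ClassifierHead(4, rng=rng, dtype=np.float64)
        head.out.zero_()
        probs = classify(rng.standard_normal((3, 4)), head)
        np.testing.assert_allclose(probs, 0.5)

    def test_softmax_limit(self):
        p = nn.softmax(np.array([[30.0, -30.0]]))
        assert p[0, 0] > 1 - 1e-12 and abs(p.sum() - 1) < 1e-12

    def test_hand_set_affine_matches_scalar_oracle(self, rng):
        head = ClassifierHead(3, rng=rng, dtype=np.float64)
        head.out.W.data[:] = [[1.0, -1.0], [0.5, 0.0], [0.0, 2.0]]
        head.out.b.data[:] = [0.1, -0.2]
        z = np.array([[[1.0, 2.0, 3.0]]])  # one position
        probs = classify(z[0], head)
        logits = np.array([1 * 1 + 2 * 0.5 + 3 * 0 + 0.1,
                           1 * -1 + 2 * 0 + 3 * 2 - 0.2])
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(probs, e / e.sum(), atol=1e-12)
        assert abs(probs.sum() - 1) < 1e-12

    def test_mask_aware_mean_pooling(self, rng):
        head = ClassifierHead(4, rng=rng, dtype=np.float64)
        z = rng.standard_normal((1, 5, 4))
        mask = np.array([[True, True, False, False, False]])
        full = classify(z[:, :2], head)
        masked = classify(z, head, mask)
        np.testing.assert_allclose(masked, full, atol=1e-12)

    def test_all_pad_rejected(self, rng):
        head = ClassifierHead(4, rng=rng, dtype=np.float64)
        with pytest.raises(ValueError, match="masked"):
            classify(rng.standard_normal((1, 3, 4)), head, np.zeros((1, 3), bool))


def test_full_forward_matches_stepwise_oracle_on_toy_input(rng):
    """3-position toy input through a 2-block pre-norm stack + head equals
    the independently recomposed sub-step computation to 1e-6."""
    enc = TransformerEncoder(6, 2, 12, 2, "pre", 0.0, rng=rng, dtype=np.float64)
    head = ClassifierHead(6, rng=rng, dtype=np.float64)
    x = rng.standard_normal((1, 3, 6))
    z = x
    for blk in enc.blocks:
        z = prenorm_block(z, blk)
    pf = LayerNormParams(enc.final_ln.gamma.data, enc.final_ln.beta.data,
                         enc.final_ln.eps)
    z = layer_norm(z, pf)
    pooled = z.mean(axis=1)
    logits = pooled @ head.out.W.data + head.out.b.data
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    expected = e / e.sum(axis=1, keepdims=True)
    got = classify(enc.forward(x), head)
    np.testing.assert_allclose(got, expected, atol=1e-6)
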