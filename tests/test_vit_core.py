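"""Transformer/ViT primitives against closed forms and scalar-loop oracles."""

import numpy as np
import pytest

from mpvit.autodiff import Tensor
from mpvit.vit import (
    AttentionParams,
    FeedForwardParams,
    embed_patches,
    encoder_block,
    feed_forward,
    init_encoder,
    layer_norm,
    multi_head_self_attention,
    patchify,
    scaled_dot_product_attention,
    sinusoidal_position_encoding,
    sinusoidal_table,
    unpatchify,
)

# ---------------------------------------------------------------- patchify


def test_patchify_standard_vit_geometry(rng):
    """A 224x224 image with 16x16 patches gives 196 patches of 256 pixels."""
    img = rng.uniform(0, 1, (224, 224))
    patches = patchify(img, 16)
    assert patches.shape == (196, 256)
    assert img.size == 50176  # pixel-flattened sequence length


def test_patchify_single_patch_is_flattened_image(rng):
    img = rng.uniform(0, 1, (8, 8))
    patches = patchify(img, 8)
    np.testing.assert_array_equal(patches, img.reshape(1, 64))


def test_patchify_roundtrip(rng):
    img = rng.uniform(0, 1, (32, 32))
    patches = patchify(img, 8)
    assert patches.shape == (16, 64)
    np.testing.assert_array_equal(unpatchify(patches, 32, 8), img)


def test_patchify_rejects_nondivisible():
    with pytest.raises(ValueError):
        patchify(np.zeros((30, 30)), 16)


def test_patchify_row_major_order():
    img = np.arange(16.0).reshape(4, 4)
    patches = patchify(img, 2)
    # first patch is the top-left 2x2 block, row-major pixels
    np.testing.assert_array_equal(patches[0], [0, 1, 4, 5])
    np.testing.assert_array_equal(patches[1], [2, 3, 6, 7])


# ---------------------------------------------------------------- embedding


def test_embed_patches_class_token_length(rng):
    raw = rng.normal(0, 1, (196, 256))
    E = rng.normal(0, 1, (256, 16))
    pos = rng.normal(0, 1, (197, 16))
    out = embed_patches(raw, E, pos, class_token=rng.normal(0, 1, 16))
    assert out.shape == (197, 16)


def test_embed_patches_zero_embedding_leaves_positions(rng):
    raw = rng.normal(0, 1, (5, 12))
    pos = rng.normal(0, 1, (6, 4))
    out = embed_patches(raw, np.zeros((12, 4)), pos, class_token=np.zeros(4))
    np.testing.assert_allclose(out.data, pos.data if hasattr(pos, "data") else pos)


def test_embed_patches_matches_row_loop(rng):
    raw = rng.normal(0, 1, (7, 9))
    E = rng.normal(0, 1, (9, 5))
    pos = rng.normal(0, 1, (8, 5))
    ct = rng.normal(0, 1, 5)
    out = embed_patches(raw, E, pos, class_token=ct).data
    expect = np.vstack([ct] + [raw[i] @ E for i in range(7)]) + pos
    np.testing.assert_allclose(out, expect, atol=1e-10)


# ---------------------------------------------------------------- layer norm


def test_layer_norm_constant_row_is_zero():
    out = layer_norm(np.full((2, 5), 3.7), np.ones(5), np.zeros(5))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-3)


def test_layer_norm_standardizes(rng):
    out = layer_norm(rng.normal(2, 3, (4, 50)), np.ones(50), np.zeros(50)).data
    np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-4)


def test_layer_norm_matches_scalar_loop(rng):
    X = rng.normal(0, 2, (4, 6))
    g, b = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
    out = layer_norm(X, g, b, eps=1e-6).data
    expect = np.empty_like(X)
    for i in range(4):
        mu = sum(X[i]) / 6
        var = sum((v - mu) ** 2 for v in X[i]) / 6
        for j in range(6):
            expect[i, j] = (X[i, j] - mu) / np.sqrt(var + 1e-6) * g[j] + b[j]
    np.testing.assert_allclose(out, expect, atol=1e-10)


# ---------------------------------------------------------------- attention


def test_attention_singleton_returns_value(rng):
    Q = rng.normal(0, 1, (1, 4))
    K = rng.normal(0, 1, (1, 4))
    V = rng.normal(0, 1, (1, 3))
    np.testing.assert_allclose(scaled_dot_product_attention(Q, K, V).data, V)


def test_attention_identical_keys_average_values(rng):
    K = np.tile(rng.normal(0, 1, (1, 4)), (5, 1))
    V = rng.normal(0, 1, (5, 3))
    out = scaled_dot_product_attention(rng.normal(0, 1, (2, 4)), K, V).data
    np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)


def test_attention_matches_double_loop_oracle(rng):
    Q, K, V = (rng.normal(0, 1, (3, 2)) for _ in range(3))
    out = scaled_dot_product_attention(Q, K, V).data
    expect = np.zeros((3, 2))
    for i in range(3):
        logits = [sum(Q[i, d] * K[j, d] for d in range(2)) / np.sqrt(2) for j in range(3)]
        e = np.exp(logits)
        w = e / e.sum()
        for d in range(2):
            expect[i, d] = sum(w[j] * V[j, d] for j in range(3))
    np.testing.assert_allclose(out, expect, atol=1e-6)


def test_attention_weight_rows_sum_to_one(rng):
    # recover the weights by attending over identity values
    n = 6
    Q, K = rng.normal(0, 1, (n, 3)), rng.normal(0, 1, (n, 3))
    W = scaled_dot_product_attention(Q, K, np.eye(n)).data
    np.testing.assert_allclose(W.sum(axis=-1), 1.0, atol=1e-6)
    assert (W > 0).all()


def test_attention_scaling_guard(rng):
    """Scaling Q and K jointly by c multiplies the logits by c²/1 — i.e. the
    √d_k divisor is applied once, not per factor."""
    n, dk, c = 4, 4, 3.0
    Q, K = rng.normal(0, 1, (n, dk)), rng.normal(0, 1, (n, dk))
    logits = lambda q, k: (q @ k.T) / np.sqrt(dk)
    np.testing.assert_allclose(logits(c * Q, c * K), c**2 * logits(Q, K), rtol=1e-12)
    # and the attention output reflects exactly those scaled logits
    V = rng.normal(0, 1, (n, 2))
    e = np.exp(c**2 * logits(Q, K) - (c**2 * logits(Q, K)).max(axis=1, keepdims=True))
    expect = (e / e.sum(axis=1, keepdims=True)) @ V
    np.testing.assert_allclose(
        scaled_dot_product_attention(c * Q, c * K, V).data, expect, atol=1e-10
    )


# ---------------------------------------------------------------- MSA


def _attn_params(rng, d_model, h):
    return AttentionParams(
        Wq=Tensor(rng.normal(0, 1, (d_model, d_model))),
        Wk=Tensor(rng.normal(0, 1, (d_model, d_model))),
        Wv=Tensor(rng.normal(0, 1, (d_model, d_model))),
        Wo=Tensor(rng.normal(0, 1, (d_model, d_model))),
        heads=h,
    )


def test_msa_single_head_reduces_to_plain_attention(rng):
    p = _attn_params(rng, 6, 1)
    X = rng.normal(0, 1, (5, 6))
    out = multi_head_self_attention(X, p).data
    expect = (
        scaled_dot_product_attention(X @ p.Wq.data, X @ p.Wk.data, X @ p.Wv.data).data
        @ p.Wo.data
    )
    np.testing.assert_allclose(out, expect, atol=1e-10)


def test_msa_permutation_equivariance(rng):
    p = _attn_params(rng, 8, 2)
    X = rng.normal(0, 1, (7, 8))
    perm = rng.permutation(7)
    out = multi_head_self_attention(X, p).data
    out_p = multi_head_self_attention(X[perm], p).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_msa_matches_per_head_loop(rng):
    d_model, h, n = 8, 2, 5
    p = _attn_params(rng, d_model, h)
    X = rng.normal(0, 1, (n, d_model))
    dk = d_model // h
    heads = []
    for i in range(h):
        sl = slice(i * dk, (i + 1) * dk)
        Q, K, V = X @ p.Wq.data[:, sl], X @ p.Wk.data[:, sl], X @ p.Wv.data[:, sl]
        heads.append(scaled_dot_product_attention(Q, K, V).data)
    expect = np.concatenate(heads, axis=-1) @ p.Wo.data
    np.testing.assert_allclose(
        multi_head_self_attention(X, p).data, expect, atol=1e-6
    )


def test_msa_rejects_nondividing_heads(rng):
    p = _attn_params(rng, 6, 4)
    with pytest.raises(ValueError):
        multi_head_self_attention(rng.normal(0, 1, (3, 6)), p)


# ---------------------------------------------------------------- FFN


def test_feed_forward_relu_gate_and_gelu_zero():
    p = FeedForwardParams(
        W1=Tensor(np.ones((1, 1))), b1=Tensor(np.zeros(1)),
        W2=Tensor(np.ones((1, 1))), b2=Tensor(np.zeros(1)), activation="relu",
    )
    assert feed_forward(np.array([[-1.0]]), p).data.item() == 0.0
    p.activation = "gelu"
    assert feed_forward(np.array([[0.0]]), p).data.item() == 0.0


def test_feed_forward_matches_loop_oracle(rng):
    p = FeedForwardParams(
        W1=Tensor(rng.normal(0, 1, (4, 6))), b1=Tensor(rng.normal(0, 1, 6)),
        W2=Tensor(rng.normal(0, 1, (6, 4))), b2=Tensor(rng.normal(0, 1, 4)),
        activation="relu",
    )
    X = rng.normal(0, 1, (3, 4))
    expect = np.zeros((3, 4))
    for i in range(3):
        hidden = [max(0.0, sum(X[i, a] * p.W1.data[a, j] for a in range(4)) + p.b1.data[j])
                  for j in range(6)]
        for d in range(4):
            expect[i, d] = sum(hidden[j] * p.W2.data[j, d] for j in range(6)) + p.b2.data[d]
    np.testing.assert_allclose(feed_forward(X, p).data, expect, atol=1e-6)


# ---------------------------------------------------------------- encoder block


def test_encoder_block_zero_weights_is_identity(rng):
    enc = init_encoder(rng, 8, 2, 16)
    for t in (enc.attn.Wq, enc.attn.Wk, enc.attn.Wv, enc.attn.Wo,
              enc.ffn.W1, enc.ffn.W2):
        t.data[:] = 0.0
    X = rng.normal(0, 1, (5, 8))
    np.testing.assert_allclose(encoder_block(X, enc).data, X, atol=1e-12)


def test_encoder_block_is_pre_ln_not_post_ln(rng):
    from mpvit.vit import layer_norm as ln, multi_head_self_attention as msa, feed_forward as ffn

    enc = init_encoder(rng, 8, 2, 16)
    X = rng.normal(0, 1, (5, 8))
    out = encoder_block(X, enc).data
    # pre-LN oracle
    zp = msa(ln(X, enc.ln1.g.data, enc.ln1.b.data), enc.attn).data + X
    pre = ffn(ln(zp, enc.ln2.g.data, enc.ln2.b.data), enc.ffn).data + zp
    np.testing.assert_allclose(out, pre, atol=1e-10)
    # deliberately post-LN (compute then normalize) differs
    zq = ln(msa(X, enc.attn).data + X, enc.ln1.g.data, enc.ln1.b.data).data
    post = ln(ffn(zq, enc.ffn).data + zq, enc.ln2.g.data, enc.ln2.b.data).data
    assert np.abs(out - post).max() > 1e-3


def test_encoder_blocks_compose_sequentially(rng):
    enc1 = init_encoder(rng, 8, 2, 16)
    enc2 = init_encoder(rng, 8, 2, 16)
    X = rng.normal(0, 1, (4, 8))
    once = encoder_block(encoder_block(X, enc1), enc2).data
    z = encoder_block(X, enc1)
    np.testing.assert_allclose(encoder_block(z, enc2).data, once, atol=1e-12)


def test_encoder_block_preserves_shape(rng):
    enc = init_encoder(rng, 8, 4, 32)
    X = rng.normal(0, 1, (2, 9, 8))
    assert encoder_block(X, enc).shape == (2, 9, 8)


# ---------------------------------------------------------------- sinusoidal PE


def test_sinusoidal_pe_position_zero():
    np.testing.assert_allclose(
        sinusoidal_position_encoding(0, 8), [0, 1, 0, 1, 0, 1, 0, 1]
    )


def test_sinusoidal_pe_formula_oracle():
    np.testing.assert_allclose(
        sinusoidal_position_encoding(1, 4),
        [np.sin(1.0), np.cos(1.0), np.sin(1e-2), np.cos(1e-2)],
        atol=1e-12,
    )


def test_sinusoidal_pe_wavelength_geometric_progression():
    d = 16
    # wavelength of dim pair i is 2*pi*10000^(2i/d)
    lams = [2 * np.pi * 10000 ** (2 * i / d) for i in range(d // 2)]
    ratios = np.diff(np.log(lams))
    np.testing.assert_allclose(ratios, ratios[0])
    assert np.isclose(lams[0], 2 * np.pi)
    assert np.isclose(lams[-1] * 10000 ** (2 / d), 10000 * 2 * np.pi)
    # and the implementation's first pair indeed oscillates with wavelength 2*pi
    tab = sinusoidal_table(8, d)
    np.testing.assert_allclose(tab[:, 0], np.sin(np.arange(8)), atol=1e-12)


def test_sinusoidal_pe_rejects_odd_dim():
    with pytest.raises(ValueError):
        sinusoidal_position_encoding(3, 5)
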