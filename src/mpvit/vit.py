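"""Vision Transformer computational primitives.

Functional building blocks for a pre-LN ViT encoder over a token sequence:
patch extraction, linear patch embedding with class token and position
embedding, layer normalization, scaled dot-product / multi-head
self-attention, the position-wise feed-forward network, and the encoder
block. All functions accept numpy arrays or autodiff Tensors and return
Tensors; parameters live in small dataclasses so the same code serves both
the differentiable training path and the closed-form unit tests.

Shapes follow the field's conventions: a sequence is ``(n, D)`` (or batched
``(B, n, D)``), an image ``(H, W)`` single-channel, a patch grid row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, concat

__all__ = [
    "patchify",
    "unpatchify",
    "embed_patches",
    "layer_norm",
    "scaled_dot_product_attention",
    "multi_head_self_attention",
    "feed_forward",
    "encoder_block",
    "sinusoidal_position_encoding",
    "LayerNormParams",
    "AttentionParams",
    "FeedForwardParams",
    "EncoderParams",
]

LN_EPS = 1e-6


# --------------------------------------------------------------------------
# patch extraction


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Split an H×W image (or B×H×W batch) into flattened square patches.

    Returns ``(N, P*P)`` with ``N = (H/P)*(W/P)``; patches are ordered
    row-major over the patch grid and pixels row-major within each patch.
    """
    img = np.asarray(image, dtype=np.float64)
    batched = img.ndim == 3
    if not batched:
        img = img[None]
    B, H, W = img.shape
    P = int(patch_size)
    if P <= 0:
        raise ValueError(f"patch_size must be positive, got {patch_size}")
    if H % P or W % P:
        raise ValueError(f"image size {H}x{W} not divisible by patch size {P}")
    gh, gw = H // P, W // P
    patches = (
        img.reshape(B, gh, P, gw, P).transpose(0, 1, 3, 2, 4).reshape(B, gh * gw, P * P)
    )
    return patches if batched else patches[0]


def unpatchify(patches: np.ndarray, image_size: int, patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for square images."""
    P, S = int(patch_size), int(image_size)
    g = S // P
    arr = np.asarray(patches, dtype=np.float64)
    return arr.reshape(g, g, P, P).transpose(0, 2, 1, 3).reshape(S, S)


# --------------------------------------------------------------------------
# embedding


def embed_patches(
    raw,
    E,
    pos_embedding,
    class_token=None,
) -> Tensor:
    """Linear patch embedding plus position embedding, optional class token.

    ``raw`` is ``(N, P²)`` or ``(B, N, P²)``; ``E`` maps P² → D. When a class
    token (shape ``(D,)`` or ``(1, D)``) is given it is prepended at index 0
    and the position table must cover N+1 rows.
    """
    raw = astensor(raw)
    E = astensor(E)
    pos = astensor(pos_embedding)
    tokens = raw @ E
    batched = tokens.ndim == 3
    if class_token is not None:
        ct = astensor(class_token).reshape(1, -1)
        if batched:
            B = tokens.shape[0]
            ct = ct.reshape(1, 1, -1).broadcast_to((B, 1, ct.shape[-1]))
            tokens = concat([ct, tokens], axis=1)
        else:
            tokens = concat([ct, tokens], axis=0)
    n = tokens.shape[-2]
    if pos.shape[-2] != n:
        raise ValueError(
            f"position embedding covers {pos.shape[-2]} tokens, sequence has {n}"
        )
    return tokens + pos


def sinusoidal_position_encoding(pos: int, d_model: int) -> np.ndarray:
    """Fixed sin/cos position encoding: sines on even dims, cosines on odd.

    ``PE(pos, 2i) = sin(pos / 10000^(2i/d))``, ``PE(pos, 2i+1) = cos(...)``;
    wavelengths form a geometric progression from 2π to 10000·2π.
    """
    if d_model % 2:
        raise ValueError("d_model must be even for sinusoidal encoding")
    i = np.arange(d_model // 2)
    angle = pos / np.power(10000.0, 2 * i / d_model)
    out = np.empty(d_model)
    out[0::2] = np.sin(angle)
    out[1::2] = np.cos(angle)
    return out


def sinusoidal_table(n_positions: int, d_model: int) -> np.ndarray:
    return np.stack(
        [sinusoidal_position_encoding(p, d_model) for p in range(n_positions)]
    )


# --------------------------------------------------------------------------
# normalization and attention


def layer_norm(X, g, b, eps: float = LN_EPS) -> Tensor:
    """Per-row layer normalization with learned gain/bias over the feature axis."""
    X, g, b = astensor(X), astensor(g), astensor(b)
    mu = X.mean(axis=-1, keepdims=True)
    centered = X - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / ((var + eps) ** 0.5) * g + b


def scaled_dot_product_attention(Q, K, V) -> Tensor:
    """softmax(QKᵀ/√d_k) V. Leading axes are treated as batch dimensions."""
    Q, K, V = astensor(Q), astensor(K), astensor(V)
    d_k = Q.shape[-1]
    if K.shape[-1] != d_k:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share the sequence length")
    logits = (Q @ K.transpose(tuple(range(K.ndim - 2)) + (K.ndim - 1, K.ndim - 2))) * (
        1.0 / np.sqrt(d_k)
    )
    return logits.softmax(axis=-1) @ V


@dataclass
class LayerNormParams:
    g: Tensor
    b: Tensor


@dataclass
class AttentionParams:
    """Per-head projections packed as (d_model, h*d_k) matrices plus output W_O."""

    Wq: Tensor
    Wk: Tensor
    Wv: Tensor
    Wo: Tensor
    heads: int


@dataclass
class FeedForwardParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    activation: str = "gelu"


@dataclass
class EncoderParams:
    ln1: LayerNormParams
    attn: AttentionParams
    ln2: LayerNormParams
    ffn: FeedForwardParams


def _split_heads(X: Tensor, h: int) -> Tensor:
    # (..., n, h*dk) -> (..., h, n, dk)
    *lead, n, hd = X.shape
    dk = hd // h
    X = X.reshape(tuple(lead) + (n, h, dk))
    axes = tuple(range(len(lead))) + (X.ndim - 2, X.ndim - 3, X.ndim - 1)
    return X.transpose(axes)


def _merge_heads(X: Tensor) -> Tensor:
    # (..., h, n, dv) -> (..., n, h*dv)
    *lead, h, n, dv = X.shape
    axes = tuple(range(len(lead))) + (X.ndim - 2, X.ndim - 3, X.ndim - 1)
    return X.transpose(axes).reshape(tuple(lead) + (n, h * dv))


def multi_head_self_attention(X, params: AttentionParams) -> Tensor:
    """Concat(head_1..head_h) W_O with per-head scaled dot-product attention."""
    X = astensor(X)
    h = params.heads
    if params.Wq.shape[-1] % h:
        raise ValueError(f"{h} heads do not divide projection dim {params.Wq.shape[-1]}")
    Q = _split_heads(X @ params.Wq, h)
    K = _split_heads(X @ params.Wk, h)
    V = _split_heads(X @ params.Wv, h)
    return _merge_heads(scaled_dot_product_attention(Q, K, V)) @ params.Wo


def feed_forward(X, params: FeedForwardParams) -> Tensor:
    """Position-wise MLP: act(X W1 + b1) W2 + b2."""
    X = astensor(X)
    hidden = X @ params.W1 + params.b1
    hidden = hidden.relu() if params.activation == "relu" else hidden.gelu()
    return hidden @ params.W2 + params.b2


def encoder_block(z_prev, params: EncoderParams) -> Tensor:
    """Pre-LN transformer encoder block: normalize, attend, residual; repeat for MLP."""
    z_prev = astensor(z_prev)
    zp = multi_head_self_attention(layer_norm(z_prev, params.ln1.g, params.ln1.b), params.attn) + z_prev
    return feed_forward(layer_norm(zp, params.ln2.g, params.ln2.b), params.ffn) + zp


# --------------------------------------------------------------------------
# parameter initialization


def init_layer_norm(dim: int) -> LayerNormParams:
    return LayerNormParams(
        g=Tensor(np.ones(dim), requires_grad=True),
        b=Tensor(np.zeros(dim), requires_grad=True),
    )


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, s, size=(fan_in, fan_out))


def init_encoder(
    rng: np.random.Generator, d_model: int, heads: int, mlp_dim: int,
    activation: str = "gelu",
) -> EncoderParams:
    attn = AttentionParams(
        Wq=Tensor(_xavier(rng, d_model, d_model), requires_grad=True),
        Wk=Tensor(_xavier(rng, d_model, d_model), requires_grad=True),
        Wv=Tensor(_xavier(rng, d_model, d_model), requires_grad=True),
        Wo=Tensor(_xavier(rng, d_model, d_model), requires_grad=True),
        heads=heads,
    )
    ffn = FeedForwardParams(
        W1=Tensor(_xavier(rng, d_model, mlp_dim), requires_grad=True),
        b1=Tensor(np.zeros(mlp_dim), requires_grad=True),
        W2=Tensor(_xavier(rng, mlp_dim, d_model), requires_grad=True),
        b2=Tensor(np.zeros(d_model), requires_grad=True),
        activation=activation,
    )
    return EncoderParams(
        ln1=init_layer_norm(d_model), attn=attn, ln2=init_layer_norm(d_model), ffn=ffn
    )


def encoder_parameters(p: EncoderParams) -> list[Tensor]:
    return [
        p.ln1.g, p.ln1.b,
        p.attn.Wq, p.attn.Wk, p.attn.Wv, p.attn.Wo,
        p.ln2.g, p.ln2.b,
        p.ffn.W1, p.ffn.b1, p.ffn.W2, p.ffn.b2,
    ]
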