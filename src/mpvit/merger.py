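"""Patch Merger: learned token-count reduction between encoder blocks.

A Patch Merger is a learned D×M matrix W with a dedicated pre-merge layer
norm. For an n×D input sequence X it computes

    X_ln = LN(X);  A = softmax_over_tokens(X_ln W);  Y = Aᵀ X_ln  (M×D)

so each of the M output tokens is a convex combination of the layer-normalized
input tokens. The scores depend only on token content, never on position, so
the layer is permutation-invariant and accepts any n with fixed parameters —
the properties that make it usable as a drop-in reduction stage.

Placement: in the fused variant one merger follows the floor(L/3)-th encoder
and a second the floor(2L/3)-th, splitting the stack into three thirds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor
from .vit import LayerNormParams, init_layer_norm, layer_norm

__all__ = ["MergerWeights", "MergerPlan", "merge_patches", "merger_positions", "init_merger"]


@dataclass
class MergerWeights:
    """Learned D×M projection plus its dedicated pre-merge LN parameters."""

    W: Tensor  # (D, M)
    ln: LayerNormParams

    @property
    def M(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class MergerPlan:
    """Encoder indices (1-based) after which the two mergers sit."""

    L: int
    positions: tuple[int, int]


def merge_patches(X, mw: MergerWeights) -> Tensor:
    """Reduce an (..., n, D) sequence to (..., M, D) output tokens.

    Softmax normalizes over the input-token axis, one distribution per output
    token, so every output row is a convex combination of LN'd input rows.
    """
    X = astensor(X)
    D = mw.W.shape[0]
    if X.shape[-1] != D:
        raise ValueError(f"input dim {X.shape[-1]} does not match merger D={D}")
    X_ln = layer_norm(X, mw.ln.g, mw.ln.b)
    scores = X_ln @ mw.W  # (..., n, M)
    A = scores.softmax(axis=-2)  # column j: weights over the n input tokens
    axes = tuple(range(A.ndim - 2)) + (A.ndim - 1, A.ndim - 2)
    return A.transpose(axes) @ X_ln


def merger_positions(L: int) -> MergerPlan:
    """Place mergers after the floor(L/3)-th and floor(2L/3)-th encoders.

    Requires L ≥ 3; positions are clamped so that 1 ≤ p1 < p2 < L always holds.
    """
    if L < 3:
        raise ValueError(f"merger placement needs at least 3 encoders, got L={L}")
    p1 = max(1, L // 3)
    p2 = min(L - 1, max(p1 + 1, (2 * L) // 3))
    return MergerPlan(L=L, positions=(p1, p2))


def init_merger(rng: np.random.Generator, d_model: int, m_out: int) -> MergerWeights:
    s = np.sqrt(2.0 / (d_model + m_out))
    return MergerWeights(
        W=Tensor(rng.normal(0.0, s, size=(d_model, m_out)), requires_grad=True),
        ln=init_layer_norm(d_model),
    )


def merger_parameters(mw: MergerWeights) -> list[Tensor]:
    return [mw.W, mw.ln.g, mw.ln.b]
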