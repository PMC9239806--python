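"""Model assembly: plain ViT, ViT + single Patch Merger, and the fused variant.

Three variants share the same encoder primitives:

* ``vit`` — the plain classifier: class token, L pre-LN encoder blocks, final
  LN of the class-token state, linear head.
* ``vit-merger`` — one Patch Merger after the floor(L/2)-th encoder; no class
  token; classification from the mean-pooled final tokens.
* ``mp-vit`` — mergers after the floor(L/3)-th and floor(2L/3)-th encoders.
  Both merger outputs are retained, and at the top they are fused with the
  final encoder output by a shared 3→1 linear map (a kernel-size-1
  convolution over the stream axis) before mean-pooling and the linear head.

The fusion is the distinctive piece: it re-injects the intermediate merger
representations — earlier semantic levels — into the classification feature,
so information compressed away mid-stack can still reach the head directly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .merger import (
    MergerWeights,
    init_merger,
    merge_patches,
    merger_parameters,
    merger_positions,
)
from .vit import (
    EncoderParams,
    LayerNormParams,
    embed_patches,
    encoder_block,
    encoder_parameters,
    init_encoder,
    init_layer_norm,
    layer_norm,
    patchify,
)

__all__ = [
    "ModelConfig",
    "FusionState",
    "MPViTModel",
    "fuse_streams",
    "count_tokens_per_layer",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("vit", "vit-merger", "mp-vit")


@dataclass
class ModelConfig:
    variant: str = "mp-vit"
    image_size: int = 224
    patch_size: int = 16
    d_model: int = 64
    depth: int = 6
    heads: int = 4
    mlp_dim: int = 0  # 0 → 4*d_model
    m_tokens: int = 8
    n_classes: int = 2
    activation: str = "gelu"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")
        if self.variant != "vit" and self.depth < 3:
            raise ValueError("merger variants need depth >= 3")
        if self.mlp_dim == 0:
            self.mlp_dim = 4 * self.d_model

    @property
    def n_patches(self) -> int:
        g = self.image_size // self.patch_size
        return g * g

    @property
    def use_class_token(self) -> bool:
        return self.variant == "vit"


@dataclass
class FusionState:
    """The three retained M×D streams and the shared 3→1 fusion map."""

    intermediate1: Tensor
    intermediate2: Tensor
    final: Tensor
    kernel: Tensor  # (3,)
    bias: Tensor  # scalar


def fuse_streams(fs: FusionState) -> Tensor:
    """Kernel-size-1 fusion: w1·s1 + w2·s2 + w3·s3 + b at every (m, d) position."""
    s1, s2, s3 = fs.intermediate1, fs.intermediate2, fs.final
    if not (s1.shape == s2.shape == s3.shape):
        raise ValueError(
            f"fusion streams must share a shape, got {s1.shape}, {s2.shape}, {s3.shape}"
        )
    k = fs.kernel
    return s1 * k[0] + s2 * k[1] + s3 * k[2] + fs.bias


def count_tokens_per_layer(cfg: ModelConfig) -> dict:
    """Per-encoder token counts and the Σn² attention-cost proxy."""
    N = cfg.n_patches + (1 if cfg.use_class_token else 0)
    counts: list[int] = []
    n = N
    if cfg.variant == "vit":
        counts = [N] * cfg.depth
    elif cfg.variant == "vit-merger":
        mid = cfg.depth // 2
        for layer in range(1, cfg.depth + 1):
            counts.append(n)
            if layer == mid:
                n = cfg.m_tokens
    else:
        p1, p2 = merger_positions(cfg.depth).positions
        for layer in range(1, cfg.depth + 1):
            counts.append(n)
            if layer in (p1, p2):
                n = cfg.m_tokens
    return {"tokens": counts, "cost_proxy": int(sum(c * c for c in counts))}


class MPViTModel:
    """A configured variant with its parameters; callable on image batches."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        D, P = cfg.d_model, cfg.patch_size
        n_seq = cfg.n_patches + (1 if cfg.use_class_token else 0)

        s = np.sqrt(2.0 / (P * P + D))
        self.embedding = Tensor(rng.normal(0.0, s, size=(P * P, D)), requires_grad=True)
        self.pos_embedding = Tensor(
            rng.normal(0.0, 0.02, size=(n_seq, D)), requires_grad=True
        )
        self.class_token = (
            Tensor(rng.normal(0.0, 0.02, size=(D,)), requires_grad=True)
            if cfg.use_class_token
            else None
        )
        self.encoders: list[EncoderParams] = [
            init_encoder(rng, D, cfg.heads, cfg.mlp_dim, cfg.activation)
            for _ in range(cfg.depth)
        ]

        self.mergers: list[MergerWeights] = []
        if cfg.variant == "vit-merger":
            self._merge_after = (cfg.depth // 2,)
            self.mergers = [init_merger(rng, D, cfg.m_tokens)]
        elif cfg.variant == "mp-vit":
            self._merge_after = merger_positions(cfg.depth).positions
            self.mergers = [
                init_merger(rng, D, cfg.m_tokens),
                init_merger(rng, D, cfg.m_tokens),
            ]
        else:
            self._merge_after = ()

        if cfg.variant == "mp-vit":
            # near-uniform init keeps all three streams alive from step one
            self.fusion_kernel = Tensor(np.full(3, 1.0 / 3.0), requires_grad=True)
            self.fusion_bias = Tensor(0.0, requires_grad=True)
        else:
            self.fusion_kernel = None
            self.fusion_bias = None

        self.final_ln: LayerNormParams = init_layer_norm(D)
        sh = np.sqrt(2.0 / (D + cfg.n_classes))
        self.head_W = Tensor(rng.normal(0.0, sh, size=(D, cfg.n_classes)), requires_grad=True)
        self.head_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.embedding, self.pos_embedding]
        if self.class_token is not None:
            params.append(self.class_token)
        for enc in self.encoders:
            params.extend(encoder_parameters(enc))
        for mw in self.mergers:
            params.extend(merger_parameters(mw))
        if self.fusion_kernel is not None:
            params.extend([self.fusion_kernel, self.fusion_bias])
        params.extend([self.final_ln.g, self.final_ln.b, self.head_W, self.head_b])
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def forward(self, images: np.ndarray) -> tuple[Tensor, dict]:
        """Logits of shape (B, n_classes) plus diagnostics for an image batch."""
        cfg = self.cfg
        imgs = np.asarray(images, dtype=np.float64)
        if imgs.ndim == 2:
            imgs = imgs[None]
        if imgs.shape[1] != cfg.image_size or imgs.shape[2] != cfg.image_size:
            raise ValueError(
                f"expected {cfg.image_size}x{cfg.image_size} images, got {imgs.shape[1:]}"
            )
        raw = patchify(imgs, cfg.patch_size)
        z = embed_patches(raw, self.embedding, self.pos_embedding, self.class_token)

        token_counts: list[int] = []
        retained: list[Tensor] = []
        merger_idx = 0
        for layer, enc in enumerate(self.encoders, start=1):
            token_counts.append(z.shape[-2])
            z = encoder_block(z, enc)
            if merger_idx < len(self.mergers) and layer == self._merge_after[merger_idx]:
                z = merge_patches(z, self.mergers[merger_idx])
                retained.append(z)
                merger_idx += 1

        if cfg.variant == "vit":
            feat = layer_norm(z[:, 0, :], self.final_ln.g, self.final_ln.b)
        elif cfg.variant == "vit-merger":
            feat = layer_norm(z.mean(axis=1), self.final_ln.g, self.final_ln.b)
        else:
            fused = fuse_streams(
                FusionState(
                    intermediate1=retained[0],
                    intermediate2=retained[1],
                    final=z,
                    kernel=self.fusion_kernel,
                    bias=self.fusion_bias,
                )
            )
            feat = layer_norm(fused.mean(axis=1), self.final_ln.g, self.final_ln.b)

        logits = feat @ self.head_W + self.head_b
        diagnostics = {
            "token_counts": token_counts,
            "n_retained_streams": len(retained),
        }
        return logits, diagnostics

    __call__ = forward


def build_model(cfg: ModelConfig) -> MPViTModel:
    return MPViTModel(cfg)


# --------------------------------------------------------------------------
# checkpoints: npz of parameter arrays + embedded JSON config


def save_checkpoint(model: MPViTModel, path, extra: dict | None = None) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[MPViTModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode("utf-8"))
        cfg = ModelConfig(**meta["config"])
        model = MPViTModel(cfg)
        for i, p in enumerate(model.parameters()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint parameter shapes do not match config")
            p.data = arr.astype(np.float64)
    return model, meta.get("extra", {})
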