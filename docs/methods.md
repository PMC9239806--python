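# Methods

## The model

The package implements three binary image classifiers over a shared pre-LN
Vision Transformer core, for grayscale chest-radiograph-style input:

1. **Plain ViT.** The H×W image (single channel) is cut into non-overlapping
   P×P patches, giving N = (H/P)·(W/P) tokens of P² pixels each, linearly
   embedded to dimension D. A learnable class token is prepended and a
   learnable 1-D position embedding added:

       z₀ = [x_class; x_p¹E; …; x_pᴺE] + E_pos

   L encoder blocks follow, each in pre-LN residual order:

       z′ = MSA(LN(z)) + z,   z ← MLP(LN(z′)) + z′

   with multi-head self-attention softmax(QKᵀ/√d_k)V (d_k = d_v = D/h) and a
   two-layer GELU MLP. The classification feature is LN(z_L[0]), the final
   class-token state, followed by a linear D→2 head.

2. **ViT + Patch Merger.** A Patch Merger is a learned D×M matrix W with its
   own pre-merge LN. For an n×D sequence X it computes

       X_ln = LN(X),  A = softmax over the token axis of X_ln W,  Y = Aᵀ X_ln

   so each of the M outputs is a convex combination of the LN'd inputs. The
   softmax axis is chosen over the input tokens (one distribution per output
   token); this is what yields the layer's defining properties — convexity,
   permutation invariance, and independence of the parameter shapes from n —
   all of which are property-tested. In this variant a single merger sits
   after the floor(L/2)-th encoder; the class token is dropped and the head
   reads the LN of the mean-pooled final tokens.

3. **Fused variant (MP-ViT).** Mergers sit after the floor(L/3)-th and
   floor(2L/3)-th encoders (positions clamped so 1 ≤ p1 < p2 < L). Both are
   D×M → M tokens, with the same M, because the top of the network
   concatenates the two retained merger outputs with the final encoder output
   into an M×D×3 stack and fuses them by a kernel-size-1 convolution — a
   single learned 3→1 affine map (w₁, w₂, w₃, b) shared across all M·D
   positions. The head reads the LN of the mean over the M fused tokens.
   Retaining the intermediate merger outputs lets representations from
   earlier semantic levels reach the classifier directly instead of having to
   survive every later block, and gives the fusion weights a short gradient
   path to the mid-stack layers.

Design points that were genuinely open, and the choices made:

- **Class token in merger variants.** A merger would absorb the token into
  weighted mixtures, destroying its read-out role, so merger variants carry
  no class token and classify from pooled tokens instead.
- **Head shape.** A single linear layer after pooling (no hidden layer).
- **Fusion initialization.** The kernel starts at (⅓, ⅓, ⅓) so all three
  streams contribute from the first step; connectivity of gradients to all
  three weights is asserted in the tests.
- **LN epsilon** is 1e-6; the merger's LN has its own learned gain/bias,
  independent of the encoder LNs.

## Training

Targets are smoothed labels ŷ = (1−α)·one_hot + α/K (entries sum to one;
α defaults to 0.01), and the loss is the smoothed cross-entropy
−Σ ŷᵢ log softmax(z)ᵢ computed through log-sum-exp. The optimizer is Adam
with default moments. The test split doubles as the per-epoch monitoring
set and the returned model is the epoch with the best test accuracy
(earlier epoch wins ties). Everything is seeded: parameter init, batch
shuffling, and the data generator, so two runs with one config are
bit-identical up to floating-point summation order.

Two presets exist. The full-scale preset keeps lr = 1e-5 and up to 200
epochs — the published regime for the real chest X-ray corpus. The
desk-scale preset, which the test suite and `scripts/acceptance.py`
exercise, uses 64×64 images, patch 8 (N = 64 tokens), D = 64, L = 6,
h = 4, M = 8, 30 epochs, batch 32, and Adam lr = 1e-3 — the standard rate
for training a tiny transformer from scratch; at 1e-5 a 30-epoch budget
(~190 optimizer steps) would barely move the parameters. Problem sizes for
the desk runs are 200 training and 100 test images.

The whole numerical stack is numpy: a small reverse-mode autodiff tape
(`mpvit.autodiff`) supplies gradients, and every backward rule is checked
against central finite differences in the test suite.

## The synthetic data generator

The generator emulates the *geometry* of the screening problem, not its
radiology. Both classes share a background of a vertical intensity gradient
(0.25→0.60), a sinusoidal rib texture (amplitude 0.08, default period 24 px
at 224, 12 px at the 64-px desk scale) and i.i.d. Gaussian noise
(σ = 0.05). The PNEUMONIA class adds `blob_count` = 3 Gaussian opacities
(peak 0.4, radius 10 px at 224 / 4 px at 64) placed uniformly in the
central 60 % window, so the discriminative evidence is local and small
relative to the frame — the regime the merger/fusion design targets. All
intensities are clipped to [0,1]; disk format is 8-bit PNG, quantized only
at write time.

Per-image randomness derives from a SeedSequence keyed on
(seed, split, index). The class label is deliberately *not* part of the
key: the two classes are matched pairs over one background stream, the
label only gating the additive blob term, so setting blob intensity to zero
makes the classes byte-identical and every blob mask has an exact matched
control region in the NORMAL twin.

What passing tests on this data do and do not show: they demonstrate that
the full pipeline — generator, preprocessing, model, optimizer, metrics —
learns a localized additive signal reliably and deterministically. They say
nothing about performance on real radiographs, where class evidence
includes texture and shape changes, acquisition varies, and labels are
noisy; the published-scale numbers require the real corpus and a
GPU-length budget and are out of scope here.

## Preprocessing

Images are decoded with Pillow, RGB collapsed by channel averaging, scaled
to [0,1], bilinearly resized (half-pixel centers; verified against an
explicit bilinear oracle) and then optionally unsharp-masked:

    enhanced = clip(I + amount · (I − Gauss(I, σ=radius)), 0, 1)

"Radius" is read as the Gaussian σ and "amount" as a direct multiplier on
the detail signal — the most common UM parameterization; the defaults are
radius 1, amount 15. Resizing precedes enhancement so the blur scale is
resolution-independent. The alternative percentage reading of "amount" is
available simply by passing amount = 0.15.

## Metrics

With PNEUMONIA as the positive class: accuracy (TP+TN)/total, precision
TP/(TP+FP), recall TP/(TP+FN), and F_β = (β²+1)PR/(β²P+R) with F1 at β = 1.
Zero denominators report 0 with a `zero_division` flag. Because the
averaging convention behind published F-scores is often unstated, both the
positive-class and macro-averaged values are always reported. The
identities are cross-checked against scikit-learn on 1,000 random
confusion matrices.

## Numerical choices and degenerate inputs

- Softmax and cross-entropy are computed through max-shifted exponentials /
  log-sum-exp; extreme logits (±1000) stay finite.
- LN of a constant row returns b (the eps guard absorbs σ = 0).
- Merger positions are clamped to keep 1 ≤ p1 < p2 < L for every L ≥ 3;
  L < 3 is rejected.
- Best-checkpoint ties break toward the earlier epoch (strict `>` update).
- The token-cost proxy Σ nᵢ² counts tokens entering each encoder block; it
  is a hardware-independent stand-in for self-attention compute.

## Known limitations

- The autodiff engine implements exactly the operations the model needs; it
  is not a general framework (no higher-order gradients, float64 only).
- Training is single-threaded numpy; the full-size preset (D = 768, L = 12,
  224-px input) is configurable but not practical here.
- The generator's classes differ only by additive blobs; monotone
  separability in blob intensity is a property of this family, not of
  radiographs.
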