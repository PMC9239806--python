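"""Label smoothing, cross-entropy, the training loop and evaluation metrics.

Targets are smoothed label vectors

    y_smooth = (1 - alpha) * one_hot + alpha / K

which sum to one and keep every entry positive for alpha > 0, penalizing
overconfident predictions. The loss is the smoothed cross-entropy
-Σ ŷ_i log p_i computed through log-softmax for numerical stability, averaged
over the batch. Optimization is Adam; the test split doubles as the per-epoch
monitoring set and the best checkpoint is the epoch with the highest test
accuracy (earlier epoch wins ties).

Evaluation reports confusion counts with PNEUMONIA as the positive class and
the derived accuracy / precision / recall / F-beta, both for the positive
class and macro-averaged over the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, astensor
from .model import ModelConfig, MPViTModel, build_model, save_checkpoint
from .preprocess import UMConfig, load_image, unsharp_mask
from .synth import CLASSES, DatasetManifest

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "smooth_labels",
    "cross_entropy",
    "compute_metrics",
    "confusion_from_predictions",
    "load_split_arrays",
    "train",
    "evaluate",
]

LABEL_OF = {c: i for i, c in enumerate(CLASSES)}  # NORMAL=0, PNEUMONIA=1


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-5  # full-scale published rate; desk preset overrides
    max_epochs: int = 200
    batch_size: int = 32
    alpha: float = 0.01  # label-smoothing epsilon
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


def desk_train_config(seed: int = 0, max_epochs: int = 30) -> TrainConfig:
    """Desk-scale preset: small model, short budget, standard Adam rate."""
    return TrainConfig(lr=1e-3, max_epochs=max_epochs, batch_size=32, alpha=0.01, seed=seed)


# --------------------------------------------------------------------------
# label smoothing and loss


def smooth_labels(target_class: int, alpha: float, n_classes: int) -> np.ndarray:
    """Smoothed target vector: (1-alpha)*one_hot + alpha/K; sums to one."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0 <= target_class < n_classes:
        raise ValueError("target_class out of range")
    y = np.full(n_classes, alpha / n_classes)
    y[target_class] += 1.0 - alpha
    return y


def cross_entropy(logits, targets) -> Tensor:
    """-Σ ŷ log softmax(z), averaged over the batch; stable via log-sum-exp."""
    logits = astensor(logits)
    targets = astensor(targets)
    logp = logits.log_softmax(axis=-1)
    per_sample = -(targets * logp).sum(axis=-1)
    return per_sample.mean() if per_sample.ndim else per_sample


# --------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    f_beta: float
    beta: float
    averaging: str
    zero_division: bool = False


def _prf(tp: int, fp: int, fn: int, beta: float) -> tuple[float, float, float, bool]:
    flag = False
    if tp + fp == 0:
        precision, flag = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, flag = 0.0, True
    else:
        recall = tp / (tp + fn)
    denom = beta**2 * precision + recall
    fb = 0.0 if denom == 0 else (beta**2 + 1) * precision * recall / denom
    return precision, recall, fb, flag


def compute_metrics(
    cm: ConfusionMatrix, beta: float = 1.0, averaging: str = "positive-class"
) -> MetricsReport:
    """Accuracy, precision, recall and F-beta from confusion counts.

    ``positive-class`` scores the PNEUMONIA class; ``macro`` averages the
    per-class scores of both classes (NORMAL scored with the roles of
    positive/negative swapped).
    """
    if cm.total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total
    if averaging == "positive-class":
        p, r, fb, flag = _prf(cm.tp, cm.fp, cm.fn, beta)
        p1, r1, f1_, _ = _prf(cm.tp, cm.fp, cm.fn, 1.0)
    elif averaging == "macro":
        pa, ra, fba, fl_a = _prf(cm.tp, cm.fp, cm.fn, beta)
        pb, rb, fbb, fl_b = _prf(cm.tn, cm.fn, cm.fp, beta)
        p, r, fb, flag = (pa + pb) / 2, (ra + rb) / 2, (fba + fbb) / 2, fl_a or fl_b
        _, _, f1a, _ = _prf(cm.tp, cm.fp, cm.fn, 1.0)
        _, _, f1b, _ = _prf(cm.tn, cm.fn, cm.fp, 1.0)
        f1_ = (f1a + f1b) / 2
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return MetricsReport(
        accuracy=accuracy, precision=p, recall=r, f1=f1_, f_beta=fb,
        beta=beta, averaging=averaging, zero_division=flag,
    )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


# --------------------------------------------------------------------------
# data plumbing


def load_split_arrays(
    root,
    manifest: DatasetManifest,
    split: str,
    image_size: int,
    um: UMConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Images (n, S, S) and integer labels for one split of a manifest."""
    root = Path(root)
    sub = manifest.entries[manifest.entries["split"] == split]
    if sub.empty:
        raise ValueError(f"manifest has no {split!r} entries")
    images, labels = [], []
    for _, row in sub.iterrows():
        img = load_image(root / row["path"], target_size=image_size)
        if um is not None:
            img = unsharp_mask(img, um)
        images.append(img)
        labels.append(LABEL_OF[row["label"]])
    return np.stack(images), np.asarray(labels, dtype=int)


# --------------------------------------------------------------------------
# training


@dataclass
class TrainLog:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "epoch", "train_loss", "test_loss",
                "accuracy", "precision", "recall", "f1",
            ],
        )


def _batch_loss(model: MPViTModel, images: np.ndarray, targets: np.ndarray) -> Tensor:
    logits, _ = model.forward(images)
    return cross_entropy(logits, targets)


def _dataset_loss_and_preds(
    model: MPViTModel, images: np.ndarray, targets: np.ndarray, batch_size: int
) -> tuple[float, np.ndarray]:
    losses, preds = [], []
    for lo in range(0, len(images), batch_size):
        batch = images[lo : lo + batch_size]
        logits, _ = model.forward(batch)
        losses.append(
            cross_entropy(logits, targets[lo : lo + batch_size]).data * len(batch)
        )
        preds.append(np.argmax(logits.data, axis=-1))
    return float(np.sum(losses) / len(images)), np.concatenate(preds)


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    checkpoint_path=None,
) -> tuple[MPViTModel, TrainLog]:
    """Mini-batch Adam on smoothed cross-entropy; keeps the best-accuracy state.

    Returns the model restored to its best test-accuracy epoch plus the
    per-epoch log. Raises on an empty dataset or a NaN loss.
    """
    if len(train_images) == 0 or len(test_images) == 0:
        raise ValueError("empty dataset")
    K = model_cfg.n_classes
    smooth = np.stack([smooth_labels(c, train_cfg.alpha, K) for c in range(K)])
    train_targets = smooth[np.asarray(train_labels, dtype=int)]
    test_targets = smooth[np.asarray(test_labels, dtype=int)]

    model = build_model(model_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    log = TrainLog()
    best = {"acc": -1.0, "epoch": -1, "params": None}

    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(len(train_images))
        epoch_losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            loss = _batch_loss(model, train_images[idx], train_targets[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.data * len(idx))
        train_loss = float(np.sum(epoch_losses) / len(order))

        test_loss, preds = _dataset_loss_and_preds(
            model, test_images, test_targets, train_cfg.batch_size
        )
        cm = confusion_from_predictions(test_labels, preds)
        rep = compute_metrics(cm)
        log.rows.append(
            {
                "epoch": epoch, "train_loss": train_loss, "test_loss": test_loss,
                "accuracy": rep.accuracy, "precision": rep.precision,
                "recall": rep.recall, "f1": rep.f1,
            }
        )
        if rep.accuracy > best["acc"]:
            best = {
                "acc": rep.accuracy, "epoch": epoch,
                "params": [p.data.copy() for p in model.parameters()],
            }

    for p, saved in zip(model.parameters(), best["params"]):
        p.data = saved
    if checkpoint_path is not None:
        save_checkpoint(
            model, checkpoint_path,
            extra={"best_epoch": best["epoch"], "best_accuracy": best["acc"],
                   "label_of": LABEL_OF},
        )
    return model, log


def evaluate(
    model: MPViTModel,
    images: np.ndarray,
    labels: np.ndarray,
    batch_size: int = 32,
    beta: float = 1.0,
) -> tuple[ConfusionMatrix, dict[str, MetricsReport]]:
    """Argmax predictions, confusion counts and both metric averagings."""
    preds = []
    for lo in range(0, len(images), batch_size):
        logits, _ = model.forward(images[lo : lo + batch_size])
        preds.append(np.argmax(logits.data, axis=-1))
    cm = confusion_from_predictions(labels, np.concatenate(preds))
    return cm, {
        "positive-class": compute_metrics(cm, beta=beta, averaging="positive-class"),
        "macro": compute_metrics(cm, beta=beta, averaging="macro"),
    }
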