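"""Seeded generator of radiograph-like grayscale images.

Chest-film surrogates for offline testing and desk-scale experiments: both
classes share a background of a vertical intensity gradient, a sinusoidal
"rib" texture and Gaussian pixel noise; the PNEUMONIA class additionally
receives a small number of soft additive Gaussian blobs ("opacities") placed
uniformly inside a central window, so the discriminative signal is local and
covers a small fraction of the image — the situation the merger/fusion
architecture is designed for. Images are written as 8-bit PNGs in the
class-per-directory layout of the public pediatric chest X-ray datasets
(train/NORMAL, train/PNEUMONIA, test/NORMAL, test/PNEUMONIA) with a CSV
manifest.

Determinism: every image is a pure function of (spec, split, class, index).
The global seed expands to per-image seeds through a numpy SeedSequence keyed
on (seed, split, index); the class only gates whether the blob signal is
added, so the two classes are matched pairs over a shared background stream
and setting blob_intensity to zero collapses them exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["SynthSpec", "DatasetManifest", "generate_image", "generate_dataset", "desk_spec"]

CLASSES = ("NORMAL", "PNEUMONIA")
SPLITS = ("train", "test")
_SPLIT_CODE = {s: i for i, s in enumerate(SPLITS)}

# fraction of the image side occupied by the central blob-placement window
_BLOB_WINDOW = 0.6


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters; identical specs yield byte-identical datasets."""

    image_size: int = 224
    n_train_per_class: int = 100
    n_test_per_class: int = 50
    blob_count: int = 3
    blob_intensity: float = 0.4
    blob_radius: float = 10.0
    rib_period: float = 24.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")
        if not 0.0 <= self.blob_intensity <= 1.0:
            raise ValueError("blob_intensity must lie in [0, 1]")


def desk_spec(seed: int = 0, n_train_per_class: int = 100, n_test_per_class: int = 50) -> SynthSpec:
    """Desk-scale 64×64 preset with blob geometry scaled to the smaller frame."""
    return SynthSpec(
        image_size=64,
        n_train_per_class=n_train_per_class,
        n_test_per_class=n_test_per_class,
        blob_count=3,
        blob_intensity=0.4,
        blob_radius=4.0,
        rib_period=12.0,
        noise_sigma=0.05,
        seed=seed,
    )


@dataclass
class DatasetManifest:
    entries: pd.DataFrame  # columns: path, label, split

    def counts(self, split: str) -> dict[str, int]:
        sub = self.entries[self.entries["split"] == split]
        return {c: int((sub["label"] == c).sum()) for c in CLASSES}

    def class_ratio(self, split: str) -> float:
        """Positive:negative ratio (PNEUMONIA / NORMAL) for a split."""
        c = self.counts(split)
        return c["PNEUMONIA"] / c["NORMAL"]

    def summary(self) -> dict:
        out: dict = {}
        for split in SPLITS:
            c = self.counts(split)
            out[split] = {**c, "ratio_pneumonia_to_normal": round(self.class_ratio(split), 3)}
        return out


def _image_rng(spec: SynthSpec, split: str, index: int) -> np.random.Generator:
    # class is deliberately absent from the key: the two classes share one
    # background/geometry stream, so blob_intensity=0 collapses them exactly
    key = [spec.seed, _SPLIT_CODE[split], int(index)]
    return np.random.default_rng(np.random.SeedSequence(key))


def _background(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    S = spec.image_size
    y = np.linspace(0.0, 1.0, S)[:, None]
    gradient = 0.25 + 0.35 * y  # darker apices, brighter bases
    phase = rng.uniform(0.0, 2.0 * np.pi)
    ribs = 0.08 * np.sin(2.0 * np.pi * y * S / spec.rib_period + phase)
    noise = rng.normal(0.0, spec.noise_sigma, size=(S, S))
    return gradient + ribs + noise


def _blob_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian bumps with unit peak, centers in the central window."""
    S = spec.image_size
    lo = 0.5 * (1.0 - _BLOB_WINDOW) * S
    hi = S - lo
    yy, xx = np.mgrid[0:S, 0:S]
    mask = np.zeros((S, S))
    for _ in range(spec.blob_count):
        cy, cx = rng.uniform(lo, hi, size=2)
        mask += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * spec.blob_radius**2))
    return mask


def generate_image(
    class_label: str, spec: SynthSpec, index: int, split: str = "train"
) -> np.ndarray:
    """One seeded image in [0,1]; PNEUMONIA adds blob_count soft opacities."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {CLASSES}")
    rng = _image_rng(spec, split, index)
    img = _background(spec, rng)
    # blob geometry is drawn for both classes from the shared stream so that
    # blob_intensity=0 makes the classes identically distributed
    blobs = _blob_mask(spec, rng)
    if class_label == "PNEUMONIA":
        img = img + spec.blob_intensity * blobs
    return np.clip(img, 0.0, 1.0)


def blob_regions(spec: SynthSpec, index: int, split: str = "train") -> np.ndarray:
    """Boolean mask of the blob loci the PNEUMONIA image at `index` received.

    Exposes the generator's own geometry so tests can compare intensity inside
    lesion regions against matched control regions in NORMAL images.
    """
    rng = _image_rng(spec, split, index)
    _background(spec, rng)  # consume the background stream
    return _blob_mask(spec, rng) > 0.5


def write_png(img: np.ndarray, path) -> None:
    q = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path, format="PNG")


def generate_dataset(spec: SynthSpec, out_dir) -> DatasetManifest:
    """Write the train/test class-per-directory PNG tree and manifest.csv."""
    out = Path(out_dir)
    rows = []
    for split in SPLITS:
        n = spec.n_train_per_class if split == "train" else spec.n_test_per_class
        for cls in CLASSES:
            d = out / split / cls
            d.mkdir(parents=True, exist_ok=True)
            for i in range(n):
                path = d / f"{cls.lower()}_{i:04d}.png"
                write_png(generate_image(cls, spec, i, split=split), path)
                rows.append(
                    {"path": os.path.relpath(path, out), "label": cls, "split": split}
                )
    entries = pd.DataFrame(rows, columns=["path", "label", "split"])
    entries.to_csv(out / "manifest.csv", index=False)
    return DatasetManifest(entries=entries)
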