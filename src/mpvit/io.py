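"""Dataset-directory ingest and run-configuration plumbing.

`read_dataset_dir` scans a class-per-directory tree (train/NORMAL,
train/PNEUMONIA, test/NORMAL, test/PNEUMONIA — the layout of the public
pediatric chest X-ray releases) into the same manifest the synthetic
generator emits, recording unreadable files in a skipped list rather than
silently dropping them. `RunConfig` is the flat YAML schema every CLI
command resolves and writes next to its outputs, so any artifact can be
regenerated from its saved config and seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from PIL import Image

from .model import ModelConfig
from .preprocess import UMConfig
from .synth import CLASSES, SPLITS, DatasetManifest, SynthSpec
from .train import TrainConfig

__all__ = ["read_dataset_dir", "RunConfig"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def read_dataset_dir(root, splits=SPLITS) -> tuple[DatasetManifest, list[str]]:
    """Manifest plus a list of files that were present but failed to decode."""
    root = Path(root)
    rows, skipped = [], []
    for split in splits:
        split_dir = root / split
        if not split_dir.is_dir():
            raise FileNotFoundError(f"missing split directory: {split_dir}")
        for cls_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
            if cls_dir.name not in CLASSES:
                raise ValueError(
                    f"unknown class directory {cls_dir.name!r}; expected one of {CLASSES}"
                )
            for p in sorted(cls_dir.iterdir()):
                if p.suffix.lower() not in _IMAGE_SUFFIXES:
                    continue
                try:
                    with Image.open(p) as im:
                        im.verify()
                except Exception:
                    skipped.append(os.path.relpath(p, root))
                    continue
                rows.append(
                    {"path": os.path.relpath(p, root), "label": cls_dir.name, "split": split}
                )
    if not rows:
        raise ValueError(f"no decodable images under {root}")
    entries = pd.DataFrame(rows, columns=["path", "label", "split"])
    return DatasetManifest(entries=entries), skipped


@dataclass
class RunConfig:
    """Flat section-per-module configuration; CLI flags override file keys."""

    synth: SynthSpec = field(default_factory=SynthSpec)
    um: UMConfig = field(default_factory=UMConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "synth": dataclasses.asdict(self.synth),
            "um": dataclasses.asdict(self.um),
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            synth=SynthSpec(**d.get("synth", {})),
            um=UMConfig(**d.get("um", {})),
            model=ModelConfig(**d.get("model", {})),
            train=TrainConfig(**d.get("train", {})),
            out_dir=d.get("out_dir", "runs"),
            log_level=d.get("log_level", "INFO"),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
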