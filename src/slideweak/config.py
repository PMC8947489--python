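"""Run configuration: one YAML file driving every pipeline stage.

Defaults follow the two standard tiling configurations (20x magnification
with 512-px tiles, or 10x with 224-px tiles) and the training recipe
(k=8, N=256, batch 32, lr 1e-3 with 0.95 decay every 2 epochs, early stop
patience 10, mining switch patience 2, 1000 bootstrap iterations).
Synthetic fixtures use smaller tiles; every value is overridable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .sampling import MiningConfig
from .training import TrainConfig

#: the two standard magnification / tile-size pairings
STANDARD_TILE_CONFIGS = {"20x": 512, "10x": 224}


@dataclass
class SynthSection:
    n_pos: int = 5
    n_neg: int = 5
    image_size: int = 1024
    n_cores: int = 4
    core_shape: str = "needle"
    lesion_fraction: float = 0.3
    texture_contrast: float = 15.0
    background_level: int = 232
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)


@dataclass
class RunConfig:
    manifest: str = "manifest.csv"
    out_dir: str = "out"
    magnification: str = "20x"
    tile_size: int | None = None  # default: the standard size for the magnification
    stride: int | None = None  # default: tile_size (non-overlapping)
    min_tissue_frac: float = 0.1
    threshold: float = 0.5
    n_bootstrap: int = 1000
    seed: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    mining: MiningConfig = field(default_factory=MiningConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.tile_size is None:
            self.tile_size = STANDARD_TILE_CONFIGS.get(self.magnification, 512)

    @classmethod
    def from_yaml(cls, path: str | Path | None, **overrides) -> "RunConfig":
        raw: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("synth", SynthSection), ("mining", MiningConfig), ("train", TrainConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write_run_manifest(self, stage: str, out_dir: str | Path) -> Path:
        """Record config hash, seed and versions so a run is regenerable."""
        from . import __version__

        payload = {
            "stage": stage,
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "versions": {
                "slideweak": __version__,
                "numpy": np.__version__,
                "python": platform.python_version(),
            },
        }
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"run_{stage}.json"
        path.write_text(json.dumps(payload, indent=2))
        return path
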