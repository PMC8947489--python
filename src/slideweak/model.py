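"""High-level modelling interface.

``WeakSlideClassifier`` is built from a cohort manifest (slide images with
slide-level labels only); ``fit()`` runs the two-phase weakly-supervised
training loop and returns a ``WeakSlideResults`` object carrying the fitted
backbone, the epoch history, slide scoring, heatmap rendering, evaluation
with bootstrap CIs, and a text ``summary()``.

Example
-------
>>> model = WeakSlideClassifier.from_manifest("cohort/manifest.csv", tile_size=128)
>>> res = model.fit()
>>> print(res.summary())
>>> report = res.evaluate(split="test")
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import MetricReport, ScoredCohort, metric_report
from .inference import TileProbabilityMap, predict_tiles, render_heatmap, slide_score
from .nn import TinyCNN
from .sampling import MiningConfig
from .synthetic import load_image, read_manifest
from .tissue import build_tissue_mask, tile_grid
from .training import TrainConfig, TrainState, fit


class WeakSlideClassifier:
    """Weakly-supervised slide classifier over a cohort manifest."""

    def __init__(
        self,
        manifest: pd.DataFrame,
        tile_size: int = 128,
        stride: int | None = None,
        min_tissue_frac: float = 0.1,
        train_config: TrainConfig | None = None,
        mining_config: MiningConfig | None = None,
    ):
        self.manifest = manifest
        self.tile_size = tile_size
        self.stride = stride
        self.min_tissue_frac = min_tissue_frac
        self.train_config = train_config or TrainConfig()
        self.mining_config = mining_config or MiningConfig()

    @classmethod
    def from_manifest(cls, path: str | Path, **kwargs) -> "WeakSlideClassifier":
        return cls(read_manifest(path), **kwargs)

    def fit(self, validation_fn=None) -> "WeakSlideResults":
        backbone, state = fit(
            self.manifest,
            self.train_config,
            self.mining_config,
            tile_size=self.tile_size,
            stride=self.stride,
            min_tissue_frac=self.min_tissue_frac,
            validation_fn=validation_fn,
        )
        return WeakSlideResults(self, backbone, state)


class WeakSlideResults:
    """Fitted weakly-supervised slide classifier."""

    def __init__(self, model: WeakSlideClassifier, backbone: TinyCNN, state: TrainState):
        self.model = model
        self.backbone = backbone
        self.state = state

    # -- prediction ---------------------------------------------------------
    def predict_slide(self, image_path: str | Path, slide_id: str = "") -> TileProbabilityMap:
        """Tile probabilities over the tissue grid of one slide image."""
        image = load_image(image_path)
        mask = build_tissue_mask(image)
        grid = tile_grid(
            mask, self.model.tile_size, self.model.stride, self.model.min_tissue_frac, slide_id
        )
        return predict_tiles(self.backbone, image, grid, self.model.mining_config.batch_size)

    def score_slides(self, split: str = "test") -> ScoredCohort:
        """Max-aggregated slide scores for every slide of a split."""
        sub = self.model.manifest[self.model.manifest["split"] == split]
        if sub.empty:
            raise ValueError(f"no slides in split {split!r}")
        ids, labels, scores = [], [], []
        for row in sub.itertuples():
            pmap = self.predict_slide(row.image_path, row.slide_id)
            ids.append(row.slide_id)
            labels.append(1 if row.label == "adenocarcinoma" else 0)
            scores.append(slide_score(pmap))
        return ScoredCohort(ids, np.array(labels), np.array(scores))

    def heatmap(self, image_path: str | Path, slide_id: str = "", alpha: float = 0.5) -> np.ndarray:
        pmap = self.predict_slide(image_path, slide_id)
        return render_heatmap(pmap, load_image(image_path), alpha)

    # -- evaluation ---------------------------------------------------------
    def evaluate(
        self,
        split: str = "test",
        threshold: float = 0.5,
        n_bootstrap: int = 1000,
        seed: int = 0,
    ) -> MetricReport:
        return metric_report(self.score_slides(split), threshold, n_bootstrap, seed)

    def summary(self) -> str:
        s = self.state
        lines = [
            "Weakly-supervised slide classifier (tiny CNN backbone)",
            f"  epochs trained        : {s.epoch}",
            f"  mining switch at epoch: {s.switch_epoch}",
            f"  best validation loss  : {s.best_val:.4f} (epoch {s.best_epoch})",
            f"  tile size / stride    : {self.model.tile_size} / "
            f"{self.model.stride or self.model.tile_size}",
            "",
            f"  {'epoch':>5} {'phase':<16} {'train_loss':>10} {'val_loss':>9}",
        ]
        for e, (tl, vl, ph) in enumerate(zip(s.train_loss, s.val_loss, s.phase)):
            mark = " *" if e == s.best_epoch else ""
            lines.append(f"  {e:>5} {ph:<16} {tl:>10.4f} {vl:>9.4f}{mark}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.backbone.save(path)
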