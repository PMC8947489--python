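"""Sliding-window tile prediction, max-aggregated slide scoring, heatmaps.

A slide's prediction is the maximum positive-class probability over all its
tissue tiles: a slide is called positive if a single tile is confidently
positive, which matches how a pathologist needs only one carcinoma focus to
call a slide malignant.  Heatmaps paint each tile's probability onto the
slide with the jet colormap (blue = low, red = high).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tissue import TileRef

PREDICTION_COLUMNS = ["slide_id", "x", "y", "tile_size", "prob"]


@dataclass
class TileProbabilityMap:
    """Per-tile positive-class probabilities for one slide on a fixed grid."""

    slide_id: str
    tile_size: int
    stride: int
    tiles: list[TileRef]
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if len(self.tiles) != len(self.probs):
            raise ValueError("tiles and probs length mismatch")
        if len(self.probs) and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def items(self):
        return list(zip(self.tiles, self.probs))

    def __len__(self):
        return len(self.tiles)


def extract_tile(image: np.ndarray, tile: TileRef) -> np.ndarray:
    """Cut one tile as a float NCHW-slice input, gray rescaled to [-0.5, 0.5]."""
    t = tile.tile_size
    patch = image[tile.y : tile.y + t, tile.x : tile.x + t]
    if patch.shape[:2] != (t, t):
        raise ValueError(f"tile {tile} exceeds image bounds {image.shape}")
    if patch.ndim == 3:
        patch = patch.mean(axis=2)
    return patch.astype(np.float64) / 255.0 - 0.5


def predict_tiles(model, image: np.ndarray, grid: list[TileRef], batch_size: int = 32) -> TileProbabilityMap:
    """Score every tile of the grid with the model in evaluation mode.

    Evaluation mode uses the backbone's running normalization statistics,
    so the probabilities do not depend on how tiles are batched.
    """
    if not grid:
        raise ValueError("no tissue detected: empty tile grid")
    probs = np.empty(len(grid))
    for start in range(0, len(grid), batch_size):
        chunk = grid[start : start + batch_size]
        x = np.stack([extract_tile(image, t) for t in chunk])[:, None, :, :]
        probs[start : start + len(chunk)] = model.predict_proba(x)
    stride = grid[1].x - grid[0].x if len(grid) > 1 else grid[0].tile_size
    return TileProbabilityMap(
        slide_id=grid[0].slide_id,
        tile_size=grid[0].tile_size,
        stride=max(stride, 1),
        tiles=list(grid),
        probs=probs,
    )


def slide_score(pmap: TileProbabilityMap) -> float:
    """Slide prediction: the maximum over all tile probabilities."""
    if len(pmap) == 0:
        raise ValueError("empty tile probability map")
    return float(np.max(pmap.probs))


def jet_colormap(p: np.ndarray) -> np.ndarray:
    """Piecewise-linear jet (blue -> cyan -> yellow -> red), RGB in [0, 1]."""
    p = np.clip(np.asarray(p, dtype=np.float64), 0.0, 1.0)
    r = np.clip(1.5 - np.abs(4.0 * p - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * p - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * p - 1.0), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def render_heatmap(pmap: TileProbabilityMap, image: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend tile probabilities (jet colors) over the slide.

    Overlapping tile footprints average their probabilities for display;
    pixels outside every tile are returned bit-identical to the input.
    """
    if image.ndim == 2:
        rgb = np.stack([image] * 3, axis=-1)
    else:
        rgb = image[..., :3].copy()
    h, w = rgb.shape[:2]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for tile, p in zip(pmap.tiles, pmap.probs):
        t = tile.tile_size
        if tile.x < 0 or tile.y < 0 or tile.x + t > w or tile.y + t > h:
            raise ValueError(f"tile {tile} misaligned with image of shape {image.shape}")
        acc[tile.y : tile.y + t, tile.x : tile.x + t] += p
        cnt[tile.y : tile.y + t, tile.x : tile.x + t] += 1

    covered = cnt > 0
    mean_p = np.zeros((h, w))
    mean_p[covered] = acc[covered] / cnt[covered]
    colors = 255.0 * jet_colormap(mean_p)
    out = rgb.astype(np.float64)
    out[covered] = (1.0 - alpha) * out[covered] + alpha * colors[covered]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def write_predictions_tsv(pmap: TileProbabilityMap, path: str | Path) -> None:
    rows = [
        {"slide_id": t.slide_id, "x": t.x, "y": t.y, "tile_size": t.tile_size, "prob": p}
        for t, p in pmap.items()
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, sep="\t", index=False)
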