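"""Tissue detection by Otsu thresholding and tile-grid enumeration.

Slides sit on a near-white scanner background; tissue is darker.  A global
threshold chosen by Otsu's method on the grayscale image separates the two,
and square tiles are then enumerated over the tissue region in a sliding
window with a fixed stride.

Conventions (used everywhere in the package): pixel coordinates are
0-based with x growing right and y growing down; a tile occupies the
half-open box [x, x+T) x [y, y+T); tiles are ordered row-major (y, then x).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.morphology import remove_small_objects

#: ITU-R BT.601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])

TILE_COLUMNS = ["slide_id", "x", "y", "tile_size", "tissue_fraction"]


@dataclass(frozen=True)
class TileRef:
    """One square tile: slide, pixel origin, size and tissue coverage."""

    slide_id: str
    x: int
    y: int
    tile_size: int
    tissue_fraction: float


@dataclass
class TissueMask:
    """Binary tissue map plus the Otsu threshold that produced it."""

    mask: np.ndarray  # bool, same shape as the source image
    threshold: int  # tissue = gray < threshold

    @property
    def source_size(self) -> tuple[int, int]:
        return self.mask.shape


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to gray with BT.601 weights.

    Already-gray input is returned unchanged.
    """
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got {image.dtype}")
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        gray = image[..., :3].astype(np.float64) @ _LUMA
        return np.round(gray).astype(np.uint8)
    raise ValueError(f"unsupported image shape {image.shape}")


def otsu_threshold(gray: np.ndarray) -> int:
    """Threshold maximizing between-class variance on the 256-bin histogram.

    Pixels strictly below the returned level form the dark (tissue) class.
    All 255 candidate thresholds are evaluated; ties are broken by the
    lowest threshold.  A constant image has no valid split and raises.
    """
    if gray.dtype != np.uint8:
        raise ValueError("otsu_threshold expects an 8-bit grayscale image")
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 gray levels")

    # cum0[t] = pixels below t, i.e. class {0..t-1}, for t = 1..255
    w0 = np.cumsum(hist)[:-1]
    s0 = np.cumsum(hist * levels)[:-1]
    w1 = total - w0
    s1 = (hist * levels).sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, s1 / np.where(w1 > 0, w1, 1), 0.0)
    var_between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    # argmax returns the first (lowest) maximizer; index i is threshold i+1
    return int(np.argmax(var_between)) + 1


def build_tissue_mask(image: np.ndarray, min_object_size: int = 0) -> TissueMask:
    """Detect tissue: pixels darker than the Otsu threshold of the gray image.

    ``min_object_size`` optionally removes connected tissue components
    smaller than that many pixels (no other cleanup is applied).
    """
    gray = to_grayscale(image)
    threshold = otsu_threshold(gray)
    mask = gray < threshold
    if min_object_size > 0:
        mask = remove_small_objects(mask, min_size=min_object_size)
    return TissueMask(mask=mask, threshold=threshold)


def tile_grid(
    tmask: TissueMask,
    tile_size: int,
    stride: int | None = None,
    min_tissue_frac: float = 0.1,
    slide_id: str = "",
) -> list[TileRef]:
    """Enumerate tiles over tissue, row-major, at origins (i*stride, j*stride).

    Only tiles lying fully inside the image and covering at least
    ``min_tissue_frac`` tissue are emitted.  Default stride equals
    ``tile_size`` (non-overlapping grid).
    """
    h, w = tmask.mask.shape
    if tile_size > min(h, w):
        raise ValueError(f"tile_size {tile_size} exceeds image side {min(h, w)}")
    stride = tile_size if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")

    # summed-area table for O(1) per-tile tissue counts
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(tmask.mask, axis=0), axis=1, out=sat[1:, 1:])

    area = tile_size * tile_size
    tiles: list[TileRef] = []
    for y in range(0, h - tile_size + 1, stride):
        for x in range(0, w - tile_size + 1, stride):
            count = (
                sat[y + tile_size, x + tile_size]
                - sat[y, x + tile_size]
                - sat[y + tile_size, x]
                + sat[y, x]
            )
            frac = count / area
            if frac >= min_tissue_frac:
                tiles.append(TileRef(slide_id, x, y, tile_size, float(frac)))
    return tiles


def write_tile_tsv(tiles: list[TileRef], path: str | Path) -> None:
    pd.DataFrame([t.__dict__ for t in tiles], columns=TILE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_tile_tsv(path: str | Path) -> list[TileRef]:
    df = pd.read_csv(path, sep="\t", dtype={"slide_id": str})
    return [
        TileRef(str(r.slide_id), int(r.x), int(r.y), int(r.tile_size), float(r.tissue_fraction))
        for r in df.itertuples()
    ]
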