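"""Synthetic whole-slide images with planted lesions and weak labels.

Real prostate cohorts are needle-biopsy cores (long thin tissue strips) or
TUR-P chips (irregular blobs) on a near-white scanner background, labelled
only at the slide level.  This module emulates exactly those properties so
the full weakly-supervised pipeline — tissue masking, tile sampling, hard
mining, training, max-aggregated scoring — can be exercised and tested with
known ground truth.

Texture model
-------------
Benign tissue is Gaussian-smoothed white noise around a gray level ``g_b``
with a coarse correlation length; lesion tissue uses the same construction
around ``g_b - texture_contrast`` with a much shorter correlation length.
Per-pixel intensity histograms of the two textures overlap heavily, so a
single-pixel threshold cannot separate them reliably, while a small CNN
seeing a whole tile can.  Slide labels are the only supervision exposed to
training; ground-truth lesion masks are written alongside for evaluation
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

from ._rng import substream

MANIFEST_COLUMNS = [
    "slide_id",
    "image_path",
    "label",
    "magnification",
    "split",
    "lesion_mask_path",
]

#: gray-level drop from background to mean benign tissue
_TISSUE_DROP = 80.0
#: std of the smoothed texture noise, in gray levels
_NOISE_AMPLITUDE = 18.0
#: correlation lengths (gaussian sigma, px) of benign vs lesion texture
_SIGMA_BENIGN = 3.0
_SIGMA_LESION = 1.2
#: std of the background sensor noise
_BACKGROUND_NOISE = 1.0


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic slide (or a whole cohort).

    ``lesion_fraction`` is the fraction of tissue area carrying lesion
    texture; it must be 0 exactly when the slide label is benign.
    Identical params (seed included) produce bit-identical images.
    """

    image_size: int = 1024
    n_cores: int = 4
    core_shape: str = "needle"  # "needle" | "blob"
    lesion_fraction: float = 0.3
    texture_contrast: float = 15.0
    background_level: int = 232
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.core_shape not in ("needle", "blob"):
            raise ValueError(f"unknown core_shape {self.core_shape!r}")
        if self.n_cores < 1:
            raise ValueError("n_cores must be >= 1")


@dataclass
class SlideRecord:
    """One slide of a cohort manifest."""

    slide_id: str
    image_path: str
    label: str  # "adenocarcinoma" | "benign"
    magnification: str = "20x"  # "20x" | "10x"
    split: str = "train"  # "train" | "validation" | "test"
    lesion_mask_path: str = ""
    tissue_mask_path: str = field(default="", compare=False)

    @property
    def y(self) -> int:
        return 1 if self.label == "adenocarcinoma" else 0


def _draw_cores(params: SynthParams, rng: np.random.Generator) -> list[np.ndarray]:
    """Rasterize the tissue pieces; returns one boolean mask per core."""
    n = params.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cores = []
    for _ in range(params.n_cores):
        cy, cx = rng.uniform(0.2 * n, 0.8 * n, size=2)
        if params.core_shape == "needle":
            # long thin rotated rectangle, aspect ratio >= 8:1
            length = rng.uniform(0.55, 0.85) * n
            aspect = rng.uniform(8.0, 12.0)
            width = length / aspect
            theta = rng.uniform(0, np.pi)
            c, s = np.cos(theta), np.sin(theta)
            u = (xx - cx) * c + (yy - cy) * s
            v = -(xx - cx) * s + (yy - cy) * c
            cores.append((np.abs(u) <= length / 2) & (np.abs(v) <= width / 2))
        else:
            # TUR-P-like chip: union of overlapping discs
            blob = np.zeros((n, n), dtype=bool)
            r0 = rng.uniform(0.06, 0.10) * n
            for _ in range(5):
                dy, dx = rng.uniform(-0.6 * r0, 0.6 * r0, size=2)
                r = rng.uniform(0.6, 1.0) * r0
                blob |= (yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2 <= r**2
            cores.append(blob)
    return cores


def _texture(shape, mean, sigma, rng):
    """Gaussian-smoothed noise renormalized to _NOISE_AMPLITUDE std."""
    noise = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    noise /= noise.std()
    return mean + _NOISE_AMPLITUDE * noise


def _grow_lesion(
    cores: list[np.ndarray], tissue: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick a connected lesion region of exactly ``target`` tissue pixels.

    Grows radially from a seed pixel inside one core, spilling into further
    cores (nearest pixels first) only if a single core is too small.  The
    pixel count is exact by construction, so the planted fraction matches
    the request up to the integer rounding of ``target``.
    """
    n = tissue.shape[0]
    yy, xx = np.mgrid[0:n, 0:n]
    assigned = np.zeros_like(tissue)
    lesion = np.zeros_like(tissue)
    remaining = target
    order = rng.permutation(len(cores))
    for idx in order:
        if remaining <= 0:
            break
        core = cores[idx] & tissue & ~assigned
        assigned |= core
        if not core.any():
            continue
        pix = np.argwhere(core)
        cy, cx = pix[rng.integers(len(pix))]
        dist = (yy - cy) ** 2 + (xx - cx) ** 2
        flat = np.flatnonzero(core)
        # nearest-first, ties broken row-major for determinism
        take = flat[np.lexsort((flat, dist.ravel()[flat]))][:remaining]
        sel = np.zeros(n * n, dtype=bool)
        sel[take] = True
        lesion |= sel.reshape(n, n)
        remaining -= take.size
    return lesion


def generate_slide(
    params: SynthParams,
    label: str,
    out_dir: str | Path,
    slide_id: str = "slide",
    magnification: str = "20x",
    split: str = "train",
) -> SlideRecord:
    """Render one synthetic slide and write image + ground-truth masks.

    Writes ``<slide_id>.png`` (8-bit grayscale), ``<slide_id>_lesion.png``
    and ``<slide_id>_tissue.png`` (255 = foreground) into ``out_dir``.

    Raises ``ValueError`` if ``label`` contradicts ``lesion_fraction``
    (a benign slide must have lesion_fraction 0, and vice versa).
    """
    positive = label == "adenocarcinoma"
    if label not in ("adenocarcinoma", "benign"):
        raise ValueError(f"unknown label {label!r}")
    if (params.lesion_fraction > 0) != positive:
        raise ValueError(
            f"label {label!r} inconsistent with lesion_fraction={params.lesion_fraction}"
        )

    rng = substream(params.seed, "slide", slide_id)
    n = params.image_size
    cores = _draw_cores(params, rng)
    tissue = np.logical_or.reduce(cores)

    g_b = params.background_level - _TISSUE_DROP
    g_l = g_b - params.texture_contrast
    img = params.background_level + _BACKGROUND_NOISE * rng.standard_normal((n, n))
    benign_tex = _texture((n, n), g_b, _SIGMA_BENIGN, rng)
    img[tissue] = benign_tex[tissue]

    lesion = np.zeros_like(tissue)
    if positive:
        target = int(round(params.lesion_fraction * int(tissue.sum())))
        lesion = _grow_lesion(cores, tissue, target, rng)
        lesion_tex = _texture((n, n), g_l, _SIGMA_LESION, rng)
        img[lesion] = lesion_tex[lesion]

    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_path = out_dir / f"{slide_id}.png"
    lesion_path = out_dir / f"{slide_id}_lesion.png"
    tissue_path = out_dir / f"{slide_id}_tissue.png"
    Image.fromarray(img8).save(image_path)
    Image.fromarray((lesion * 255).astype(np.uint8)).save(lesion_path)
    Image.fromarray((tissue * 255).astype(np.uint8)).save(tissue_path)

    return SlideRecord(
        slide_id=slide_id,
        image_path=str(image_path),
        label=label,
        magnification=magnification,
        split=split,
        lesion_mask_path=str(lesion_path),
        tissue_mask_path=str(tissue_path),
    )


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n slides to (train, val, test)."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([base[i] - raw[i] for i in range(3)])  # largest remainder first
    for i in range(short):
        base[order[i]] += 1
    return base


def generate_cohort(
    n_pos: int,
    n_neg: int,
    params: SynthParams,
    out_dir: str | Path,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    magnification: str = "20x",
) -> pd.DataFrame:
    """Generate a labelled cohort and write images plus ``manifest.csv``.

    Splits are allocated per label by largest-remainder rounding so the
    label balance of each split matches the cohort's.  "10x" slides are
    rendered at half the linear resolution of "20x" ones (magnification is
    otherwise nominal metadata).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one slide of each label")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")

    size = params.image_size if magnification == "20x" else params.image_size // 2
    splits = ("train", "validation", "test")
    records: list[SlideRecord] = []
    rng = substream(params.seed, "cohort")
    for label, count in (("adenocarcinoma", n_pos), ("benign", n_neg)):
        counts = _split_counts(count, split_fractions)
        for frac, got in zip(split_fractions, counts):
            if frac > 0 and got == 0:
                warnings.warn(
                    f"split fraction {frac} of {count} {label} slides rounds to 0",
                    stacklevel=2,
                )
        assignment = sum(([s] * c for s, c in zip(splits, counts)), [])
        for i, split in enumerate(assignment):
            slide_id = f"{'pos' if label == 'adenocarcinoma' else 'neg'}{i:03d}"
            sp = replace(
                params,
                image_size=size,
                lesion_fraction=params.lesion_fraction if label == "adenocarcinoma" else 0.0,
                seed=int(rng.integers(2**31)),
            )
            records.append(
                generate_slide(sp, label, out_dir, slide_id, magnification, split)
            )

    manifest = pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "image_path": r.image_path,
                "label": r.label,
                "magnification": r.magnification,
                "split": r.split,
                "lesion_mask_path": r.lesion_mask_path,
            }
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB slide image as a numpy array."""
    arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return arr


def load_mask(path: str | Path) -> np.ndarray:
    """Read a ground-truth mask PNG (255 = foreground) as boolean."""
    return np.asarray(Image.open(path)) > 127
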