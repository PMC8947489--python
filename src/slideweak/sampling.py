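"""Balanced slide queue, balanced tile batches, and hard-example mining.

Training uses slide-level labels only.  Slides enter a shuffled queue that
alternates labels (positive, negative, ...); when one label runs out before
the other within an epoch, slides of the exhausted label are re-drawn with
replacement (oversampling) so the alternation — and hence batch balance —
is maintained and every slide contributes tiles each epoch.

Hard mining alternates inference and training: the frozen model scores each
slide's full tile grid, and the k most label-inconsistent tiles (highest
positive probability on negative slides, lowest on positive slides) enter a
FIFO pool; every time the pool holds N tiles they are released as a
training subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .tissue import TileRef


@dataclass(frozen=True)
class MiningConfig:
    """Hard-mining and batching configuration.

    Defaults are the standard configuration for this training scheme:
    k=8 mined tiles per slide, training triggered at N=256 pooled tiles,
    batches of 32 tiles, and the switch to mining after 2 epochs without
    validation improvement.
    """

    k: int = 8
    N: int = 256
    batch_size: int = 32
    num_labels: int = 2
    switch_patience: int = 2

    def __post_init__(self):
        if min(self.k, self.N, self.batch_size, self.num_labels, self.switch_patience) < 1:
            raise ValueError("all MiningConfig fields must be positive integers")
        if self.batch_size % self.num_labels:
            raise ValueError("batch_size must be divisible by num_labels")
        if self.k > self.N:
            raise ValueError("k must not exceed N")


@dataclass
class TileBatch:
    """A label-balanced training batch of tile references."""

    tiles: list[TileRef]
    labels: np.ndarray  # int, aligned with tiles

    def __len__(self):
        return len(self.tiles)


class SlideQueue:
    """Label-alternating shuffled queue over a cohort's training slides."""

    def __init__(self, pos_ids: list[str], neg_ids: list[str], seed: int):
        if not pos_ids or not neg_ids:
            raise ValueError("queue needs at least one slide of each label")
        self.pos_ids = list(pos_ids)
        self.neg_ids = list(neg_ids)
        self._rng = substream(seed, "slide-queue")
        self.epoch = 0
        self._pending: list[tuple[str, int]] = []
        self.cursor = 0

    def _plan_epoch(self) -> list[tuple[str, int]]:
        rng = self._rng
        pools = {
            1: list(rng.permutation(self.pos_ids)),
            0: list(rng.permutation(self.neg_ids)),
        }
        label = int(rng.integers(2))  # seeded starting label
        out: list[tuple[str, int]] = []
        remaining = {1: len(pools[1]), 0: len(pools[0])}
        while remaining[0] or remaining[1]:
            pool = pools[label]
            if remaining[label]:
                sid = pool[len(pool) - remaining[label]]
                remaining[label] -= 1
            else:
                # oversample the exhausted label to keep alternating
                full = self.pos_ids if label else self.neg_ids
                sid = full[rng.integers(len(full))]
            out.append((sid, label))
            label = 1 - label
        return out

    def next_slide(self) -> tuple[str, int]:
        """Return the next (slide_id, label), rolling epochs transparently."""
        if self.cursor >= len(self._pending):
            self._pending = self._plan_epoch()
            self.cursor = 0
            self.epoch += 1
        item = self._pending[self.cursor]
        self.cursor += 1
        return item

    def epoch_slides(self) -> list[tuple[str, int]]:
        """Plan and consume one full epoch of slide draws."""
        plan = self._plan_epoch()
        self.epoch += 1
        self._pending, self.cursor = [], 0
        return plan


def build_queue(manifest: pd.DataFrame, seed: int, split: str = "train") -> SlideQueue:
    """Build the alternating queue from a manifest's given split.

    Only slide ids and labels are consumed — lesion masks never reach the
    sampling stage.
    """
    sub = manifest[manifest["split"] == split]
    pos = sub.loc[sub["label"] == "adenocarcinoma", "slide_id"].tolist()
    neg = sub.loc[sub["label"] == "benign", "slide_id"].tolist()
    if not pos or not neg:
        raise ValueError(f"split {split!r} needs both labels (got {len(pos)} pos / {len(neg)} neg)")
    return SlideQueue(pos, neg, seed)


def _draw_tiles(pool: list[TileRef], n: int, rng: np.random.Generator) -> list[TileRef]:
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    else:  # oversample small slides with replacement
        idx = rng.integers(len(pool), size=n)
    return [pool[i] for i in idx]


def sample_balanced_batch(
    queue: SlideQueue,
    tile_pools: dict[str, list[TileRef]],
    cfg: MiningConfig,
    rng: np.random.Generator,
) -> TileBatch:
    """Draw one slide per label from the queue and batch_size/num_labels
    tiles from each, uniformly (with replacement only when a slide has
    fewer tiles than requested)."""
    per_slide = cfg.batch_size // cfg.num_labels
    chosen: dict[int, str] = {}
    attempts = 0
    while len(chosen) < cfg.num_labels:
        attempts += 1
        if attempts > 4 * (len(queue.pos_ids) + len(queue.neg_ids) + 2):
            raise ValueError("no slide with a non-empty tile pool for some label")
        sid, label = queue.next_slide()
        if label in chosen:
            continue
        if not tile_pools.get(sid):
            warnings.warn(f"slide {sid} has an empty tile pool; skipping", stacklevel=2)
            continue
        chosen[label] = sid

    tiles: list[TileRef] = []
    labels: list[int] = []
    for label in sorted(chosen, reverse=True):  # positives first, then negatives
        picked = _draw_tiles(tile_pools[chosen[label]], per_slide, rng)
        tiles.extend(picked)
        labels.extend([label] * per_slide)
    return TileBatch(tiles=tiles, labels=np.array(labels))


def select_hard_tiles(tile_probs, slide_label: int, k: int) -> list[TileRef]:
    """Pick the k tiles most inconsistent with the slide label.

    Negative slide: k highest positive-probability tiles; positive slide:
    k lowest.  Ties are broken by row-major tile order (y, then x).  If the
    map holds fewer than k tiles, all are returned.
    """
    entries = list(tile_probs.items())
    if not entries:
        raise ValueError("empty tile probability map")
    sign = 1.0 if slide_label == 1 else -1.0
    entries.sort(key=lambda tp: (sign * tp[1], tp[0].y, tp[0].x))
    return [t for t, _ in entries[:k]]


def should_switch_to_mining(val_loss_history: list[float], patience: int) -> bool:
    """True once the running-minimum validation loss is ``patience`` epochs
    stale (no strict improvement within the last ``patience`` epochs)."""
    if not val_loss_history:
        raise ValueError("empty validation history")
    best_epoch = int(np.argmin(val_loss_history))
    return best_epoch <= len(val_loss_history) - 1 - patience


class MiningPool:
    """FIFO accumulator of mined tiles, releasing exactly N per training run."""

    def __init__(self, N: int):
        self.N = N
        self.tiles: list[tuple[TileRef, int]] = []

    def update(self, selected: list[TileRef], label: int) -> list[tuple[TileRef, int]] | None:
        """Append mined tiles; return an N-tile training subset when full."""
        self.tiles.extend((t, label) for t in selected)
        if len(self.tiles) >= self.N:
            released, self.tiles = self.tiles[: self.N], self.tiles[self.N :]
            return released
        return None

    def __len__(self):
        return len(self.tiles)

    # -- resumable-training checkpoint --------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "N": self.N,
            "tiles": [[t.slide_id, t.x, t.y, t.tile_size, t.tissue_fraction, lab] for t, lab in self.tiles],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MiningPool":
        payload = json.loads(Path(path).read_text())
        pool = cls(payload["N"])
        pool.tiles = [
            (TileRef(sid, int(x), int(y), int(ts), float(tf)), int(lab))
            for sid, x, y, ts, tf, lab in payload["tiles"]
        ]
        return pool
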