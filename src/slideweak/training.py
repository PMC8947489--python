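"""Weakly-supervised training loop: partial fine-tuning, Adam with a
stepped learning-rate decay, balanced random sampling followed by
hard-example mining, and early stopping on validation loss.

The loop has two phases.  Phase 1 draws label-balanced tile batches from
the alternating slide queue (tiles inherit their slide's label).  Once the
validation loss stops improving for ``switch_patience`` epochs, the loop
switches — exactly once — to hard mining: the frozen model scores each
training slide's full tile grid, the k most label-inconsistent tiles per
slide enter a FIFO pool, and each time the pool reaches N tiles those are
trained on.  Training stops when the validation loss has not improved for
``early_stop_patience`` epochs, and the checkpoint with the lowest
validation loss is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .nn import Adam, Parameter, TinyCNN, bce_loss, sigmoid
from .sampling import (
    MiningConfig,
    MiningPool,
    build_queue,
    sample_balanced_batch,
    select_hard_tiles,
    should_switch_to_mining,
)
from .synthetic import load_image
from .tissue import TileRef, build_tissue_mask, tile_grid
from .inference import extract_tile, predict_tiles

_PARTIAL_KINDS = {"norm_scale", "norm_shift", "head_weight", "head_bias"}


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, schedule and stopping configuration.

    Defaults follow the standard recipe for this training scheme: Adam
    (beta1 0.9, beta2 0.999), initial learning rate 1e-3 decayed by 0.95
    every 2 epochs, binary cross-entropy loss, early stopping after 10
    epochs without validation improvement.
    """

    lr0: float = 0.001
    decay_factor: float = 0.95
    decay_every: int = 2
    beta1: float = 0.9
    beta2: float = 0.999
    early_stop_patience: int = 10
    max_epochs: int = 100
    backbone: str = "tiny_cnn"
    width: int = 8
    partial: bool = False
    pretrained: bool = False
    val_tiles_per_slide: int = 64
    seed: int = 0


@dataclass
class TrainState:
    """Per-epoch history of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)  # per epoch
    best_val: float = np.inf
    best_epoch: int = -1
    switch_epoch: int | None = None

    @property
    def epoch(self) -> int:
        return len(self.val_loss)


def lr_at_epoch(e: int, cfg: TrainConfig) -> float:
    """Stepped decay: lr0 * decay_factor ** floor(e / decay_every), e 0-based."""
    if e < 0:
        raise ValueError("epoch index must be >= 0")
    return cfg.lr0 * cfg.decay_factor ** (e // cfg.decay_every)


def trainable_parameter_mask(model, partial: bool) -> set[str]:
    """Names of the parameters to train.

    Partial fine-tuning trains only the normalization scale/shift and the
    final classification layer; full mode trains everything.
    """
    params: list[Parameter] = model.parameters()
    if not partial:
        return {p.name for p in params}
    names = {p.name for p in params if p.kind in _PARTIAL_KINDS}
    if not any(p.kind in ("norm_scale", "norm_shift") for p in params):
        raise ValueError("partial fine-tuning requires a backbone with normalization layers")
    return names


def apply_trainable_mask(model, names: set[str]) -> None:
    for p in model.parameters():
        p.trainable = p.name in names


def build_backbone(cfg: TrainConfig) -> TinyCNN:
    if cfg.backbone != "tiny_cnn":
        raise NotImplementedError(
            f"backbone {cfg.backbone!r}: only the tiny_cnn reference backbone ships with this package"
        )
    return TinyCNN(in_channels=1, width=cfg.width, seed=cfg.seed)


class _SlideStore:
    """In-memory images + tile grids for the slides of one or more splits.

    Tissue masks come from Otsu on the images themselves — ground-truth
    lesion masks are never read here, preserving weak supervision.
    """

    def __init__(self, manifest: pd.DataFrame, tile_size: int, stride: int | None, min_tissue_frac: float):
        self.images: dict[str, np.ndarray] = {}
        self.grids: dict[str, list[TileRef]] = {}
        self.labels: dict[str, int] = {}
        for row in manifest.itertuples():
            img = load_image(row.image_path)
            mask = build_tissue_mask(img)
            self.images[row.slide_id] = img
            self.grids[row.slide_id] = tile_grid(
                mask, tile_size, stride, min_tissue_frac, slide_id=row.slide_id
            )
            self.labels[row.slide_id] = 1 if row.label == "adenocarcinoma" else 0

    def batch_array(self, tiles: list[TileRef]) -> np.ndarray:
        return np.stack([extract_tile(self.images[t.slide_id], t) for t in tiles])[:, None, :, :]


def _train_step(model, optimizer, x, y, lr) -> float:
    logit = model.forward(x, training=True)
    p = sigmoid(logit)
    loss = bce_loss(p, y)
    model.backward((p - y) / len(y))
    optimizer.step(lr)
    return loss


def validation_loss(model, store: _SlideStore, val_tiles: list[TileRef], batch_size: int = 32) -> float:
    """Mean BCE over a fixed tile sample of the validation slides."""
    losses = []
    for start in range(0, len(val_tiles), batch_size):
        chunk = val_tiles[start : start + batch_size]
        x = store.batch_array(chunk)
        y = np.array([store.labels[t.slide_id] for t in chunk], dtype=np.float64)
        p = model.predict_proba(x)
        losses.append(bce_loss(p, y) * len(chunk))
    return float(np.sum(losses) / len(val_tiles))


def _fixed_validation_sample(store: _SlideStore, ids: list[str], per_slide: int, seed: int) -> list[TileRef]:
    rng = substream(seed, "validation-tiles")
    out: list[TileRef] = []
    for sid in sorted(ids):
        pool = store.grids[sid]
        if not pool:
            continue
        take = min(per_slide, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out


def fit(
    manifest: pd.DataFrame,
    cfg: TrainConfig,
    mining: MiningConfig | None = None,
    tile_size: int = 128,
    stride: int | None = None,
    min_tissue_frac: float = 0.1,
    validation_fn=None,
    model: TinyCNN | None = None,
) -> tuple[TinyCNN, TrainState]:
    """Run the full two-phase weakly-supervised training loop.

    ``validation_fn(model, epoch) -> loss`` may replace the tile-based
    validation evaluator (used for stopping-rule tests); by default the
    loss is computed on a fixed seeded tile sample of the validation split.
    Returns the model restored to its lowest-validation-loss checkpoint,
    plus the epoch history.
    """
    mining = mining or MiningConfig()
    train_df = manifest[manifest["split"] == "train"]
    val_df = manifest[manifest["split"] == "validation"]
    if validation_fn is None and val_df.empty:
        raise ValueError("empty validation split: both stopping rules depend on it")
    if train_df.empty:
        raise ValueError("empty training split")

    store = _SlideStore(pd.concat([train_df, val_df]), tile_size, stride, min_tissue_frac)
    queue = build_queue(manifest, cfg.seed)
    rng = substream(cfg.seed, "tile-sampling")

    if model is None:
        model = build_backbone(cfg)
    apply_trainable_mask(model, trainable_parameter_mask(model, cfg.partial))
    optimizer = Adam([p for p in model.parameters() if p.trainable], cfg.beta1, cfg.beta2)

    val_tiles = (
        _fixed_validation_sample(store, val_df["slide_id"].tolist(), cfg.val_tiles_per_slide, cfg.seed)
        if validation_fn is None
        else []
    )

    state = TrainState()
    best_state_dict = model.state_dict()
    phase = "random_sampling"
    pool = MiningPool(mining.N)
    pairs_per_epoch = max(
        len(queue.pos_ids), len(queue.neg_ids)
    )  # one alternation cycle over the longer label list

    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg)
        epoch_losses: list[float] = []

        if phase == "random_sampling":
            for _ in range(pairs_per_epoch):
                batch = sample_balanced_batch(queue, store.grids, mining, rng)
                x = store.batch_array(batch.tiles)
                y = batch.labels.astype(np.float64)
                epoch_losses.append(_train_step(model, optimizer, x, y, lr))
        else:
            # alternate inference (frozen weights) and training
            for sid, label in queue.epoch_slides():
                grid = store.grids[sid]
                if not grid:
                    continue
                pmap = predict_tiles(model, store.images[sid], grid, mining.batch_size)
                released = pool.update(select_hard_tiles(pmap, label, mining.k), label)
                if released is not None:
                    for start in range(0, len(released), mining.batch_size):
                        chunk = released[start : start + mining.batch_size]
                        x = store.batch_array([t for t, _ in chunk])
                        y = np.array([lab for _, lab in chunk], dtype=np.float64)
                        epoch_losses.append(_train_step(model, optimizer, x, y, lr))

        if validation_fn is not None:
            vloss = float(validation_fn(model, epoch))
        else:
            vloss = validation_loss(model, store, val_tiles, mining.batch_size)

        state.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        state.val_loss.append(vloss)
        state.phase.append(phase)
        if vloss < state.best_val:
            state.best_val = vloss
            state.best_epoch = epoch
            best_state_dict = model.state_dict()

        if phase == "random_sampling" and should_switch_to_mining(
            state.val_loss, mining.switch_patience
        ):
            phase = "hard_mining"
            state.switch_epoch = epoch + 1

        if epoch - state.best_epoch >= cfg.early_stop_patience:
            break

    model.load_state_dict(best_state_dict)
    return model, state
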