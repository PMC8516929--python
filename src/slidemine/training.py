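"""Two-phase training: balanced random sampling, then hard mining of tiles.

Phase 1 trains on label-balanced batches drawn from the per-slide tile pools.
Once the validation loss has not improved for ``switch_patience`` consecutive
epochs, training switches — exactly once — into hard mining: the current
model is applied in a sliding-window fashion over all tissue regions of each
training slide, and the k tiles the model gets most wrong relative to the
slide label (highest-scoring tiles on negative slides, lowest-scoring on
positive ones) are accumulated into a subset. Whenever the subset reaches N
tiles it is flushed: trained on in arrival order in batches of
``batch_size``, then cleared. Training stops when the validation loss has
not improved for ``stop_patience`` epochs, and the weights snapshot with the
lowest validation loss is the final model.

The optimizer is Adam (beta1=0.9, beta2=0.999) with a learning-rate decay of
0.95 every 2 epochs; epochs are counted globally across both phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import load_tiles, score_tiles
from .models import Adam, TileCNN, bce_loss
from .sampling import BalancedBatch, TilePool, balanced_batch_stream
from .slide_io import LabeledSlide, TileRef
from .tissue import detect_tissue, enumerate_tiles

__all__ = [
    "OptimizerConfig",
    "HardMiningConfig",
    "HardMiningState",
    "learning_rate",
    "select_hard_tiles",
    "train_phase1",
    "train_phase2",
    "fit",
    "draw_validation_tiles",
]

logger = logging.getLogger("slidemine.training")


@dataclass
class OptimizerConfig:
    """Adam schedule. ``initial_lr`` is 0.001 from scratch, 0.0001 fine-tuning."""

    beta1: float = 0.9
    beta2: float = 0.999
    initial_lr: float = 0.001
    lr_decay: float = 0.95
    decay_every: int = 2
    batch_size: int = 32

    def validate(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.initial_lr <= 0 or self.lr_decay <= 0 or self.batch_size < 1:
            raise ValueError("optimizer parameters must be positive")


@dataclass
class HardMiningConfig:
    """Hard-mining and early-stopping parameters (k=16, N=256 defaults)."""

    k: int = 16
    subset_size: int = 256
    switch_patience: int = 2
    stop_patience: int = 10
    max_phase1_epochs: int = 50
    max_phase2_epochs: int = 100

    def validate(self) -> None:
        if self.k < 1 or self.subset_size < self.k:
            raise ValueError("need k >= 1 and subset_size >= k")
        if self.switch_patience < 1 or self.stop_patience < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class HardMiningState:
    """Mutable training-loop state shared between the two phases."""

    phase: str = "random_balanced"
    subset: list[tuple[TileRef, int]] = field(default_factory=list)
    best_val_loss: float = np.inf
    epochs_since_improvement: int = 0
    epoch: int = 0  # global 1-based epoch counter, shared across phases
    best_state: dict | None = None
    history: list[dict] = field(default_factory=list)

    def record(self, **kwargs) -> None:
        entry = {"phase": self.phase, "epoch": self.epoch, **kwargs}
        self.history.append(entry)
        logger.info(
            "epoch=%d phase=%s %s",
            self.epoch,
            self.phase,
            " ".join(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}" for k, v in kwargs.items()),
        )


def learning_rate(opt: OptimizerConfig, epoch: int) -> float:
    """lr(e) = lr0 * decay^floor(e / decay_every) for 1-based epoch e.

    The decay applies at epochs 2, 4, ... so epoch 4 with lr0=0.001 trains at
    0.001 * 0.95**2.
    """
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return opt.initial_lr * opt.lr_decay ** (epoch // opt.decay_every)


def select_hard_tiles(
    tile_probs: list[tuple[TileRef, float]], slide_label: int, k: int
) -> list[TileRef]:
    """The k tiles the model scores worst relative to the slide label.

    Negative slides keep their k highest-probability tiles (false-positive
    candidates), positive slides their k lowest. Ties preserve the input
    (row-major) order; if fewer than k tiles exist all are returned.
    """
    if not tile_probs:
        raise ValueError("tile_probs must be nonempty")
    probs = np.array([p for _, p in tile_probs], dtype=np.float64)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    key = -probs if slide_label == 0 else probs
    order = np.argsort(key, kind="stable")
    return [tile_probs[i][0] for i in order[:k]]


# ---------------------------------------------------------------------------
# batch training helpers
# ---------------------------------------------------------------------------


class _Trainer:
    """Drives one model through mini-batch updates.

    Works with :class:`TileCNN` (Adam on the partial fine-tuning mask) or any
    stub exposing ``train_batch(X, y, lr) -> loss`` for contract tests.
    """

    def __init__(self, model, opt: OptimizerConfig):
        self.model = model
        self.opt_cfg = opt
        self.adam = (
            Adam(model, beta1=opt.beta1, beta2=opt.beta2)
            if isinstance(model, TileCNN)
            else None
        )

    def step(self, rasters: np.ndarray, labels: np.ndarray, lr: float) -> float:
        if self.adam is None:
            return float(self.model.train_batch(rasters, labels, lr))
        probs, cache = self.model.forward(rasters, training=True)
        loss = bce_loss(probs, labels)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss {loss}; aborting (lr={lr})"
            )
        grads = self.model.backward(cache, labels)
        self.adam.step(grads, lr)
        return loss


def _validation_loss(model, val_tiles: np.ndarray, val_labels: np.ndarray) -> float:
    probs = np.asarray(model.predict_proba(val_tiles), dtype=np.float64)
    return bce_loss(probs, val_labels)


def _snapshot(model) -> dict | None:
    return model.snapshot() if hasattr(model, "snapshot") else None


def draw_validation_tiles(
    val_pools: list[TilePool],
    slides: dict[str, LabeledSlide],
    n_tiles: int = 256,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed, label-balanced validation tile sample (drawn once, seeded)."""
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[tuple[str, TileRef]]] = {}
    for pool in val_pools:
        for t in pool.tiles:
            by_label.setdefault(pool.y, []).append((pool.slide_id, t))
    rasters, labels = [], []
    per_label = max(n_tiles // max(len(by_label), 1), 1)
    for y, entries in sorted(by_label.items()):
        idx = rng.choice(len(entries), size=min(per_label, len(entries)), replace=False)
        for i in idx:
            sid, tile = entries[i]
            rasters.append(load_tiles(slides[sid].slide, [tile])[0])
            labels.append(y)
    return np.stack(rasters), np.array(labels)


# ---------------------------------------------------------------------------
# phase 1: fully-random balanced sampling
# ---------------------------------------------------------------------------


def _epoch_batches(stream) -> "list[BalancedBatch]":
    """Yield lists of batches, one list per streamed epoch."""
    current = 0
    buf: list[BalancedBatch] = []
    for batch in stream:
        if batch.epoch != current:
            yield buf
            buf = []
            current = batch.epoch
        buf.append(batch)


def train_phase1(
    model,
    pools: list[TilePool],
    slides: dict[str, LabeledSlide],
    opt: OptimizerConfig,
    val_tiles: np.ndarray,
    val_labels: np.ndarray,
    cfg: HardMiningConfig,
    seed: int = 0,
    state: HardMiningState | None = None,
) -> HardMiningState:
    """Balanced-sampling phase; exits into hard mining on validation plateau.

    Trains with binary cross-entropy on tile labels inherited from the slide.
    The validation loss is evaluated each epoch; after ``switch_patience``
    consecutive epochs without improvement the state switches (once) to the
    hard-mining phase.
    """
    opt.validate()
    cfg.validate()
    if not pools or val_tiles.shape[0] == 0:
        raise ValueError("phase 1 needs nonempty pools and validation tiles")
    state = state or HardMiningState()
    trainer = _Trainer(model, opt)
    stream = balanced_batch_stream(pools, opt.batch_size, seed=seed)
    for batches in _epoch_batches(stream):
        state.epoch += 1
        lr = learning_rate(opt, state.epoch)
        losses = []
        for batch in batches:
            rasters = np.stack(
                [load_tiles(slides[t.slide_id].slide, [t])[0] for t, _ in batch.tiles]
            )
            labels = np.array([y for _, y in batch.tiles])
            losses.append(trainer.step(rasters, labels, lr))
        val_loss = _validation_loss(model, val_tiles, val_labels)
        state.record(train_loss=float(np.mean(losses)), val_loss=val_loss, lr=lr)
        if val_loss < state.best_val_loss - 1e-9:
            state.best_val_loss = val_loss
            state.epochs_since_improvement = 0
            state.best_state = _snapshot(model)
        else:
            state.epochs_since_improvement += 1
        if state.epochs_since_improvement >= cfg.switch_patience:
            break
        if state.epoch >= cfg.max_phase1_epochs:
            logger.warning("phase 1 hit max_phase1_epochs without plateau")
            break
    state.phase = "hard_mining"
    state.epochs_since_improvement = 0
    return state


# ---------------------------------------------------------------------------
# phase 2: hard mining of tiles
# ---------------------------------------------------------------------------


def _flush_subset(
    trainer: _Trainer,
    subset: list[tuple[TileRef, int]],
    slides: dict[str, LabeledSlide],
    opt: OptimizerConfig,
    lr: float,
) -> list[float]:
    """Train on the accumulated subset in arrival order, batch by batch."""
    losses = []
    for start in range(0, len(subset), opt.batch_size):
        chunk = subset[start : start + opt.batch_size]
        rasters = np.stack(
            [load_tiles(slides[t.slide_id].slide, [t])[0] for t, _ in chunk]
        )
        labels = np.array([y for _, y in chunk])
        losses.append(trainer.step(rasters, labels, lr))
    return losses


def train_phase2(
    model,
    train_slides: list[LabeledSlide],
    slides: dict[str, LabeledSlide],
    opt: OptimizerConfig,
    val_tiles: np.ndarray,
    val_labels: np.ndarray,
    cfg: HardMiningConfig,
    magnification: float,
    tile_size: int,
    stride: int | None = None,
    min_tissue_fraction: float = 0.25,
    working_downsample: int = 32,
    seed: int = 0,
    state: HardMiningState | None = None,
    tissue_tiles: dict[str, list[TileRef]] | None = None,
) -> HardMiningState:
    """Hard-mining phase alternating sliding-window inference and training.

    One epoch is a full pass over all training slides in a shuffled order.
    Sliding-window inference covers all tissue regions of each slide —
    including annotated positives — and the selected hard tiles accumulate in
    a subset that is trained on and cleared whenever it reaches ``subset_size``.
    A partial subset persists across epochs (it stays strictly below
    ``subset_size`` between flushes). Returns the state with the best-weights
    snapshot restored into the model.
    """
    opt.validate()
    cfg.validate()
    if not train_slides:
        raise ValueError("phase 2 needs at least one training slide")
    state = state or HardMiningState(phase="hard_mining")
    if state.phase != "hard_mining":
        raise ValueError("phase 2 requires state.phase == 'hard_mining'")
    rng = np.random.default_rng(seed)
    trainer = _Trainer(model, opt)
    stride = stride or tile_size

    if tissue_tiles is None:
        tissue_tiles = {}
    for ls in train_slides:
        if ls.slide_id not in tissue_tiles:
            mask = detect_tissue(ls.slide, working_downsample)
            tissue_tiles[ls.slide_id] = enumerate_tiles(
                mask, ls.slide, magnification, tile_size, stride, min_tissue_fraction
            )

    stop_epochs = 0
    while stop_epochs < cfg.max_phase2_epochs:
        state.epoch += 1
        stop_epochs += 1
        lr = learning_rate(opt, state.epoch)
        order = rng.permutation(len(train_slides))
        losses: list[float] = []
        n_flushes = 0
        for si in order:
            ls = train_slides[si]
            tiles = tissue_tiles[ls.slide_id]
            if not tiles:
                continue
            probs = score_tiles(ls.slide, model, tiles)
            hard = select_hard_tiles(list(zip(tiles, probs)), ls.y, cfg.k)
            state.subset.extend((t, ls.y) for t in hard)
            if len(state.subset) >= cfg.subset_size:
                losses.extend(_flush_subset(trainer, state.subset, slides, opt, lr))
                state.subset = []
                n_flushes += 1
        val_loss = _validation_loss(model, val_tiles, val_labels)
        state.record(
            train_loss=float(np.mean(losses)) if losses else float("nan"),
            val_loss=val_loss,
            lr=lr,
            flushes=n_flushes,
        )
        if val_loss < state.best_val_loss - 1e-9:
            state.best_val_loss = val_loss
            state.epochs_since_improvement = 0
            state.best_state = _snapshot(model)
        else:
            state.epochs_since_improvement += 1
        if state.epochs_since_improvement >= cfg.stop_patience:
            break
    if state.best_state is not None and hasattr(model, "load_state_dict"):
        model.load_state_dict(state.best_state)
    return state


# ---------------------------------------------------------------------------
# end-to-end fit
# ---------------------------------------------------------------------------


def fit(
    model,
    train_slides: list[LabeledSlide],
    val_slides: list[LabeledSlide],
    opt: OptimizerConfig,
    cfg: HardMiningConfig,
    magnification: float,
    tile_size: int,
    stride: int | None = None,
    min_tissue_fraction: float = 0.25,
    working_downsample: int = 32,
    n_val_tiles: int = 256,
    seed: int = 0,
) -> HardMiningState:
    """Run both phases end to end and return the final state.

    Tile pools follow the annotation rules (annotation-restricted positives,
    whole-tissue otherwise); the validation loss is tracked on a fixed,
    seeded tile sample from the validation slides.
    """
    from .sampling import build_pool

    slides = {ls.slide_id: ls for ls in [*train_slides, *val_slides]}
    pools = [
        build_pool(
            ls, tile_size, magnification,
            working_downsample=working_downsample,
            min_tissue_fraction=min_tissue_fraction,
            stride_px=stride,
        )
        for ls in train_slides
    ]
    val_pools = [
        build_pool(
            ls, tile_size, magnification,
            working_downsample=working_downsample,
            min_tissue_fraction=min_tissue_fraction,
            stride_px=stride,
        )
        for ls in val_slides
    ]
    val_tiles, val_labels = draw_validation_tiles(
        val_pools, slides, n_tiles=n_val_tiles, seed=seed
    )
    state = train_phase1(
        model, pools, slides, opt, val_tiles, val_labels, cfg, seed=seed
    )
    state = train_phase2(
        model,
        train_slides,
        slides,
        opt,
        val_tiles,
        val_labels,
        cfg,
        magnification,
        tile_size,
        stride,
        min_tissue_fraction,
        working_downsample,
        seed=seed + 1,
        state=state,
    )
    return state
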