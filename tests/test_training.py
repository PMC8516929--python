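"""Two-phase training loop: schedules, patience, hard mining, snapshots."""

import numpy as np
import pytest

from slidemine.models import TileCNN
from slidemine.sampling import TilePool
from slidemine.slide_io import LabeledSlide, AnnotationSet, SlideImage, TileRef
from slidemine.training import (
    HardMiningConfig,
    HardMiningState,
    OptimizerConfig,
    learning_rate,
    select_hard_tiles,
    train_phase1,
    train_phase2,
)


class StubModel:
    """Constant scorer that records training calls; for loop contracts."""

    def __init__(self, prob=0.5, loss=0.7):
        self.prob = prob
        self.loss = loss
        self.batch_sizes = []
        self.restored = None

    def predict_proba(self, x):
        return np.full(len(x), self.prob)

    def train_batch(self, x, y, lr):
        self.batch_sizes.append(len(x))
        return self.loss

    def snapshot(self):
        return {"n_batches": len(self.batch_sizes)}

    def load_state_dict(self, state):
        self.restored = dict(state)


def _flat_slide(sid, value):
    base = np.full((128, 128, 3), value, dtype=np.uint8)
    return SlideImage([base], [1], 0.5, 20.0, sid)


def _cohort(n_pos=2, n_neg=2, tile=16, tiles_per_slide=16):
    """Flat dark positives vs flat light negatives with ready-made pools."""
    slides, pools = {}, []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        sid = f"s{i}"
        value = 90 if positive else 200
        ls = LabeledSlide(
            _flat_slide(sid, value), AnnotationSet(), "positive" if positive else "negative"
        )
        slides[sid] = ls
        refs = [
            TileRef(sid, 20.0, tile * (j % 7), tile * (j // 7), tile)
            for j in range(tiles_per_slide)
        ]
        pools.append(TilePool(sid, ls.label, refs, "whole_tissue"))
    return slides, pools


def _val_data(tile=16, n=8):
    rng = np.random.default_rng(0)
    dark = rng.integers(80, 100, (n // 2, tile, tile, 3)).astype(np.uint8)
    light = rng.integers(190, 210, (n // 2, tile, tile, 3)).astype(np.uint8)
    return np.concatenate([dark, light]), np.array([1] * (n // 2) + [0] * (n // 2))


class TestSchedule:
    def test_learning_rate_closed_form(self):
        opt = OptimizerConfig(initial_lr=0.001)
        assert learning_rate(opt, 1) == pytest.approx(0.001)
        assert learning_rate(opt, 2) == pytest.approx(0.001 * 0.95)
        assert learning_rate(opt, 4) == pytest.approx(0.001 * 0.95**2)
        assert learning_rate(opt, 5) == pytest.approx(0.001 * 0.95**2)

    def test_schedule_is_non_increasing(self):
        opt = OptimizerConfig()
        lrs = [learning_rate(opt, e) for e in range(1, 40)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_paper_defaults(self):
        opt = OptimizerConfig()
        cfg = HardMiningConfig()
        assert (opt.beta1, opt.beta2, opt.batch_size) == (0.9, 0.999, 32)
        assert (cfg.k, cfg.subset_size) == (16, 256)
        assert (cfg.switch_patience, cfg.stop_patience) == (2, 10)


class TestSelectHardTiles:
    def _refs(self, probs):
        return [(TileRef("s", 10.0, i, 0, 8), p) for i, p in enumerate(probs)]

    def test_negative_slide_takes_highest_probabilities(self):
        picked = select_hard_tiles(self._refs([0.1, 0.9, 0.5, 0.7]), 0, k=2)
        assert [t.x for t in picked] == [1, 3]

    def test_positive_slide_takes_lowest_probabilities(self):
        picked = select_hard_tiles(self._refs([0.1, 0.9, 0.5, 0.7]), 1, k=2)
        assert [t.x for t in picked] == [0, 2]

    def test_short_list_returns_all(self):
        picked = select_hard_tiles(self._refs([0.3, 0.4]), 0, k=16)
        assert len(picked) == 2

    def test_ties_preserve_row_major_order(self):
        picked = select_hard_tiles(self._refs([0.5, 0.5, 0.5, 0.5]), 0, k=2)
        assert [t.x for t in picked] == [0, 1]

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(100):
            probs = rng.random(1000)
            refs = self._refs(probs)
            label = int(rng.integers(0, 2))
            got = [t.x for t in select_hard_tiles(refs, label, k=16)]
            reverse = label == 0
            want = [
                i
                for i, _ in sorted(
                    enumerate(probs),
                    key=lambda ip: (-ip[1] if reverse else ip[1], ip[0]),
                )[:16]
            ]
            assert got == want

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            select_hard_tiles(self._refs([0.5, 1.5]), 0, 1)


class TestPhase1:
    def test_constant_validation_loss_switches_after_patience(self):
        slides, pools = _cohort()
        stub = StubModel(prob=0.5)
        val_x, val_y = _val_data()
        state = train_phase1(
            stub, pools, slides, OptimizerConfig(batch_size=4),
            val_x, val_y, HardMiningConfig(switch_patience=2), seed=0,
        )
        # first epoch improves on +inf; then exactly 2 plateau epochs
        assert state.phase == "hard_mining"
        assert state.epoch == 3
        assert [h["phase"] for h in state.history] == ["random_balanced"] * 3

    def test_training_loss_falls_on_separable_cohort(self):
        slides, pools = _cohort(tiles_per_slide=32)
        model = TileCNN(16, (4,), seed=1)
        val_x, val_y = _val_data()
        state = train_phase1(
            model, pools, slides, OptimizerConfig(batch_size=8, initial_lr=0.01),
            val_x, val_y,
            HardMiningConfig(switch_patience=10, max_phase1_epochs=3), seed=0,
        )
        losses = [h["train_loss"] for h in state.history]
        assert len(losses) == 3
        assert losses[2] < losses[0]

    def test_epoch_counter_and_lr_recorded(self):
        slides, pools = _cohort()
        stub = StubModel()
        val_x, val_y = _val_data()
        state = train_phase1(
            stub, pools, slides, OptimizerConfig(batch_size=4),
            val_x, val_y, HardMiningConfig(), seed=0,
        )
        assert [h["epoch"] for h in state.history] == list(
            range(1, state.epoch + 1)
        )
        opt = OptimizerConfig(batch_size=4)
        for h in state.history:
            assert h["lr"] == pytest.approx(learning_rate(opt, h["epoch"]))


def _phase2_setup(n_slides=20, tiles_per_slide=30):
    slides = {}
    train = []
    tissue_tiles = {}
    for i in range(n_slides):
        sid = f"s{i}"
        positive = i % 2 == 0
        ls = LabeledSlide(
            _flat_slide(sid, 90 if positive else 200),
            AnnotationSet(),
            "positive" if positive else "negative",
        )
        slides[sid] = ls
        train.append(ls)
        tissue_tiles[sid] = [
            TileRef(sid, 20.0, 16 * (j % 7), 16 * (j // 7), 16)
            for j in range(tiles_per_slide)
        ]
    return slides, train, tissue_tiles


class TestPhase2:
    def test_subset_flushes_every_sixteen_slides(self):
        # k=16, N=256 -> a flush every 256/16 = 16 slides
        slides, train, tissue_tiles = _phase2_setup(n_slides=20)
        stub = StubModel()
        val_x, val_y = _val_data()
        state = train_phase2(
            stub, train, slides, OptimizerConfig(),
            val_x, val_y,
            HardMiningConfig(stop_patience=10, max_phase2_epochs=1),
            magnification=20.0, tile_size=16, seed=0,
            state=HardMiningState(phase="hard_mining"),
            tissue_tiles=tissue_tiles,
        )
        assert state.history[-1]["flushes"] == 1
        # 20 slides x 16 tiles = 320; one flush of 256 leaves 64 pending
        assert len(state.subset) == 64
        # the flush trained in arrival-order batches of 32
        assert stub.batch_sizes == [32] * 8

    def test_constant_loss_stops_after_patience_and_restores_best(self):
        slides, train, tissue_tiles = _phase2_setup(n_slides=4, tiles_per_slide=20)
        stub = StubModel(prob=0.5)
        val_x, val_y = _val_data()
        state = train_phase2(
            stub, train, slides, OptimizerConfig(),
            val_x, val_y, HardMiningConfig(stop_patience=10),
            magnification=20.0, tile_size=16, seed=0,
            state=HardMiningState(phase="hard_mining"),
            tissue_tiles=tissue_tiles,
        )
        # epoch 1 improves on +inf, then 10 plateau epochs
        assert state.epoch == 11
        assert state.epochs_since_improvement == 10
        # best snapshot (end of epoch 1: 4 slides x k=16 = 64 tiles, no flush
        # yet) restored into the model
        assert stub.restored == {"n_batches": 0}

    def test_subset_stays_below_capacity_between_flushes(self):
        slides, train, tissue_tiles = _phase2_setup(n_slides=7, tiles_per_slide=25)
        stub = StubModel()
        val_x, val_y = _val_data()
        state = train_phase2(
            stub, train, slides, OptimizerConfig(),
            val_x, val_y,
            HardMiningConfig(stop_patience=2, max_phase2_epochs=6),
            magnification=20.0, tile_size=16, seed=0,
            state=HardMiningState(phase="hard_mining"),
            tissue_tiles=tissue_tiles,
        )
        assert len(state.subset) < 256

    def test_phase_flag_must_be_hard_mining(self):
        slides, train, tissue_tiles = _phase2_setup(n_slides=2)
        with pytest.raises(ValueError):
            train_phase2(
                StubModel(), train, slides, OptimizerConfig(),
                *_val_data(), HardMiningConfig(),
                magnification=20.0, tile_size=16,
                state=HardMiningState(phase="random_balanced"),
                tissue_tiles=tissue_tiles,
            )

    def test_empty_slide_list_rejected(self):
        with pytest.raises(ValueError):
            train_phase2(
                StubModel(), [], {}, OptimizerConfig(),
                *_val_data(), HardMiningConfig(),
                magnification=20.0, tile_size=16,
            )
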