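"""Balanced queue, balanced batches, hard-tile selection, mining pool."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slideweak.inference import TileProbabilityMap
from slideweak.sampling import (
    MiningConfig,
    MiningPool,
    SlideQueue,
    build_queue,
    sample_balanced_batch,
    select_hard_tiles,
    should_switch_to_mining,
)
from slideweak.tissue import TileRef


def make_pmap(probs_by_xy, slide_id="s", tile_size=16):
    tiles = [TileRef(slide_id, x, y, tile_size, 1.0) for (x, y) in probs_by_xy]
    probs = np.array(list(probs_by_xy.values()))
    return TileProbabilityMap(slide_id, tile_size, tile_size, tiles, probs)


class TestMiningConfig:
    def test_defaults_match_standard_recipe(self):
        cfg = MiningConfig()
        assert (cfg.k, cfg.N, cfg.batch_size, cfg.switch_patience) == (8, 256, 32, 2)

    @pytest.mark.parametrize(
        "kwargs", [dict(batch_size=33), dict(k=300), dict(k=0), dict(batch_size=0)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MiningConfig(**kwargs)


class TestSlideQueue:
    def test_emission_alternates_labels(self):
        q = SlideQueue(["p1", "p2"], ["n1", "n2"], seed=0)
        labels = [q.next_slide()[1] for _ in range(8)]
        for a, b in zip(labels, labels[1:3]):
            assert a != b
        # alternation holds within each epoch of 4 draws
        assert labels[:2] in ([0, 1], [1, 0])

    def test_minority_label_is_oversampled(self):
        q = SlideQueue(["p1", "p2", "p3"], ["n1"], seed=1)
        plan = q.epoch_slides()
        pos = [s for s, lab in plan if lab == 1]
        neg = [s for s, lab in plan if lab == 0]
        assert sorted(set(pos)) == ["p1", "p2", "p3"]
        assert set(neg) == {"n1"} and len(neg) >= len(pos) - 1  # redrawn to alternate
        labels = [lab for _, lab in plan]
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_same_seed_same_order(self):
        a = SlideQueue(["p1", "p2"], ["n1", "n2"], seed=5)
        b = SlideQueue(["p1", "p2"], ["n1", "n2"], seed=5)
        assert [a.next_slide() for _ in range(12)] == [b.next_slide() for _ in range(12)]

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            SlideQueue(["p1"], [], seed=0)

    def test_build_queue_requires_both_labels(self, small_cohort):
        q = build_queue(small_cohort, seed=0)
        assert len(q.pos_ids) == 3 and len(q.neg_ids) == 3
        single = small_cohort[small_cohort["label"] == "benign"]
        with pytest.raises(ValueError, match="both labels"):
            build_queue(single, seed=0)


def _pools(n_tiles_by_slide):
    return {
        sid: [TileRef(sid, 16 * i, 0, 16, 1.0) for i in range(n)]
        for sid, n in n_tiles_by_slide.items()
    }


class TestBalancedBatch:
    def test_batch_is_exactly_label_balanced(self, rng):
        q = SlideQueue(["p1", "p2"], ["n1", "n2"], seed=0)
        pools = _pools({"p1": 30, "p2": 30, "n1": 30, "n2": 30})
        batch = sample_balanced_batch(q, pools, MiningConfig(), rng)
        assert len(batch) == 32
        assert (batch.labels == 1).sum() == 16
        assert (batch.labels == 0).sum() == 16
        # per-slide contribution is batch_size / num_labels
        by_slide = {}
        for t in batch.tiles:
            by_slide[t.slide_id] = by_slide.get(t.slide_id, 0) + 1
        assert set(by_slide.values()) == {16}

    def test_tiny_slide_oversampled_with_replacement(self, rng):
        q = SlideQueue(["p1"], ["n1"], seed=0)
        pools = _pools({"p1": 1, "n1": 40})
        batch = sample_balanced_batch(q, pools, MiningConfig(), rng)
        pos_tiles = [t for t, lab in zip(batch.tiles, batch.labels) if lab == 1]
        assert len(pos_tiles) == 16
        assert len({(t.x, t.y) for t in pos_tiles}) == 1  # same tile repeated

    def test_every_slide_contributes_each_epoch(self, rng):
        ids_p, ids_n = [f"p{i}" for i in range(4)], [f"n{i}" for i in range(4)]
        q = SlideQueue(ids_p, ids_n, seed=3)
        pools = _pools({sid: 20 for sid in ids_p + ids_n})
        seen = set()
        for _ in range(4):  # one epoch = 4 alternation cycles at 4+4 slides
            batch = sample_balanced_batch(q, pools, MiningConfig(), rng)
            seen.update(t.slide_id for t in batch.tiles)
        assert seen == set(ids_p + ids_n)

    def test_empty_pool_slide_skipped_with_warning(self, rng):
        q = SlideQueue(["p1", "p2"], ["n1"], seed=0)
        pools = _pools({"p1": 0, "p2": 10, "n1": 10})
        with pytest.warns(UserWarning, match="empty tile pool"):
            for _ in range(4):
                batch = sample_balanced_batch(q, pools, MiningConfig(), rng)
                assert all(t.slide_id != "p1" for t in batch.tiles)

    def test_all_pools_of_a_label_empty_raises(self, rng):
        q = SlideQueue(["p1"], ["n1"], seed=0)
        pools = _pools({"p1": 0, "n1": 10})
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="non-empty tile pool"):
            sample_balanced_batch(q, pools, MiningConfig(), rng)


def brute_force_hard_tiles(items, slide_label, k):
    """Full-sort oracle with row-major tie-break."""
    sign = 1.0 if slide_label == 1 else -1.0
    return [t for t, _ in sorted(items, key=lambda tp: (sign * tp[1], tp[0].y, tp[0].x))][:k]


class TestHardTiles:
    def test_negative_slide_takes_highest_probabilities(self):
        pmap = make_pmap({(0, 0): 0.9, (16, 0): 0.2, (32, 0): 0.5})
        picked = select_hard_tiles(pmap, slide_label=0, k=2)
        assert [(t.x, t.y) for t in picked] == [(0, 0), (32, 0)]

    def test_positive_slide_takes_lowest_probabilities(self):
        pmap = make_pmap({(0, 0): 0.9, (16, 0): 0.2, (32, 0): 0.5})
        picked = select_hard_tiles(pmap, slide_label=1, k=2)
        assert [(t.x, t.y) for t in picked] == [(16, 0), (32, 0)]

    def test_k_at_least_tile_count_returns_all(self):
        pmap = make_pmap({(0, 0): 0.9, (16, 0): 0.2})
        assert len(select_hard_tiles(pmap, 0, k=10)) == 2

    def test_empty_map_raises(self):
        pmap = make_pmap({})
        with pytest.raises(ValueError, match="empty"):
            select_hard_tiles(pmap, 0, 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    def test_matches_full_sort_oracle_with_ties(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        # coarse probabilities force ties; shuffled grid order exercises the
        # row-major tie-break
        xs = rng.permutation(n)
        tiles = [TileRef("s", int(x) * 16, int(rng.integers(4)) * 16, 16, 1.0) for x in xs]
        probs = rng.integers(0, 4, size=n) / 3.0
        pmap = TileProbabilityMap("s", 16, 16, tiles, probs)
        label = int(rng.integers(2))
        assert select_hard_tiles(pmap, label, k) == brute_force_hard_tiles(
            list(zip(tiles, probs)), label, k
        )


class TestMiningSwitch:
    @pytest.mark.parametrize(
        "history,patience,expected",
        [
            ([0.9, 0.8, 0.7], 2, False),
            ([0.9, 0.8, 0.81, 0.82], 2, True),
            ([0.9], 2, False),
            ([0.9, 0.9, 0.9], 2, True),  # never improved since epoch 0
            ([0.5, 0.6, 0.4, 0.45, 0.46], 2, True),
        ],
    )
    def test_switch_rule(self, history, patience, expected):
        assert should_switch_to_mining(history, patience) is expected

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            should_switch_to_mining([], 2)


class TestMiningPool:
    def test_release_at_capacity_is_fifo(self):
        pool = MiningPool(N=256)
        first = [TileRef("a", i, 0, 16, 1.0) for i in range(250)]
        assert pool.update(first, 1) is None
        assert len(pool) == 250
        released = pool.update([TileRef("b", i, 0, 16, 1.0) for i in range(8)], 0)
        assert released is not None and len(released) == 256
        assert len(pool) == 2
        # FIFO: the 250 earlier tiles lead, then 6 of the new ones
        assert [t.slide_id for t, _ in released] == ["a"] * 250 + ["b"] * 6
        assert [t.slide_id for t, _ in pool.tiles] == ["b", "b"]

    def test_below_capacity_not_ready(self):
        pool = MiningPool(N=256)
        assert pool.update([TileRef("a", 0, 0, 16, 1.0)] * 8, 1) is None

    def test_releases_partition_stream_in_order(self):
        pool = MiningPool(N=10)
        stream = [TileRef("s", i, 0, 16, 1.0) for i in range(35)]
        out = []
        for i in range(0, 35, 5):
            rel = pool.update(stream[i : i + 5], 1)
            if rel:
                out.extend(rel)
        assert [t.x for t, _ in out] == list(range(30))

    def test_json_roundtrip(self, tmp_path):
        pool = MiningPool(N=16)
        pool.update([TileRef("s", 0, 16, 16, 0.5)], 1)
        pool.to_json(tmp_path / "pool.json")
        back = MiningPool.from_json(tmp_path / "pool.json")
        assert back.N == 16 and back.tiles == pool.tiles
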