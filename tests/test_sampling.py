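"""Annotation sampling rules, pool construction, and balanced streaming."""

import itertools

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon, box

from slidemine.sampling import (
    EmptyPoolError,
    TilePool,
    balanced_batch_stream,
    build_pool,
    tiles_from_annotation,
)
from slidemine.slide_io import LabeledSlide, TileRef


DIMS = (1000, 1000)


def square(cx, cy, side):
    h = side / 2
    return Polygon([(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)])


class TestTilesFromAnnotation:
    def test_small_annotation_gives_one_centred_tile(self):
        poly = square(300, 400, 50)
        tiles = tiles_from_annotation(poly, DIMS, 224, 20.0, 20.0)
        assert len(tiles) == 1
        t = tiles[0]
        # tile centre coincides with the bounding-box centre
        assert t.x + 112 == 300 and t.y + 112 == 400

    def test_exactly_tile_sized_annotation_is_boundary_inclusive(self):
        poly = square(500, 500, 224)
        tiles = tiles_from_annotation(poly, DIMS, 224, 20.0, 20.0)
        assert len(tiles) == 1
        assert (tiles[0].x, tiles[0].y) == (388, 388)

    def test_centred_tile_clamped_near_slide_edge(self):
        poly = square(30, 30, 40)
        tiles = tiles_from_annotation(poly, DIMS, 224, 20.0, 20.0)
        assert tiles == [TileRef("", 20.0, 0, 0, 224)]

    def test_large_annotation_matches_brute_force_grid(self, rng):
        """Overlapping-grid path vs an independent grid + intersection scan."""
        for _ in range(25):
            cx, cy = rng.uniform(300, 700, size=2)
            r = rng.uniform(150, 320)
            poly = Point(cx, cy).buffer(r, quad_segs=16)
            size, stride = 224, 112
            got = tiles_from_annotation(poly, DIMS, size, 20.0, 20.0)
            minx, miny, maxx, maxy = poly.bounds
            want = set()
            y = int(miny)
            while y < maxy:
                x = int(minx)
                while x < maxx:
                    xi = int(min(max(x, 0), DIMS[0] - size))
                    yi = int(min(max(y, 0), DIMS[1] - size))
                    if box(xi, yi, xi + size, yi + size).intersects(poly):
                        want.add((xi, yi))
                    x += stride
                y += stride
            assert {(t.x, t.y) for t in got} == want

    def test_magnification_scaling_halves_coordinates(self):
        poly = square(400, 600, 60)  # base-level (x20) coordinates
        tiles = tiles_from_annotation(poly, (500, 500), 64, 10.0, 20.0)
        assert len(tiles) == 1
        assert tiles[0].x + 32 == 200 and tiles[0].y + 32 == 300

    def test_polygon_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            tiles_from_annotation(square(990, 990, 100), DIMS, 64, 20.0, 20.0)


class TestBuildPool:
    def test_positive_slide_uses_annotation_restricted_source(self, pos_result):
        pool = build_pool(
            pos_result.as_labeled_slide(), 64, 10.0,
            working_downsample=8, min_tissue_fraction=0.25,
        )
        assert pool.source == "annotation_restricted"
        # two lesion blobs smaller than the tile -> one centred tile each
        assert len(pool.tiles) == 2

    def test_every_annotation_tile_intersects_a_polygon(self, pos_result):
        ls = pos_result.as_labeled_slide()
        pool = build_pool(ls, 32, 10.0, working_downsample=8)
        scaled = [
            affinity.scale(p, 0.5, 0.5, origin=(0, 0))
            for p, _ in ls.annotations.polygons
        ]
        for t in pool.tiles:
            tile_geom = box(t.x, t.y, t.x + t.size_px, t.y + t.size_px)
            assert any(tile_geom.intersects(p) for p in scaled)

    def test_negative_slide_uses_whole_tissue_grid(self, neg_result):
        pool = build_pool(
            neg_result.as_labeled_slide(), 64, 10.0,
            working_downsample=8, min_tissue_fraction=0.25,
        )
        assert pool.source == "whole_tissue"
        assert len(pool.tiles) > 2

    def test_overlapping_polygons_deduplicated(self, pos_result):
        from slidemine.slide_io import AnnotationSet

        ls = pos_result.as_labeled_slide()
        # duplicate every polygon: the pool must not change
        doubled = LabeledSlide(
            ls.slide, AnnotationSet(ls.annotations.polygons * 2), ls.label
        )
        pool = build_pool(doubled, 64, 10.0, working_downsample=8)
        assert len({(t.x, t.y) for t in pool.tiles}) == len(pool.tiles)
        assert len(pool.tiles) == 2


def _fake_pool(sid, label, n_tiles):
    tiles = [TileRef(sid, 10.0, 64 * i, 0, 64) for i in range(n_tiles)]
    return TilePool(sid, label, tiles, "whole_tissue")


class TestBalancedBatchStream:
    def test_every_batch_is_exactly_balanced(self):
        pools = [
            _fake_pool("p1", "positive", 30),
            _fake_pool("p2", "positive", 5),
            _fake_pool("n1", "negative", 40),
        ]
        stream = balanced_batch_stream(pools, 32, seed=3)
        for batch in itertools.islice(stream, 10_000):
            labels = [y for _, y in batch.tiles]
            assert len(labels) == 32
            assert sum(labels) == 16

    def test_scarce_label_recycles_within_epoch(self):
        pools = [
            _fake_pool("p1", "positive", 10),
            _fake_pool("p2", "positive", 10),
            _fake_pool("p3", "positive", 10),
            _fake_pool("n1", "negative", 10),
        ]
        stream = balanced_batch_stream(pools, 8, seed=0)
        drawn_neg = 0
        for batch in stream:
            sids = {t.slide_id for t, _ in batch.tiles}
            if "n1" in sids:
                drawn_neg += 1
            if batch.epoch > 0:
                break
        assert drawn_neg >= 3

    def test_epoch_covers_every_slide(self):
        pools = [_fake_pool(f"p{i}", "positive", 8) for i in range(5)] + [
            _fake_pool(f"n{i}", "negative", 8) for i in range(3)
        ]
        stream = balanced_batch_stream(pools, 4, seed=1)
        drawn = set()
        for batch in stream:
            if batch.epoch > 0:
                break
            drawn.update(t.slide_id for t, _ in batch.tiles)
        assert drawn == {p.slide_id for p in pools}

    def test_fixed_seed_reproduces_batch_sequence(self):
        pools = [_fake_pool("p", "positive", 20), _fake_pool("n", "negative", 20)]
        a = list(itertools.islice(balanced_batch_stream(pools, 8, seed=9), 50))
        b = list(itertools.islice(balanced_batch_stream(pools, 8, seed=9), 50))
        for ba, bb in zip(a, b):
            assert [(t.x, t.y, y) for t, y in ba.tiles] == [
                (t.x, t.y, y) for t, y in bb.tiles
            ]

    def test_small_pool_oversampled_with_replacement(self):
        pools = [_fake_pool("p", "positive", 2), _fake_pool("n", "negative", 40)]
        batch = next(balanced_batch_stream(pools, 32, seed=0))
        pos_tiles = [t for t, y in batch.tiles if y == 1]
        assert len(pos_tiles) == 16
        assert len({(t.x, t.y) for t in pos_tiles}) <= 2

    def test_missing_label_category_rejected(self):
        with pytest.raises(ValueError):
            next(balanced_batch_stream([_fake_pool("p", "positive", 5)], 32))

    def test_indivisible_batch_size_rejected(self):
        pools = [_fake_pool("p", "positive", 5), _fake_pool("n", "negative", 5)]
        with pytest.raises(ValueError):
            next(balanced_batch_stream(pools, 33))
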