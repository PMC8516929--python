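"""Per-slide tile pools and label-balanced batch streaming.

Positive training slides carry free-hand lesion annotations, and tiles are
sampled only from the annotated regions: an annotation smaller than the tile
is represented by a single tile centred on it, a larger one by an overlapping
grid of tiles. Unannotated slides contribute their entire tissue area.

Batches are balanced by looping over the label categories in succession over
per-label shuffled queues of slides; each drawn slide contributes
``batch_size / num_labels`` tiles of its own label. Slides of the scarcer
label are recycled (over-sampled) so that an epoch — defined as the point at
which every slide has been drawn at least once — always covers the full
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon, box

from .slide_io import LabeledSlide, TileRef, binary_label
from .tissue import TissueMask, detect_tissue, enumerate_tiles

__all__ = [
    "TilePool",
    "BalancedBatch",
    "tiles_from_annotation",
    "build_pool",
    "balanced_batch_stream",
    "EmptyPoolError",
]


class EmptyPoolError(ValueError):
    """Annotated slide whose annotations yield no tiles (inconsistent truth)."""


@dataclass
class TilePool:
    """All candidate training tiles of one slide."""

    slide_id: str
    label: str
    tiles: list[TileRef]
    source: str  # "annotation_restricted" | "whole_tissue"

    @property
    def y(self) -> int:
        return binary_label(self.label)


@dataclass
class BalancedBatch:
    """One training batch with exact per-label balance."""

    tiles: list[tuple[TileRef, int]]
    epoch: int


def tiles_from_annotation(
    polygon: Polygon,
    slide_dims: tuple[int, int],
    size_px: int,
    magnification: float,
    base_magnification: float,
) -> list[TileRef]:
    """Tiles representing one annotation polygon at the working magnification.

    The polygon is given in base-level coordinates. If its bounding box fits
    within one tile, a single tile centred on the bounding-box centre is
    returned (clamped in-bounds). Otherwise tiles are laid on an overlapping
    grid with stride ``size_px // 2`` over the bounding box and those
    intersecting the polygon are kept, in row-major order.
    """
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    w, h = slide_dims
    r = magnification / base_magnification
    poly = affinity.scale(polygon, xfact=r, yfact=r, origin=(0, 0)) if r != 1 else polygon
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > w or maxy > h:
        raise ValueError(f"annotation bounds {poly.bounds} outside slide {w}x{h}")

    def clamp(v: float, hi: int) -> int:
        return int(min(max(v, 0), max(hi - size_px, 0)))

    if (maxx - minx) <= size_px and (maxy - miny) <= size_px:
        cx = (minx + maxx) / 2.0
        cy = (miny + maxy) / 2.0
        x = clamp(round(cx - size_px / 2.0), w)
        y = clamp(round(cy - size_px / 2.0), h)
        return [TileRef("", magnification, x, y, size_px)]

    stride = max(size_px // 2, 1)
    x0, y0 = int(minx), int(miny)
    out = []
    y = y0
    while y < maxy:
        x = x0
        while x < maxx:
            xi, yi = clamp(x, w), clamp(y, h)
            tile_geom = box(xi, yi, xi + size_px, yi + size_px)
            if tile_geom.intersects(poly):
                out.append(TileRef("", magnification, xi, yi, size_px))
            x += stride
        y += stride
    # clamping near edges can duplicate positions; keep first occurrence
    seen: set[tuple[int, int]] = set()
    uniq = []
    for t in out:
        if (t.x, t.y) not in seen:
            seen.add((t.x, t.y))
            uniq.append(t)
    return uniq


def build_pool(
    slide: LabeledSlide,
    size_px: int,
    magnification: float,
    working_downsample: int = 32,
    min_tissue_fraction: float = 0.25,
    stride_px: int | None = None,
    tissue_mask: TissueMask | None = None,
) -> TilePool:
    """Candidate-tile pool for one slide.

    Annotated slides are restricted to their annotations (union over polygons,
    deduplicated by position); unannotated slides use the whole detected
    tissue area. ``tissue_mask`` may be supplied to reuse a cached detection.
    """
    sid = slide.slide_id
    dims = slide.slide.dimensions_at(magnification)
    if slide.annotations:
        tiles: list[TileRef] = []
        seen: set[tuple[int, int]] = set()
        for poly, _ in slide.annotations.polygons:
            for t in tiles_from_annotation(
                poly, dims, size_px, magnification, slide.slide.base_magnification
            ):
                if (t.x, t.y) not in seen:
                    seen.add((t.x, t.y))
                    tiles.append(TileRef(sid, magnification, t.x, t.y, size_px))
        if not tiles:
            raise EmptyPoolError(f"annotated slide {sid} produced no tiles")
        return TilePool(sid, slide.label, tiles, "annotation_restricted")
    mask = tissue_mask if tissue_mask is not None else detect_tissue(slide.slide, working_downsample)
    tiles = enumerate_tiles(
        mask, slide.slide, magnification, size_px, stride_px, min_tissue_fraction
    )
    return TilePool(sid, slide.label, tiles, "whole_tissue")


def balanced_batch_stream(
    pools: list[TilePool], batch_size: int, seed: int = 0
) -> Iterator[BalancedBatch]:
    """Infinite stream of balanced batches over a shuffled slide queue.

    Each batch draws one slide per label category (labels in a fixed,
    alternating order) and samples ``batch_size / num_labels`` tiles from it —
    uniformly without replacement when the pool is large enough, with
    replacement otherwise. Per-label queues reshuffle when exhausted, so
    scarce labels are over-sampled. ``BalancedBatch.epoch`` increments once
    every slide has been drawn at least once.
    """
    by_label: dict[int, list[TilePool]] = {}
    for p in pools:
        by_label.setdefault(p.y, []).append(p)
    if len(by_label) < 2:
        raise ValueError("balanced streaming needs pools for every label category")
    labels = sorted(by_label)
    if batch_size % len(labels) != 0:
        raise ValueError("batch_size must be divisible by the number of labels")
    per_label = batch_size // len(labels)
    rng = np.random.default_rng(seed)

    queues: dict[int, list[int]] = {y: [] for y in labels}
    all_ids = {p.slide_id for p in pools}
    drawn: set[str] = set()
    epoch = 0
    while True:
        batch: list[tuple[TileRef, int]] = []
        for y in labels:
            if not queues[y]:
                order = rng.permutation(len(by_label[y]))
                queues[y] = list(order)
            pool = by_label[y][queues[y].pop()]
            drawn.add(pool.slide_id)
            n = len(pool.tiles)
            replace = n < per_label
            idx = rng.choice(n, size=per_label, replace=replace)
            batch.extend((pool.tiles[i], y) for i in idx)
        yield BalancedBatch(batch, epoch)
        if drawn >= all_ids:
            epoch += 1
            drawn = set()
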