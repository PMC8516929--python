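"""Sliding-window heatmap inference and slide-level probability aggregation.

A trained tile scorer is applied in a sliding-window fashion over all tissue
tiles of a slide, producing a probability grid (heatmap). The slide-level
probability is the maximum over valid cells. For the two-stage workflow the
slide probability of the second-stage model is multiplied with an externally
supplied first-stage probability:

    P(diffuse-type ADC) = P2(diffuse-type ADC | ADC) * P1(ADC)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .slide_io import SlideImage, TileRef, read_tile
from .tissue import TissueMask, detect_tissue, enumerate_tiles

__all__ = [
    "HeatmapResult",
    "score_tiles",
    "predict_heatmap",
    "slide_probability",
    "two_stage_probability",
    "render_overlay",
]


@dataclass
class HeatmapResult:
    """Grid of per-tile probabilities with a tissue-validity mask.

    ``grid[i, j]`` is the probability of the tile whose top-left corner is
    ``(j * stride, i * stride)`` on the pixel grid of ``magnification``;
    cells without tissue are marked invalid and carry NaN.
    """

    slide_id: str
    magnification: float
    tile_size_px: int
    stride_px: int
    grid: np.ndarray
    valid: np.ndarray
    origin_px: tuple[int, int] = (0, 0)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_probabilities(self) -> np.ndarray:
        return self.grid[self.valid]

    def tiles(self) -> list[TileRef]:
        """Valid tiles in row-major order."""
        out = []
        for i, j in zip(*np.nonzero(self.valid)):
            out.append(
                TileRef(
                    self.slide_id,
                    self.magnification,
                    int(j) * self.stride_px + self.origin_px[0],
                    int(i) * self.stride_px + self.origin_px[1],
                    self.tile_size_px,
                )
            )
        return out


def load_tiles(slide: SlideImage, tiles: list[TileRef]) -> np.ndarray:
    """Stack tile rasters into a (n, size, size, 3) uint8 array."""
    if not tiles:
        size = 0
        return np.empty((0, size, size, 3), dtype=np.uint8)
    return np.stack([read_tile(slide, t) for t in tiles])


def score_tiles(slide: SlideImage, model, tiles: list[TileRef]) -> np.ndarray:
    """Per-tile probabilities from any scorer exposing ``predict_proba``."""
    if not tiles:
        return np.empty(0)
    rasters = load_tiles(slide, tiles)
    probs = np.asarray(model.predict_proba(rasters), dtype=np.float64)
    return probs


def predict_heatmap(
    slide: SlideImage,
    model,
    magnification: float,
    tile_size: int,
    stride: int | None = None,
    tissue_mask: TissueMask | None = None,
    min_tissue_fraction: float = 0.25,
    working_downsample: int = 32,
) -> HeatmapResult:
    """Sliding-window probability heatmap over all tissue regions.

    The tile grid is the one produced by :func:`slidemine.tissue.enumerate_tiles`;
    the output grid covers the full slide at the working magnification, with
    non-tissue cells invalid. Deterministic given the model weights.
    """
    stride = stride or tile_size
    mask = tissue_mask if tissue_mask is not None else detect_tissue(slide, working_downsample)
    tiles = enumerate_tiles(
        mask, slide, magnification, tile_size, stride, min_tissue_fraction
    )
    w, h = slide.dimensions_at(magnification)
    nx = max((w - tile_size) // stride + 1, 0)
    ny = max((h - tile_size) // stride + 1, 0)
    grid = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    if not tiles:
        warnings.warn(f"slide {slide.slide_id}: no tissue tiles; empty heatmap")
        return HeatmapResult(slide.slide_id, magnification, tile_size, stride, grid, valid)
    probs = score_tiles(slide, model, tiles)
    for t, p in zip(tiles, probs):
        grid[t.y // stride, t.x // stride] = p
        valid[t.y // stride, t.x // stride] = True
    return HeatmapResult(slide.slide_id, magnification, tile_size, stride, grid, valid)


def slide_probability(heatmap: HeatmapResult) -> float:
    """Slide-level probability: the maximum over valid heatmap cells."""
    if heatmap.n_valid == 0:
        raise ValueError(f"heatmap of {heatmap.slide_id} has no valid cells")
    return float(np.max(heatmap.grid[heatmap.valid]))


def two_stage_probability(p1: float, p2: float) -> float:
    """Product rule combining stage-1 P(ADC) with stage-2 P(diffuse | ADC)."""
    if not (0.0 <= p1 <= 1.0) or not (0.0 <= p2 <= 1.0):
        raise ValueError(f"probabilities must lie in [0, 1]; got {p1}, {p2}")
    return p1 * p2


def render_overlay(
    slide: SlideImage,
    heatmap: HeatmapResult,
    out_uri: str | Path,
    downsample: int | None = None,
    colormap: str = "jet",
    max_alpha: float = 0.6,
) -> Path:
    """Write a PNG of the slide thumbnail with a probability overlay.

    Each valid heatmap cell is drawn as a colour-mapped square whose opacity
    scales with the probability, so p=0 cells are fully transparent and p=1
    cells show the colormap endpoint at ``max_alpha``.
    """
    from matplotlib import colormaps

    if downsample is None:
        # aim for a thumbnail around 1024 px on the long side
        w, h = slide.base_shape
        downsample = max(1, 2 ** int(np.floor(np.log2(max(w, h) / 1024))) if max(w, h) > 1024 else 1)
    thumb = slide.thumbnail(downsample).astype(np.float64)
    cmap = colormaps[colormap]
    # heatmap-grid -> thumbnail scale
    scale = slide.downsample_for(heatmap.magnification) / downsample
    overlay = thumb.copy()
    for i, j in zip(*np.nonzero(heatmap.valid)):
        p = float(heatmap.grid[i, j])
        x0 = int((j * heatmap.stride_px + heatmap.origin_px[0]) * scale)
        y0 = int((i * heatmap.stride_px + heatmap.origin_px[1]) * scale)
        side = max(int(round(heatmap.tile_size_px * scale)), 1)
        x1 = min(x0 + side, overlay.shape[1])
        y1 = min(y0 + side, overlay.shape[0])
        rgba = cmap(p)
        color = np.array(rgba[:3]) * 255.0
        alpha = max_alpha * p
        overlay[y0:y1, x0:x1] = (1 - alpha) * overlay[y0:y1, x0:x1] + alpha * color
    out_uri = Path(out_uri)
    Image.fromarray(np.clip(np.rint(overlay), 0, 255).astype(np.uint8)).save(out_uri)
    return out_uri
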