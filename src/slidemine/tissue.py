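"""Tissue detection by Otsu thresholding and candidate-tile enumeration.

Tissue is located on a grayscale thumbnail: pixels darker than the Otsu
threshold are tissue, brighter pixels are background. Candidate tiles are
then enumerated on a sliding-window grid at the working magnification and
kept when their tissue-pixel fraction (measured on the thumbnail mask)
reaches a minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .slide_io import SlideImage, TileRef

__all__ = [
    "TissueMask",
    "otsu_threshold",
    "detect_tissue",
    "enumerate_tiles",
    "DegenerateHistogramError",
]

# Rec. 601 luma coefficients for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateHistogramError(ValueError):
    """Histogram with fewer than two occupied gray levels."""


@dataclass
class TissueMask:
    """Binary tissue raster at a stated downsample of the base level.

    ``True`` marks tissue (gray at or below ``threshold_used`` — the
    threshold level itself belongs to the dark class of the Otsu split),
    ``False`` background.
    """

    mask: np.ndarray
    downsample: int
    threshold_used: float

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())

    def save_png(self, uri) -> None:
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(uri)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold for a 256-bin gray histogram.

    Returns the gray level ``t`` maximizing the between-class variance of the
    split ``gray <= t`` vs ``gray > t``; on ties the lowest qualifying level
    is returned. A histogram with a single occupied bin has no separable
    groups and raises :class:`DegenerateHistogramError`.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 occupied bins")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative class 0 (<= t) statistics for every candidate t
    w0 = np.cumsum(hist)
    m0_sum = np.cumsum(hist * levels)
    mean_all = m0_sum[-1] / total
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0_sum / w0
        mu1 = (m0_sum[-1] - m0_sum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # candidate thresholds with both classes nonempty: w0>0 and w1>0
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between))  # argmax returns the lowest maximizer


def detect_tissue(slide: SlideImage, working_downsample: int = 32) -> TissueMask:
    """Detect tissue on a thumbnail; eliminates the white background.

    The thumbnail at ``working_downsample`` (relative to the base level) is
    converted to grayscale with Rec. 601 luma weights; Otsu's threshold is
    computed on its 256-bin histogram and pixels in the dark class of the
    split (gray <= threshold) are marked tissue. An effectively blank slide
    yields an empty mask with a warning rather than an error.
    """
    thumb = slide.thumbnail(working_downsample)
    gray = np.rint(thumb.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)
    try:
        thr = otsu_threshold(hist)
    except DegenerateHistogramError:
        warnings.warn("single-valued slide; returning empty tissue mask")
        return TissueMask(np.zeros_like(gray, dtype=bool), working_downsample, float(gray.flat[0]))
    mask = gray <= thr
    if not mask.any():
        warnings.warn("no tissue detected (blank slide?)")
    return TissueMask(mask, working_downsample, float(thr))


def enumerate_tiles(
    tissue: TissueMask,
    slide: SlideImage,
    magnification: float,
    size_px: int,
    stride_px: int | None = None,
    min_tissue_fraction: float = 0.25,
) -> list[TileRef]:
    """All in-bounds grid tiles whose tissue fraction meets the minimum.

    The grid starts at (0, 0) on the pixel grid of ``magnification`` and
    advances by ``stride_px`` (default: the tile size, i.e. non-overlapping
    tiles); tiles that would cross the right/bottom edge are discarded, not
    padded. Tiles are returned in row-major order. The tissue fraction of a
    tile is the mean of the thumbnail mask over the tile's footprint.
    """
    if stride_px is None:
        stride_px = size_px
    if stride_px < 1:
        raise ValueError("stride must be >= 1")
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    w, h = slide.dimensions_at(magnification)
    # scale from the working grid to thumbnail pixels
    scale = slide.downsample_for(magnification) / tissue.downsample
    mh, mw = tissue.mask.shape
    # integral image for O(1) per-tile tissue fractions
    integral = np.zeros((mh + 1, mw + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(tissue.mask, axis=0), axis=1)

    out: list[TileRef] = []
    for y in range(0, h - size_px + 1, stride_px):
        my0 = min(int(y * scale), mh)
        my1 = min(max(int(np.ceil((y + size_px) * scale)), my0 + 1), mh)
        for x in range(0, w - size_px + 1, stride_px):
            mx0 = min(int(x * scale), mw)
            mx1 = min(max(int(np.ceil((x + size_px) * scale)), mx0 + 1), mw)
            area = (my1 - my0) * (mx1 - mx0)
            if area <= 0:
                continue
            count = (
                integral[my1, mx1]
                - integral[my0, mx1]
                - integral[my1, mx0]
                + integral[my0, mx0]
            )
            frac = count / area
            # tiles entirely off tissue are never candidates, even at min=0
            if frac > 0 and frac >= min_tissue_fraction:
                out.append(TileRef(slide.slide_id, magnification, x, y, size_px))
    return out
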