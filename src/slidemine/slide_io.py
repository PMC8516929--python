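"""Slide and annotation data model, coordinate conventions, and file I/O.

Coordinate conventions used throughout the package:

* Pixel coordinates are 0-based with the origin at the top-left corner;
  a tile of side ``size_px`` at ``(x, y)`` covers the half-open square
  ``[x, x + size) x [y, y + size)``.
* A nominal magnification ``m`` is tied to physical resolution through the
  scanner calibration ``x20 == 0.5 um/px`` (equivalently ``x10 == 1.0 um/px``),
  i.e. ``mpp(m) = 10 / m`` micrometres per pixel.
* Converting a coordinate between magnifications multiplies by the
  magnification ratio and rounds toward zero.

Slides are stored as multi-page TIFF pyramids (one page per level, metadata in
the ImageDescription tag) with a plain PNG fallback for single-level rasters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "SlideImage",
    "TileRef",
    "AnnotationSet",
    "LabeledSlide",
    "CalibrationError",
    "AnnotationError",
    "TileBoundsError",
    "open_slide",
    "save_slide",
    "read_tile",
    "read_annotations",
    "write_annotations",
    "magnification_for_mpp",
    "mpp_for_magnification",
]

# Calibration constant: nominal power x20 corresponds to 0.5 um per pixel.
_MPP_MAG_PRODUCT = 10.0


class CalibrationError(ValueError):
    """Raised when a slide has no microns-per-pixel calibration."""


class AnnotationError(ValueError):
    """Raised for malformed or self-intersecting annotation geometry."""


class TileBoundsError(ValueError):
    """Raised when a tile request falls outside the slide."""


def magnification_for_mpp(mpp: float) -> float:
    """Nominal objective power for a given resolution (x20 == 0.5 um/px)."""
    if mpp <= 0:
        raise CalibrationError(f"mpp must be positive, got {mpp}")
    return _MPP_MAG_PRODUCT / mpp


def mpp_for_magnification(magnification: float) -> float:
    """Micrometres per pixel at a nominal power (x20 == 0.5 um/px)."""
    if magnification <= 0:
        raise ValueError(f"magnification must be positive, got {magnification}")
    return _MPP_MAG_PRODUCT / magnification


@dataclass(frozen=True)
class TileRef:
    """Addressed square region of a slide at a stated magnification.

    ``(x, y)`` is the top-left corner on the pixel grid of that magnification;
    the tile covers the half-open square ``[x, x+size) x [y, y+size)``.
    """

    slide_id: str
    magnification: float
    x: int
    y: int
    size_px: int


@dataclass
class SlideImage:
    """Multi-level raster pyramid with physical calibration.

    ``levels`` holds one RGB uint8 array per pyramid level; ``downsamples[i]``
    is the integer factor of level *i* relative to the base level (level 0 has
    factor 1; factors strictly increase).
    """

    levels: list[np.ndarray]
    downsamples: list[int]
    mpp_base: float
    base_magnification: float
    slide_id: str = "slide"
    uri: str | None = None

    def __post_init__(self) -> None:
        if self.mpp_base <= 0:
            raise CalibrationError("mpp_base must be positive")
        if not self.levels:
            raise ValueError("slide needs at least one pyramid level")
        if self.downsamples[0] != 1:
            raise ValueError("level 0 must have downsample factor 1")
        if any(b <= a for a, b in zip(self.downsamples, self.downsamples[1:])):
            raise ValueError("downsample factors must strictly increase")

    # -- geometry ---------------------------------------------------------

    @property
    def base_shape(self) -> tuple[int, int]:
        """(width, height) of the base level."""
        h, w = self.levels[0].shape[:2]
        return w, h

    def level_geometry(self) -> list[tuple[int, int, int]]:
        """List of (width, height, downsample) per level."""
        return [
            (lvl.shape[1], lvl.shape[0], ds)
            for lvl, ds in zip(self.levels, self.downsamples)
        ]

    def mpp(self, magnification: float) -> float:
        return mpp_for_magnification(magnification)

    def downsample_for(self, magnification: float) -> float:
        """Downsample factor relative to base for a requested power."""
        return self.base_magnification / magnification

    def dimensions_at(self, magnification: float) -> tuple[int, int]:
        """(width, height) of the virtual pixel grid at ``magnification``."""
        w, h = self.base_shape
        d = self.downsample_for(magnification)
        return int(w / d), int(h / d)

    def best_level_for(self, magnification: float) -> int:
        """Pyramid level whose downsample is nearest the requested one."""
        target = self.downsample_for(magnification)
        if target <= 0:
            raise ValueError("magnification must be positive")
        diffs = [abs(np.log(ds / target)) for ds in self.downsamples]
        return int(np.argmin(diffs))

    def thumbnail(self, downsample: int) -> np.ndarray:
        """RGB thumbnail at an integer downsample relative to the base level."""
        level = int(np.argmin([abs(np.log(ds / downsample)) for ds in self.downsamples]))
        arr = self.levels[level]
        remaining = downsample / self.downsamples[level]
        if remaining == 1:
            return arr.copy()
        if remaining > 1:
            return _area_downsample(arr, int(round(remaining)))
        return _bilinear_resize(arr, (int(arr.shape[0] / remaining), int(arr.shape[1] / remaining)))


@dataclass
class AnnotationSet:
    """Labelled closed polygons in base-level pixel coordinates."""

    polygons: list[tuple[Polygon, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)

    def __bool__(self) -> bool:
        return bool(self.polygons)

    def labels(self) -> list[str]:
        return [label for _, label in self.polygons]

    def validate(self, bounds: tuple[int, int] | None = None) -> None:
        """Reject self-intersecting rings and out-of-bounds vertices."""
        for poly, label in self.polygons:
            if not poly.is_valid:
                raise AnnotationError(
                    f"invalid (self-intersecting?) polygon with label {label!r}"
                )
            if bounds is not None:
                w, h = bounds
                minx, miny, maxx, maxy = poly.bounds
                if minx < 0 or miny < 0 or maxx > w or maxy > h:
                    raise AnnotationError(
                        f"polygon with label {label!r} exceeds slide bounds {bounds}"
                    )


# Label vocabulary for the gastric diffuse-type adenocarcinoma task.
POSITIVE_LABELS = frozenset({"diffuse_ADC", "positive"})
NEGATIVE_LABELS = frozenset({"other_ADC", "non_neoplastic", "negative"})


def binary_label(label: str) -> int:
    """Deterministic binary mapping: diffuse-type ADC is the positive class."""
    if label in POSITIVE_LABELS:
        return 1
    if label in NEGATIVE_LABELS:
        return 0
    raise ValueError(f"unknown slide label {label!r}")


@dataclass
class LabeledSlide:
    """A slide together with its (possibly empty) annotations and label."""

    slide: SlideImage
    annotations: AnnotationSet
    label: str

    @property
    def y(self) -> int:
        return binary_label(self.label)

    @property
    def slide_id(self) -> str:
        return self.slide.slide_id


# -- resampling primitives ------------------------------------------------


def _area_downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor area-average downsampling with round-half-to-even.

    Trailing rows/columns that do not fill a complete block are dropped, so
    the output has shape ``floor(shape / factor)``.
    """
    h, w = arr.shape[:2]
    nh, nw = h // factor, w // factor
    arr = arr[: nh * factor, : nw * factor]
    if arr.ndim == 2:
        blocks = arr.reshape(nh, factor, nw, factor).astype(np.float64)
        out = blocks.mean(axis=(1, 3))
    else:
        c = arr.shape[2]
        blocks = arr.reshape(nh, factor, nw, factor, c).astype(np.float64)
        out = blocks.mean(axis=(1, 3))
    return np.rint(out).astype(np.uint8)


def _bilinear_resize(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    out = resize(
        arr.astype(np.float64), out_hw, order=1, anti_aliasing=False, preserve_range=True
    )
    return np.rint(out).astype(np.uint8)


def build_pyramid(base: np.ndarray, n_levels: int) -> tuple[list[np.ndarray], list[int]]:
    """Synthesize a pyramid by repeated 2x area-average downsampling."""
    levels = [base]
    downsamples = [1]
    for _ in range(1, n_levels):
        prev = levels[-1]
        if min(prev.shape[:2]) < 2:
            break
        levels.append(_area_downsample(prev, 2))
        downsamples.append(downsamples[-1] * 2)
    return levels, downsamples


# -- slide file I/O --------------------------------------------------------


def save_slide(slide: SlideImage, uri: str | Path) -> None:
    """Write a slide as a multi-page TIFF pyramid with calibration metadata."""
    uri = Path(uri)
    meta = {
        "slidemine": {
            "mpp_base": slide.mpp_base,
            "base_magnification": slide.base_magnification,
            "downsamples": slide.downsamples,
            "slide_id": slide.slide_id,
        }
    }
    with tifffile.TiffWriter(uri) as tw:
        for i, lvl in enumerate(slide.levels):
            tw.write(
                lvl,
                description=json.dumps(meta) if i == 0 else None,
                photometric="rgb",
                compression="zlib",
            )


def open_slide(
    uri: str | Path,
    mpp: float | None = None,
    base_magnification: float | None = None,
    slide_id: str | None = None,
) -> SlideImage:
    """Open a pyramidal TIFF (or plain raster) as a :class:`SlideImage`.

    ``mpp`` overrides (or supplies, for uncalibrated files) the base-level
    microns-per-pixel. A file without calibration metadata and without an
    override raises :class:`CalibrationError`.
    """
    uri = Path(uri)
    if not uri.exists():
        raise FileNotFoundError(uri)
    sid = slide_id or uri.stem
    if uri.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(uri) as tf:
            pages = [p.asarray() for p in tf.pages]
            desc = tf.pages[0].description
        meta = None
        if desc:
            try:
                meta = json.loads(desc).get("slidemine")
            except (json.JSONDecodeError, AttributeError):
                meta = None
        if meta is not None:
            mpp_base = mpp if mpp is not None else float(meta["mpp_base"])
            mag = (
                base_magnification
                if base_magnification is not None
                else float(meta["base_magnification"])
            )
            downsamples = [int(d) for d in meta["downsamples"]]
            return SlideImage(pages, downsamples, mpp_base, mag, sid, str(uri))
        if mpp is None:
            raise CalibrationError(
                f"{uri} has no microns-per-pixel metadata; pass mpp= to override"
            )
        downsamples = [
            int(round(pages[0].shape[1] / p.shape[1])) for p in pages
        ]
        mag = base_magnification or magnification_for_mpp(mpp)
        return SlideImage(pages, downsamples, mpp, mag, sid, str(uri))
    # plain raster fallback (PNG etc.): single level, calibration required
    if mpp is None:
        raise CalibrationError(
            f"{uri} is a plain raster with no calibration; pass mpp= to override"
        )
    arr = np.asarray(Image.open(uri).convert("RGB"))
    mag = base_magnification or magnification_for_mpp(mpp)
    return SlideImage([arr], [1], mpp, mag, sid, str(uri))


# -- tile reading ----------------------------------------------------------


def read_tile(slide: SlideImage, tile: TileRef) -> np.ndarray:
    """Read a tile as an exact ``size x size`` RGB uint8 raster.

    Pixels come from the pyramid level nearest the requested magnification and
    are resampled to the target grid: area averaging when scaling down,
    bilinear when scaling up. Out-of-bounds requests raise
    :class:`TileBoundsError`.
    """
    w, h = slide.dimensions_at(tile.magnification)
    if tile.x < 0 or tile.y < 0 or tile.x + tile.size_px > w or tile.y + tile.size_px > h:
        raise TileBoundsError(
            f"tile {tile} exceeds {w}x{h} grid at x{tile.magnification:g}"
        )
    level = slide.best_level_for(tile.magnification)
    arr = slide.levels[level]
    # scale from the requested grid to the chosen level's grid
    scale = slide.downsample_for(tile.magnification) / slide.downsamples[level]
    if scale == 1:
        return arr[tile.y : tile.y + tile.size_px, tile.x : tile.x + tile.size_px].copy()
    x0 = int(tile.x * scale)
    y0 = int(tile.y * scale)
    span = int(np.ceil(tile.size_px * scale))
    x0 = min(x0, arr.shape[1] - span)
    y0 = min(y0, arr.shape[0] - span)
    region = arr[y0 : y0 + span, x0 : x0 + span]
    if scale > 1:
        f = scale
        if abs(f - round(f)) < 1e-9 and span == tile.size_px * int(round(f)):
            return _area_downsample(region, int(round(f)))
        return _bilinear_resize(region, (tile.size_px, tile.size_px))
    return _bilinear_resize(region, (tile.size_px, tile.size_px))


def tile_extent_um(size_px: int, magnification: float) -> float:
    """Physical side length of a tile in micrometres (224 px at x20 -> 112)."""
    return size_px * mpp_for_magnification(magnification)


# -- annotation file I/O ---------------------------------------------------


def write_annotations(annotations: AnnotationSet, uri: str | Path) -> None:
    """Write an annotation set as a GeoJSON FeatureCollection of Polygons."""
    features = []
    for poly, label in annotations.polygons:
        features.append(
            {"type": "Feature", "properties": {"label": label}, "geometry": mapping(poly)}
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(uri).write_text(json.dumps(payload))


def read_annotations(uri: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection; rejects self-intersecting rings."""
    try:
        payload = json.loads(Path(uri).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed annotation file {uri}: {exc}") from exc
    if payload.get("type") != "FeatureCollection":
        raise AnnotationError(f"{uri}: expected a GeoJSON FeatureCollection")
    out = AnnotationSet()
    for feat in payload.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise AnnotationError(f"{uri}: unsupported geometry {geom.geom_type}")
        if not geom.is_valid:
            raise AnnotationError(f"{uri}: self-intersecting or degenerate polygon ring")
        label = str(feat.get("properties", {}).get("label", "lesion"))
        out.polygons.append((geom, label))
    return out


def tile_box(tile: TileRef, to_magnification: float | None = None):
    """Shapely box of a tile, optionally rescaled to another magnification."""
    if to_magnification is None or to_magnification == tile.magnification:
        x, y, s = tile.x, tile.y, tile.size_px
        return box(x, y, x + s, y + s)
    r = to_magnification / tile.magnification
    return box(tile.x * r, tile.y * r, (tile.x + tile.size_px) * r, (tile.y + tile.size_px) * r)
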