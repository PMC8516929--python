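"""Deterministic generator of labelled synthetic slides with ground truth.

The generator emulates the imaging context of H&E-stained endoscopic biopsy
slides at the level of gray structure rather than appearance: a near-white
scanner background, darker tissue fragments with per-pixel noise, and — on
positive slides only — lesion regions carrying a high-frequency dark-speckle
texture that a small convolutional scorer can separate from plain tissue.
Each lesion region comes with a matching free-hand-style polygon annotation,
so every generated cohort has exact tissue and lesion ground truth.

Default gray levels: background 240 +/- 5, tissue 180 +/- 15, lesion speckle
dots 60 +/- 20 — chosen so Otsu thresholding cleanly splits background from
tissue and the speckle is statistically separable from plain tissue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .slide_io import (
    AnnotationSet,
    LabeledSlide,
    SlideImage,
    build_pyramid,
    save_slide,
    write_annotations,
)

__all__ = [
    "SyntheticSlideSpec",
    "SyntheticSlideResult",
    "generate_slide",
    "generate_cohort",
    "write_cohort",
]

# gray-level palette (mean, sd); see module docstring
BACKGROUND_GRAY = (240.0, 5.0)
TISSUE_GRAY = (180.0, 15.0)
SPECKLE_GRAY = (60.0, 20.0)
# mild eosin-like tint added to tissue pixels (R, G, B offsets)
TISSUE_TINT = (10.0, -12.0, 2.0)
SPECKLE_DOT_DENSITY = 0.02  # dot seeds per pixel before 3x3 dilation


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``lesion`` controls whether lesion texture (and hence annotations and a
    positive label) are present; ``n_lesion_regions`` must be consistent with
    it. All sizes are base-level pixels.
    """

    width_px: int = 768
    height_px: int = 768
    mpp_base: float = 0.5
    base_magnification: float = 20.0
    n_tissue_blobs: int = 3
    lesion: bool = False
    n_lesion_regions: int = 0
    lesion_region_diameter_px: int = 140
    seed: int = 0
    n_levels: int = 3

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp_base <= 0:
            raise ValueError("mpp_base must be positive")
        if self.n_tissue_blobs < 1:
            raise ValueError("need at least one tissue blob")
        if self.lesion and self.n_lesion_regions < 1:
            raise ValueError("lesion=True requires n_lesion_regions >= 1")
        if not self.lesion and self.n_lesion_regions != 0:
            raise ValueError("lesion=False requires n_lesion_regions == 0")
        if self.lesion_region_diameter_px <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.lesion_region_diameter_px >= min(self.width_px, self.height_px):
            raise ValueError("lesion diameter must be smaller than the slide")


@dataclass
class SyntheticSlideResult:
    """A generated slide plus its exact ground truth.

    ``tissue_mask`` and ``lesion_mask`` are boolean base-level rasters drawn
    directly from the generator's own geometry (not re-detected).
    """

    slide: SlideImage
    annotations: AnnotationSet
    label: str
    tissue_mask: np.ndarray = field(repr=False, default=None)
    lesion_mask: np.ndarray = field(repr=False, default=None)

    def as_labeled_slide(self) -> LabeledSlide:
        return LabeledSlide(self.slide, self.annotations, self.label)


def _blob_ring(
    rng: np.random.Generator,
    cx: float,
    cy: float,
    radius: float,
    wobble: float,
    n_vertices: int,
) -> np.ndarray:
    """Closed perturbed-circle ring (n_vertices x 2 array of x, y).

    The radial perturbation is a smooth periodic signal built from a few
    random Fourier components, mimicking a free-hand outline. The returned
    radii stay within ``radius * (1 +/- wobble)``.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    perturb = np.zeros_like(theta)
    for harmonic in (2, 3, 5):
        amp = rng.uniform(0.2, 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        perturb += amp * np.sin(harmonic * theta + phase)
    perturb /= np.max(np.abs(perturb)) + 1e-12
    r = radius * (1.0 + wobble * perturb)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    return np.column_stack([xs, ys])


def _rasterize_ring(ring: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape_hw, dtype=bool)
    rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=shape_hw)
    mask[rr, cc] = True
    return mask


def generate_slide(spec: SyntheticSlideSpec) -> SyntheticSlideResult:
    """Generate one synthetic slide; byte-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # background
    gray = rng.normal(*BACKGROUND_GRAY, size=(h, w))

    # tissue blobs: perturbed circles on a jittered grid of centres
    tissue_mask = np.zeros((h, w), dtype=bool)
    min_dim = min(w, h)
    blob_centres = []
    blob_radii = []
    n = spec.n_tissue_blobs
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    for i in range(n):
        gx, gy = i % cols, i // cols
        base_r = rng.uniform(0.14, 0.20) * min_dim
        cx = (gx + 0.5) / cols * w + rng.uniform(-0.08, 0.08) * w
        cy = (gy + 0.5) / rows * h + rng.uniform(-0.08, 0.08) * h
        cx = float(np.clip(cx, base_r * 1.3, w - base_r * 1.3))
        cy = float(np.clip(cy, base_r * 1.3, h - base_r * 1.3))
        ring = _blob_ring(rng, cx, cy, base_r, wobble=0.22, n_vertices=72)
        tissue_mask |= _rasterize_ring(ring, (h, w))
        blob_centres.append((cx, cy))
        blob_radii.append(base_r)
    gray[tissue_mask] = rng.normal(*TISSUE_GRAY, size=int(tissue_mask.sum()))

    # lesion regions: one free-hand style polygon each, inside a tissue blob
    annotations = AnnotationSet()
    lesion_mask = np.zeros((h, w), dtype=bool)
    if spec.lesion:
        for j in range(spec.n_lesion_regions):
            bi = j % len(blob_centres)
            bx, by = blob_centres[bi]
            blob_r = blob_radii[bi]
            # Containment: lesion stays inside the blob's guaranteed interior
            # disc of radius blob_r * (1 - wobble).
            inner = blob_r * 0.78
            req_r = spec.lesion_region_diameter_px / 2.0
            jitter = min(0.15 * blob_r, max(inner - req_r * 1.25, 0.0))
            les_r = min(req_r, (inner - jitter) / 1.25)
            cx = bx + rng.uniform(-jitter, jitter)
            cy = by + rng.uniform(-jitter, jitter)
            ring = _blob_ring(rng, cx, cy, les_r, wobble=0.2, n_vertices=48)
            ring = np.clip(ring, [0, 0], [w - 1, h - 1])
            poly = Polygon(ring)
            annotations.polygons.append((poly, "lesion"))
            lesion_mask |= _rasterize_ring(ring, (h, w))
        lesion_mask &= tissue_mask
        # high-frequency dark speckle strictly inside the polygons
        dots = rng.random((h, w)) < SPECKLE_DOT_DENSITY
        dots = binary_dilation(dots, structure=np.ones((3, 3), dtype=bool))
        dots &= lesion_mask
        gray[dots] = rng.normal(*SPECKLE_GRAY, size=int(dots.sum()))

    gray = np.clip(gray, 0, 255)
    rgb = np.stack([gray, gray, gray], axis=-1)
    tint = np.array(TISSUE_TINT)
    rgb[tissue_mask] = rgb[tissue_mask] + tint
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    levels, downsamples = build_pyramid(rgb, spec.n_levels)
    slide = SlideImage(
        levels=levels,
        downsamples=downsamples,
        mpp_base=spec.mpp_base,
        base_magnification=spec.base_magnification,
        slide_id=f"synthetic-{spec.seed}",
    )
    label = "positive" if annotations else "negative"
    return SyntheticSlideResult(slide, annotations, label, tissue_mask, lesion_mask)


def _slide_seed(cohort_seed: int, index: int) -> int:
    """Fixed per-slide seed hash: stable under cohort reordering."""
    return (cohort_seed * 1_000_003 + index * 7919) % (2**31 - 1)


def generate_cohort(
    n_positive: int,
    n_negative: int,
    base_spec: SyntheticSlideSpec | None = None,
    seed: int = 0,
    n_lesion_regions: int = 2,
) -> list[SyntheticSlideResult]:
    """Generate ``n_positive + n_negative`` slides with derived per-slide seeds.

    Positives come first. Each slide's spec is ``base_spec`` with ``lesion``,
    ``n_lesion_regions`` and the derived seed substituted.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("cohort counts must be non-negative")
    base = base_spec or SyntheticSlideSpec()
    out: list[SyntheticSlideResult] = []
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        spec = SyntheticSlideSpec(
            width_px=base.width_px,
            height_px=base.height_px,
            mpp_base=base.mpp_base,
            base_magnification=base.base_magnification,
            n_tissue_blobs=base.n_tissue_blobs,
            lesion=positive,
            n_lesion_regions=n_lesion_regions if positive else 0,
            lesion_region_diameter_px=base.lesion_region_diameter_px,
            seed=_slide_seed(seed, i),
            n_levels=base.n_levels,
        )
        result = generate_slide(spec)
        result.slide.slide_id = f"cohort{seed}-s{i:03d}-{'pos' if positive else 'neg'}"
        out.append(result)
    return out


def write_cohort(
    cohort: list[SyntheticSlideResult], out_dir: str | Path
) -> Path:
    """Write slides (pyramidal TIFF), annotations (GeoJSON) and a manifest CSV.

    Returns the manifest path. Manifest columns: slide_path, annotation_path
    (empty for negatives), label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_path", "annotation_path", "label"])
        for res in cohort:
            sid = res.slide.slide_id
            slide_path = out_dir / f"{sid}.tiff"
            save_slide(res.slide, slide_path)
            ann_path = ""
            if res.annotations:
                ann_path = str(out_dir / f"{sid}.geojson")
                write_annotations(res.annotations, ann_path)
            writer.writerow([str(slide_path), ann_path, res.label])
    return manifest
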