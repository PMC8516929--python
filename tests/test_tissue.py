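"""Otsu thresholding and tile enumeration against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slidemine.slide_io import SlideImage, build_pyramid
from slidemine.tissue import (
    DegenerateHistogramError,
    TissueMask,
    detect_tissue,
    enumerate_tiles,
    otsu_threshold,
)


def otsu_brute_force(hist):
    """Independent exhaustive scan over all 255 split points."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9:  # strictly better: keeps the lowest tie
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_spike_histogram_splits_between_modes(self):
        hist = np.zeros(256)
        hist[60] = 500
        hist[200] = 500
        t = otsu_threshold(hist)
        assert 60 <= t < 200

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        for _ in range(120):
            hist = rng.integers(0, 50, size=256)
            # randomly sparsify to vary the support
            hist[rng.random(256) < rng.uniform(0.2, 0.95)] = 0
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == otsu_brute_force(hist)

    def test_tie_break_returns_lowest_level(self):
        # symmetric two-spike histogram: every split between the spikes has
        # the same between-class variance; the lowest qualifying level wins
        hist = np.zeros(256)
        hist[10] = 100
        hist[250] = 100
        assert otsu_threshold(hist) == otsu_brute_force(hist) == 10

    def test_degenerate_histogram_rejected(self):
        hist = np.zeros(256)
        hist[42] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist)

    def test_agrees_with_skimage_on_bimodal_data(self, rng):
        """Cross-check against an independent implementation."""
        from skimage.filters import threshold_otsu

        data = np.concatenate(
            [rng.normal(180, 15, 4000), rng.normal(240, 5, 6000)]
        ).clip(0, 255).astype(np.uint8)
        ours = otsu_threshold(np.bincount(data, minlength=256))
        theirs = threshold_otsu(data)
        assert abs(ours - theirs) <= 1


class TestDetectTissue:
    def test_mask_overlaps_generator_ground_truth(self, pos_result):
        tm = detect_tissue(pos_result.slide, working_downsample=8)
        # ground truth at the same scale: block-mean > 0.5
        gt = pos_result.tissue_mask.astype(float)
        gt = gt.reshape(64, 8, 64, 8).mean(axis=(1, 3)) > 0.5
        inter = (tm.mask & gt).sum()
        union = (tm.mask | gt).sum()
        assert inter / union >= 0.9

    def test_pure_white_slide_gives_empty_mask(self):
        base = np.full((64, 64, 3), 255, dtype=np.uint8)
        levels, downs = build_pyramid(base, 2)
        slide = SlideImage(levels, downs, 0.5, 20.0, "white")
        with pytest.warns(UserWarning):
            tm = detect_tissue(slide, working_downsample=2)
        assert not tm.mask.any()

    def test_all_dark_slide_gives_full_mask(self):
        rng = np.random.default_rng(0)
        base = rng.integers(20, 60, size=(64, 64, 3)).astype(np.uint8)
        base[:8] = 200  # a sliver of background so Otsu has two groups
        levels, downs = build_pyramid(base, 2)
        slide = SlideImage(levels, downs, 0.5, 20.0, "dark")
        tm = detect_tissue(slide, working_downsample=1)
        assert tm.mask[8:].all()
        assert not tm.mask[:8].any()

    def test_mask_dimensions_follow_downsample(self, pos_result):
        tm = detect_tissue(pos_result.slide, working_downsample=4)
        assert tm.mask.shape == (128, 128)
        assert tm.downsample == 4


def _mask_slide(mask, downsample=1, mag=20.0):
    """Slide whose base level matches a given thumbnail-scale mask."""
    h, w = mask.shape
    base = np.full((h * downsample, w * downsample, 3), 255, dtype=np.uint8)
    slide = SlideImage([base], [1], 0.5, mag, "m")
    return slide, TissueMask(mask, downsample, 128.0)


def enumerate_brute_force(tm, slide, mag, size, stride, min_frac):
    """Independent double loop with explicit per-tile mask counting."""
    w, h = slide.dimensions_at(mag)
    scale = slide.downsample_for(mag) / tm.downsample
    mh, mw = tm.mask.shape
    out = []
    for y in range(0, h - size + 1, stride):
        for x in range(0, w - size + 1, stride):
            x0 = min(int(x * scale), mw)
            x1 = min(max(int(np.ceil((x + size) * scale)), x0 + 1), mw)
            y0 = min(int(y * scale), mh)
            y1 = min(max(int(np.ceil((y + size) * scale)), y0 + 1), mh)
            window = tm.mask[y0:y1, x0:x1]
            if window.size == 0:
                continue
            count = sum(int(v) for row in window for v in row)
            frac = count / window.size
            if frac > 0 and frac >= min_frac:
                out.append((x, y))
    return out


class TestEnumerateTiles:
    def test_full_mask_grid_count(self):
        # 1000 px, tiles of 224 at stride 224 -> floor((1000-224)/224)+1 = 4 per axis
        mask = np.ones((1000, 1000), dtype=bool)
        slide, tm = _mask_slide(mask)
        tiles = enumerate_tiles(tm, slide, 20.0, 224, 224, 0.5)
        assert len(tiles) == 16
        assert (tiles[0].x, tiles[0].y) == (0, 0)
        # row-major order
        assert [(t.x, t.y) for t in tiles[:4]] == [(0, 0), (224, 0), (448, 0), (672, 0)]

    def test_empty_mask_yields_no_tiles_even_at_zero_threshold(self):
        mask = np.zeros((100, 100), dtype=bool)
        slide, tm = _mask_slide(mask)
        assert enumerate_tiles(tm, slide, 20.0, 32, 32, 0.0) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            mh = int(rng.integers(20, 60))
            mask = rng.random((mh, mh)) < rng.uniform(0.2, 0.8)
            down = int(rng.choice([1, 2, 4]))
            slide, tm = _mask_slide(mask, downsample=down)
            mag = float(rng.choice([10.0, 20.0]))
            size = int(rng.choice([8, 16, 32]))
            stride = int(rng.choice([size // 2, size]))
            frac = float(rng.choice([0.0, 0.25, 0.5, 1.0]))
            got = [(t.x, t.y) for t in enumerate_tiles(tm, slide, mag, size, stride, frac)]
            want = enumerate_brute_force(tm, slide, mag, size, stride, frac)
            assert got == want

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_raising_threshold_never_adds_tiles(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) < 0.5
        slide, tm = _mask_slide(mask)
        fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
        counts = [
            len(enumerate_tiles(tm, slide, 20.0, 16, 16, f)) for f in fracs
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nonoverlapping_tiles_are_disjoint(self):
        mask = np.ones((200, 200), dtype=bool)
        slide, tm = _mask_slide(mask)
        tiles = enumerate_tiles(tm, slide, 20.0, 50, 50, 0.5)
        boxes = {(t.x, t.y) for t in tiles}
        assert len(boxes) == len(tiles)
        for t in tiles:
            assert t.x % 50 == 0 and t.y % 50 == 0
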