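"""Thresholding, border following and the N_G / N_PC statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from dermaquant import (
    SEMImage,
    binarize_gaps,
    cell_pixel_count,
    gap_count,
    render_overlay,
    segment_tiles,
    tile_image,
    trace_borders,
)

from conftest import make_mask

EIGHT = np.ones((3, 3), dtype=bool)


def oracle_components(mask: np.ndarray) -> int:
    """Independent 8-connected component count (flood-fill labeler)."""
    return int(ndimage.label(mask, structure=EIGHT)[1])


class TestBinarize:
    def test_strict_inequality_at_cutoff(self):
        tile = SEMImage(pixels=np.array([[200, 80, 79]], dtype=np.uint8))
        m = binarize_gaps(tile, frac=0.40)
        assert m.threshold_value == pytest.approx(80.0)
        assert m.mask.tolist() == [[False, False, True]]

    def test_uniform_tile_has_no_gaps(self):
        m = binarize_gaps(SEMImage(pixels=np.full((5, 5), 7, dtype=np.uint8)))
        assert not m.mask.any()

    def test_all_zero_tile_has_no_gaps(self):
        m = binarize_gaps(SEMImage(pixels=np.zeros((4, 4), dtype=np.uint8)))
        assert not m.mask.any()

    def test_matches_elementwise_comparison(self, rng):
        px = rng.integers(0, 256, size=(50, 50), dtype=np.uint8)
        m = binarize_gaps(SEMImage(pixels=px), frac=0.40)
        assert np.array_equal(m.mask, px < 0.40 * px.max())

    def test_invalid_frac_rejected(self):
        img = SEMImage(pixels=np.zeros((2, 2), dtype=np.uint8))
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                binarize_gaps(img, frac=bad)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**16), f1=st.floats(0.05, 0.9), f2=st.floats(0.05, 0.9))
    def test_threshold_monotonicity(self, seed, f1, f2):
        """Raising the threshold fraction never shrinks the gap set."""
        lo, hi = sorted((f1, f2))
        px = np.random.default_rng(seed).integers(0, 256, (20, 20), dtype=np.uint8)
        tile = SEMImage(pixels=px)
        m_lo = binarize_gaps(tile, frac=lo).mask
        m_hi = binarize_gaps(tile, frac=hi).mask
        assert (m_hi | m_lo).sum() == m_hi.sum()  # lo subset of hi


class TestTraceBorders:
    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        (c,) = trace_borders(make_mask(m))
        assert c.kind == "outer"
        assert c.pixels == ((1, 1),)
        assert c.enclosed_area_px == 1

    def test_solid_block_perimeter(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        (c,) = trace_borders(make_mask(m))
        assert c.kind == "outer"
        perimeter = {(r, col) for r in range(1, 4) for col in range(1, 4)} - {(2, 2)}
        assert set(c.pixels) == perimeter
        assert c.enclosed_area_px == 9

    def test_ring_yields_outer_plus_hole_counted_once(self):
        m = np.ones((3, 3), bool)
        m[1, 1] = False
        contours = trace_borders(make_mask(m))
        kinds = sorted(c.kind for c in contours)
        assert kinds == ["hole", "outer"]
        hole = next(c for c in contours if c.kind == "hole")
        assert hole.enclosed_area_px == 1
        assert gap_count(make_mask(m)) == 1

    def test_contour_pixels_are_gap_pixels_and_8_connected(self, rng):
        m = rng.random((20, 20)) < 0.4
        for c in trace_borders(make_mask(m)):
            for r, col in c.pixels:
                assert m[r, col]
            closed = list(c.pixels) + [c.pixels[0]]
            for (r1, c1), (r2, c2) in zip(closed, closed[1:]):
                assert max(abs(r1 - r2), abs(c1 - c2)) <= 1

    def test_empty_mask(self):
        assert trace_borders(make_mask(np.zeros((4, 4), bool))) == []

    def test_deterministic_raster_ordering(self, rng):
        m = rng.random((30, 30)) < 0.3
        starts = [c.pixels[0] for c in trace_borders(make_mask(m)) ]
        assert starts == sorted(starts)


class TestGapCount:
    def test_empty_mask_is_zero(self):
        assert gap_count(make_mask(np.zeros((5, 5), bool))) == 0

    def test_diagonal_touch_is_one_region(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = m[1, 1] = True
        assert gap_count(make_mask(m)) == 1

    def test_separated_squares_count_each(self):
        m = np.zeros((10, 16), bool)
        for k in range(4):
            m[2:4, 4 * k : 4 * k + 2] = True
        assert gap_count(make_mask(m)) == 4

    def test_min_area_filter(self):
        m = np.zeros((8, 8), bool)
        m[0, 0] = True  # area 1
        m[4:7, 4:7] = True  # area 9
        gm = make_mask(m)
        assert gap_count(gm) == 2
        assert gap_count(gm, min_area=2) == 1

    @pytest.mark.parametrize("density", [0.15, 0.5, 0.85])
    def test_matches_flood_fill_oracle(self, density, rng):
        """Outer-border count equals an independent component labeler on
        random masks across sparsity regimes."""
        for _ in range(150):
            h, w = rng.integers(1, 64, size=2)
            m = rng.random((h, w)) < density
            assert gap_count(make_mask(m)) == oracle_components(m)

    def test_outer_contours_cover_component_borders(self, rng):
        """Outer contour pixels are exactly the pixels of their component that
        touch the background (8-neighbourhood), component by component."""
        m = rng.random((40, 40)) < 0.45
        labels, _ = ndimage.label(m, structure=EIGHT)
        interior = ndimage.binary_erosion(
            np.pad(m, 1), structure=np.ones((3, 3), bool)
        )[1:-1, 1:-1]
        border_true = m & ~interior
        outer_px = set()
        for c in trace_borders(make_mask(m)):
            if c.kind == "outer":
                outer_px.update(c.pixels)
        # every true border pixel not adjacent to a hole must be on an outer
        # contour; every outer contour pixel must be a border pixel
        assert outer_px <= {tuple(p) for p in np.argwhere(border_true)}


class TestCounts:
    def test_cell_pixel_conservation(self, rng):
        m = np.zeros((250, 250), bool)
        idx = rng.choice(250 * 250, size=100, replace=False)
        m.ravel()[idx] = True
        gm = make_mask(m)
        assert cell_pixel_count(gm) == 62400

    def test_all_gap_and_all_cell(self):
        assert cell_pixel_count(make_mask(np.ones((250, 250), bool))) == 0
        assert cell_pixel_count(make_mask(np.zeros((250, 250), bool))) == 62500


class TestSegmentTiles:
    def test_conservation_and_order(self, rng):
        px = rng.integers(0, 256, size=(500, 750), dtype=np.uint8)
        grid = tile_image(SEMImage(pixels=px), 250)
        stats = segment_tiles(grid)
        assert len(stats) == 6
        for s, origin in zip(stats, grid.origins):
            assert s.tile_origin == origin
            assert s.n_pc + s.gap_px == 250 * 250
            assert (s.n_g == 0) == (s.gap_px == 0)
            assert s.n_g <= s.gap_px

    def test_uniform_tiles_have_no_gaps(self):
        grid = tile_image(SEMImage(pixels=np.full((250, 500), 9, np.uint8)), 250)
        assert all(s.n_g == 0 for s in segment_tiles(grid))

    def test_per_tile_counts_match_oracle(self, rng):
        px = rng.integers(0, 256, size=(256, 256), dtype=np.uint8)
        grid = tile_image(SEMImage(pixels=px), 64)
        for s, tile in zip(segment_tiles(grid), grid.tiles):
            m = tile.pixels < 0.40 * tile.pixels.max()
            assert s.n_g == oracle_components(m)

    def test_image_scope_uses_parent_max(self):
        px = np.full((250, 500), 60, dtype=np.uint8)
        px[:, 250:] = 200  # right tile bright; left tile uniform dim
        grid = tile_image(SEMImage(pixels=px), 250)
        per_tile = segment_tiles(grid, threshold_scope="tile")
        per_image = segment_tiles(grid, threshold_scope="image")
        assert per_tile[0].gap_px == 0  # 60 < 0.4*60 is false
        assert per_image[0].gap_px == 250 * 250  # 60 < 0.4*200 = 80
        assert per_image[0].threshold_value == pytest.approx(80.0)

    def test_determinism(self, rng):
        px = rng.integers(0, 256, size=(250, 500), dtype=np.uint8)
        grid = tile_image(SEMImage(pixels=px), 250)
        assert segment_tiles(grid) == segment_tiles(grid)


class TestOverlay:
    def test_pixelwise_palette(self):
        m = np.zeros((2, 2), bool)
        m[0, 0] = True
        out = render_overlay(make_mask(m))
        assert out.shape == (2, 2, 3)
        assert out[0, 0].tolist() == [255, 255, 0]  # gap: yellow
        assert out[1, 1].tolist() == [0, 0, 255]  # cell: blue

    def test_uniform_masks(self):
        all_gap = render_overlay(make_mask(np.ones((3, 3), bool)))
        assert (all_gap == [255, 255, 0]).all()
        no_gap = render_overlay(make_mask(np.zeros((3, 3), bool)))
        assert (no_gap == [0, 0, 255]).all()
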