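"""Per-slice segmentation: each step against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemct.imaging import (
    CircleFitError,
    SegmentationConfig,
    SliceRegion,
    analyze_slice,
    binarize,
    boundary_pixels,
    extract_regions,
    filter_by_eccentricity,
    fit_circle,
    fit_inner_circle,
    measure_intensity,
    measure_pithy_fraction,
    measure_rind_area,
    morphological_close,
)
from stemct.phantom import generate_stack, grid_cell_centers, sample_platform_spec

from conftest import make_slice


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - cy, xx - cx) <= r


def _region_from_mask(mask) -> SliceRegion:
    regions = extract_regions(mask, area_factor=1e-9, fill_holes=False)
    assert len(regions) == 1
    return regions[0]


class TestBinarize:
    def test_all_zero_empty(self):
        assert not binarize(make_slice(np.zeros((8, 8)))).any()

    def test_all_255_full(self):
        assert binarize(make_slice(np.full((8, 8), 255))).all()

    def test_noise_free_phantom_mask_is_union_of_discs(self):
        spec = sample_platform_spec(seed=21, n_stems=5, pithy_range=(0.0, 0.0))
        slices, truth = generate_stack(spec)
        mask = binarize(slices[0])
        centers = grid_cell_centers(spec.image_shape)
        expected = np.zeros(spec.image_shape, dtype=bool)
        for stem in spec.stems:
            cy, cx = centers[stem.grid_cell]
            r = stem.max_radius_mm() / spec.pixel_spacing
            expected |= _disc_mask(spec.image_shape, cy, cx, r)
        assert np.array_equal(mask, expected)


def _brute_dilate(mask, offsets):
    out = np.zeros_like(mask)
    h, w = mask.shape
    for (r, c) in np.argwhere(mask):
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out[rr, cc] = True
    return out


def _brute_erode(mask, offsets):
    out = np.zeros_like(mask)
    h, w = mask.shape
    for (r, c) in np.argwhere(np.ones_like(mask)):
        ok = True
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                ok = False
                break
        out[r, c] = ok
    return out


class TestClosing:
    def test_solid_disc_unchanged(self):
        mask = _disc_mask((64, 64), 32, 32, 15)
        assert np.array_equal(morphological_close(mask, 3), mask)

    def test_crack_filled_matches_brute_force(self):
        # disc with a 2-px-wide crack through the middle
        mask = _disc_mask((64, 64), 32, 32, 15)
        mask[31:33, :] = False
        closed = morphological_close(mask, 3)
        # oracle: dilation then erosion with the explicit disc-3 offset set
        from skimage.morphology import disk

        offs = [tuple(p - 3) for p in np.argwhere(disk(3))]
        expected = _brute_erode(_brute_dilate(mask, offs), offs)
        # compare away from the image border (the brute-force erosion treats
        # out-of-bounds as background on all sides, as does the library)
        assert np.array_equal(closed[10:54, 10:54], expected[10:54, 10:54])
        # the crack is filled inside the disc interior
        assert closed[31:33, 25:40].all()

    def test_empty_mask_unchanged(self):
        mask = np.zeros((32, 32), dtype=bool)
        assert not morphological_close(mask, 3).any()

    def test_idempotent(self):
        mask = _disc_mask((64, 64), 32, 32, 12)
        mask[31:33, :] = False
        once = morphological_close(mask, 3)
        assert np.array_equal(morphological_close(once, 3), once)


def _flood_fill_components(mask, diagonal):
    """Brute-force connected components by flood fill."""
    comp = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diagonal:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for seed in map(tuple, np.argwhere(mask)):
        if comp[seed]:
            continue
        nxt += 1
        stack = [seed]
        comp[seed] = nxt
        while stack:
            r, c = stack.pop()
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < mask.shape[0]
                    and 0 <= cc < mask.shape[1]
                    and mask[rr, cc]
                    and not comp[rr, cc]
                ):
                    comp[rr, cc] = nxt
                    stack.append((rr, cc))
    return nxt


class TestExtractRegions:
    def test_area_filter_threshold_arithmetic(self):
        # 1000 x 1000 image: cutoff = 1000*1000*0.00005 = 50 px
        mask = np.zeros((1000, 1000), dtype=bool)
        mask[10:17, 10:17] = True  # 49 px
        assert extract_regions(mask, area_factor=0.00005) == []
        mask[10:17, 10:17] = False
        mask[30:40, 30:35] = True  # 50 px: at the cutoff, kept
        assert len(extract_regions(mask, area_factor=0.00005)) == 1

    def test_thirty_stem_phantom_gives_thirty_regions(self):
        spec = sample_platform_spec(seed=30, n_stems=30)
        slices, _ = generate_stack(spec)
        mask = morphological_close(binarize(slices[0]), 3)
        assert len(extract_regions(mask, 0.00005)) == 30

    def test_diagonal_touching_discs_merge_under_8_connectivity(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:15] = True
        mask[15:25, 15:25] = True  # touches only at the (14,14)/(15,15) diagonal
        assert _flood_fill_components(mask, diagonal=False) == 2
        assert _flood_fill_components(mask, diagonal=True) == 1
        assert len(extract_regions(mask, 1e-9)) == 1  # default is 8-connectivity

    def test_hole_filling_restores_full_cross_section(self):
        mask = _disc_mask((64, 64), 32, 32, 15)
        holes = _disc_mask((64, 64), 32, 32, 8)
        region = extract_regions(mask & ~holes, 1e-9, fill_holes=True)[0]
        assert region.area_px == mask.sum()


class TestEccentricityFilter:
    def _ellipse_region(self, a, b):
        yy, xx = np.mgrid[0:200, 0:200]
        mask = ((yy - 100) / b) ** 2 + ((xx - 100) / a) ** 2 <= 1
        return _region_from_mask(mask)

    def test_perfect_disc_excluded_in_literal_mode(self):
        region = self._ellipse_region(40, 40)
        assert region.eccentricity < 0.08
        assert filter_by_eccentricity([region], 0.08, "exclude_below") == []

    def test_perfect_disc_retained_in_exclude_above_mode(self):
        region = self._ellipse_region(40, 40)
        assert filter_by_eccentricity([region], 0.9, "exclude_above") == [region]

    def test_3_to_1_ellipse_excluded_above_cutoff(self):
        region = self._ellipse_region(60, 20)
        # second-moment oracle: for a solid ellipse with semi-axes a > b,
        # eccentricity = sqrt(1 - (b/a)^2) = 0.943 at 3:1
        assert region.eccentricity == pytest.approx(np.sqrt(1 - 1 / 9), abs=0.01)
        assert filter_by_eccentricity([region], 0.9, "exclude_above") == []


class TestFitCircle:
    def test_unit_circle_four_points(self):
        c = fit_circle([(0, 1), (1, 0), (0, -1), (-1, 0)])
        assert c.center == pytest.approx((0, 0), abs=1e-12)
        assert c.radius_px == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        cy=st.floats(-50, 50),
        cx=st.floats(-50, 50),
        r=st.floats(0.5, 100),
        n=st.integers(4, 60),
    )
    def test_exact_on_analytic_circles(self, cy, cx, r, n):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([cy + r * np.sin(th), cx + r * np.cos(th)])
        c = fit_circle(pts)
        resid = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1]) - c.radius_px
        assert np.abs(resid).max() < 1e-9

    def test_rasterised_disc_boundary_radius(self):
        mask = _disc_mask((64, 64), 32, 32, 20)
        c = fit_circle(boundary_pixels(mask))
        assert c.radius_px == pytest.approx(20, abs=0.5)
        assert c.center == pytest.approx((32, 32), abs=0.1)

    def test_too_few_points_error(self):
        with pytest.raises(CircleFitError):
            fit_circle([(0, 0), (1, 1)])

    def test_collinear_points_error(self):
        with pytest.raises(CircleFitError):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])


class TestIntensity:
    @pytest.mark.parametrize(
        "value,expected", [(255, 1.0), (51, 0.2), (0, 0.0)]
    )
    def test_uniform_region(self, value, expected):
        img = np.full((10, 10), value)
        region = _region_from_mask(np.ones((10, 10), dtype=bool))
        assert measure_intensity(region, make_slice(img)) == pytest.approx(expected)

    def test_half_and_half(self):
        img = np.zeros((10, 10))
        img[:5] = 100
        img[5:] = 200
        region = _region_from_mask(np.ones((10, 10), dtype=bool))
        assert measure_intensity(region, make_slice(img)) == pytest.approx(150 / 255)


class TestInnerCircle:
    def test_uniform_bright_region_has_no_inner(self):
        img = np.full((30, 30), 200)
        region = _region_from_mask(_disc_mask((30, 30), 15, 15, 10))
        assert fit_inner_circle(region, make_slice(img)) is None

    def test_uniform_dim_region_inner_matches_exterior(self):
        img = np.full((40, 40), 100)
        mask = _disc_mask((40, 40), 20, 20, 12)
        region = _region_from_mask(mask)
        inner = fit_inner_circle(region, make_slice(img))
        ext = fit_circle(boundary_pixels(mask))
        assert inner.radius_px == pytest.approx(ext.radius_px + 0.5, abs=1e-9)
        assert inner.center == pytest.approx(ext.center, abs=1e-9)

    def test_phantom_pith_radius_recovered(self, single_stem, circle_cfg):
        spec, slices, truth = single_stem
        traits = analyze_slice(slices[0], circle_cfg)[0]
        assert traits.inner is not None
        assert traits.inner.radius_px == pytest.approx(15, abs=1.0)

    def test_high_threshold_is_175_boundary(self):
        # pixels at exactly 175 qualify; 176 does not
        img = np.full((30, 30), 176)
        img[10:20, 10:20] = 175
        region = _region_from_mask(np.ones((30, 30), dtype=bool))
        inner = fit_inner_circle(region, make_slice(img))
        assert inner is not None
        # the fitted inner disc covers only the 175-valued square
        assert inner.radius_px < 10


class TestPithyFraction:
    def test_no_dark_pixels_zero(self, single_stem):
        img = np.full((30, 30), 100)
        region = _region_from_mask(_disc_mask((30, 30), 15, 15, 10))
        slc = make_slice(img)
        inner = fit_inner_circle(region, slc)
        assert measure_pithy_fraction(region, slc, inner) == 0.0

    def test_all_dark_inner_is_one(self):
        img = np.full((40, 40), 200)
        mask = _disc_mask((40, 40), 20, 20, 15)
        img[_disc_mask((40, 40), 20, 20, 8)] = 0
        region = _region_from_mask(mask)
        slc = make_slice(img)
        inner = fit_inner_circle(region, slc)
        assert measure_pithy_fraction(region, slc, inner) == pytest.approx(1.0)

    def test_phantom_fraction_recovered(self, single_stem, circle_cfg):
        spec, slices, truth = single_stem
        traits = analyze_slice(slices[0], circle_cfg)[0]
        assert traits.pithy_fraction == pytest.approx(
            truth.iloc[0].pithy_fraction, abs=0.02
        )

    def test_dark_threshold_is_strictly_below_20(self):
        img = np.full((40, 40), 100)
        mask = _disc_mask((40, 40), 20, 20, 15)
        inner_m = _disc_mask((40, 40), 20, 20, 8)
        img[inner_m] = 20  # exactly at the threshold: NOT dark
        region = _region_from_mask(mask)
        slc = make_slice(img)
        inner = fit_inner_circle(region, slc)
        assert measure_pithy_fraction(region, slc, inner) == 0.0
        img[inner_m] = 19  # strictly below: dark
        slc = make_slice(img)
        frac = measure_pithy_fraction(region, slc, inner)
        # everything at 100 or below qualifies as interior, so the inner disc
        # is the whole region and the dark fraction is the exact area ratio
        assert frac == pytest.approx(inner_m.sum() / mask.sum())

    def test_monotone_in_dark_threshold(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(40, 40))
        mask = _disc_mask((40, 40), 20, 20, 15)
        region = _region_from_mask(mask)
        slc = make_slice(img)
        inner = fit_inner_circle(region, slc)
        fractions = [
            measure_pithy_fraction(region, slc, inner, dark_threshold=t)
            for t in (0, 10, 20, 60, 120, 176)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestRindArea:
    def test_inner_absent_whole_region_is_rind(self):
        img = np.full((30, 30), 200)
        region = _region_from_mask(_disc_mask((30, 30), 15, 15, 10))
        assert measure_rind_area(region, None, None) == region.area_px

    def test_phantom_annulus_count_recovered(self, single_stem, circle_cfg):
        spec, slices, truth = single_stem
        traits = analyze_slice(slices[0], circle_cfg)[0]
        assert traits.rind_area_px == pytest.approx(
            truth.iloc[0].rind_area_px, rel=0.05
        )


class TestAnalyzeSlice:
    def test_blank_slice_empty(self, circle_cfg):
        assert analyze_slice(make_slice(np.zeros((64, 64))), circle_cfg) == []

    def test_subthreshold_speck_empty(self, circle_cfg):
        img = np.zeros((512, 512))
        img[100:103, 100:103] = 255  # 9 px < 512*512*5e-5 ~ 13 px
        assert analyze_slice(make_slice(img), circle_cfg) == []

    def test_thirty_stem_phantom_diameters_within_one_px(self, circle_cfg):
        spec = sample_platform_spec(seed=77, n_stems=30)
        slices, truth = generate_stack(spec)
        traits = analyze_slice(slices[0], circle_cfg)
        assert len(traits) == 30
        for t in traits:
            d = np.hypot(
                truth.center_row - t.center[0], truth.center_col - t.center[1]
            )
            row = truth.iloc[int(d.idxmin())]
            assert abs(t.diameter_px - row.diameter_px) <= 1.0

    def test_deterministic(self, single_stem, circle_cfg):
        _, slices, _ = single_stem
        a = analyze_slice(slices[0], circle_cfg)
        b = analyze_slice(slices[0], circle_cfg)
        assert len(a) == len(b) == 1
        assert a[0].diameter_px == b[0].diameter_px
        assert a[0].pithy_fraction == b[0].pithy_fraction

    def test_invariants_on_random_phantoms(self, circle_cfg):
        for seed in range(240, 248):
            spec = sample_platform_spec(seed=seed, noise_sd=5.0)
            slices, _ = generate_stack(spec)
            for t in analyze_slice(slices[0], circle_cfg):
                assert 0 <= t.intensity <= 1
                if t.pithy_fraction is not None:
                    assert 0 <= t.pithy_fraction <= 1
                if t.inner is not None:
                    assert t.inner.radius_px <= t.exterior.radius_px + 1e-9
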