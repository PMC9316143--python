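"""Optics equations vs an exact-rational oracle, pixel mapping vs brute force,
ROI crop, star selection, and brightness calibration."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iimdepth as iim

PARAMS = iim.IIMOpticalParams(f_mla=0.125, f_c=30.0, pitch_phi=2.4, g=10.0)


def rational_project(x, y, z, i, j, f_mla, f_c, phi, g):
    """Exact-rational evaluation of the EIA projection, independent of the package."""
    x, y, z = Fraction(x), Fraction(y), Fraction(z)
    f_mla, f_c, phi, g = Fraction(f_mla), Fraction(f_c), Fraction(phi), Fraction(g)
    denom = (g - f_mla) * (z - f_mla)
    xe = (f_mla * f_c * (i * phi - x) - f_c * i * phi * (z - f_mla)) / denom
    ye = (f_mla * f_c * (j * phi - y) - f_c * j * phi * (z - f_mla)) / denom
    return xe, ye


def rational_disparity(i1, j1, i2, j2, z, f_mla, f_c, phi, g):
    z, f_mla, f_c, phi, g = (Fraction(v) for v in (z, f_mla, f_c, phi, g))
    coef = f_mla * f_c * phi / ((g - f_mla) * (z - f_mla))
    return coef * (i2 - i1), coef * (j2 - j1)


class TestProjection:
    def test_matches_rational_oracle(self):
        p = iim.project_point((1.0, 1.0, 5.0), (1, 0), PARAMS)
        xe, ye = rational_project(1, 1, 5, 1, 0, Fraction(1, 8), 30, Fraction(12, 5), 10)
        assert p.x_ei == pytest.approx(float(xe), rel=1e-12)
        assert p.y_ei == pytest.approx(float(ye), rel=1e-12)

    def test_origin_through_central_lens_is_zero(self):
        p = iim.project_point((0.0, 0.0, 5.0), (0, 0), PARAMS)
        assert p.x_ei == 0.0 and p.y_ei == 0.0

    def test_on_axis_point_is_depth_independent(self):
        # x = i·φ makes the first numerator term vanish: X_EI = −f_c·i·φ/(g−f_mla)
        i = 1
        x = i * PARAMS.pitch_phi
        expected = -PARAMS.f_c * i * PARAMS.pitch_phi / (PARAMS.g - PARAMS.f_mla)
        for z in (1.0, 5.0, 100.0):
            p = iim.project_point((x, 0.0, z), (i, 0), PARAMS)
            assert p.x_ei == pytest.approx(expected, rel=1e-12)

    def test_singular_depth_raises(self):
        with pytest.raises(ValueError, match="singular"):
            iim.project_point((0.0, 0.0, PARAMS.f_mla), (0, 0), PARAMS)

    def test_singular_gap_rejected_at_construction(self):
        with pytest.raises(ValueError, match="g == f_mla"):
            iim.IIMOpticalParams(f_mla=10.0, f_c=30.0, pitch_phi=2.4, g=10.0)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.integers(-50, 50), y=st.integers(-50, 50), z=st.integers(1, 200),
        i=st.integers(-10, 10), j=st.integers(-10, 10),
    )
    def test_randomized_rational_agreement(self, x, y, z, i, j):
        p = iim.project_point((float(x), float(y), float(z)), (i, j), PARAMS)
        xe, ye = rational_project(x, y, z, i, j, Fraction(1, 8), 30, Fraction(12, 5), 10)
        assert p.x_ei == pytest.approx(float(xe), rel=1e-12, abs=1e-15)
        assert p.y_ei == pytest.approx(float(ye), rel=1e-12, abs=1e-15)


class TestInterLensDisparity:
    def test_matches_rational_oracle(self):
        dx, dy = iim.disparity_between_lenses((0, 0), (2, 1), 5.0, PARAMS)
        ex, ey = rational_disparity(0, 0, 2, 1, 5, Fraction(1, 8), 30, Fraction(12, 5), 10)
        assert dx == pytest.approx(float(ex), rel=1e-12)
        assert dy == pytest.approx(float(ey), rel=1e-12)

    def test_same_lens_zero(self):
        assert iim.disparity_between_lenses((3, 5), (3, 5), 7.0, PARAMS) == (0.0, 0.0)

    def test_antisymmetric_and_linear(self):
        d1 = iim.disparity_between_lenses((0, 0), (1, 2), 5.0, PARAMS)
        d2 = iim.disparity_between_lenses((1, 2), (0, 0), 5.0, PARAMS)
        d4 = iim.disparity_between_lenses((0, 0), (2, 4), 5.0, PARAMS)
        assert d1[0] == -d2[0] and d1[1] == -d2[1]
        assert d4[0] == pytest.approx(2 * d1[0], rel=1e-12)
        assert d4[1] == pytest.approx(2 * d1[1], rel=1e-12)


def brute_force_eia_to_ovi(image, ly, lx, py, px):
    """Four-nested-loop index permutation, the reference semantics."""
    ch = image.shape[2]
    views = np.zeros((py, px, ly, lx, ch), dtype=image.dtype)
    for a in range(py):
        for b in range(px):
            for r in range(ly):
                for c in range(lx):
                    views[a, b, r, c] = image[r * py + a, c * px + b]
    return views


class TestPixelMapping:
    def test_labeled_2x2_toy_matches_brute_force(self):
        image = (np.arange(16, dtype=np.float32) / 15.0).reshape(4, 4)[:, :, None]
        eia = iim.ElementalImageArray(image, lenses_x=2, lenses_y=2,
                                      px_per_ei_x=2, px_per_ei_y=2)
        lf = iim.eia_to_ovi(eia)
        assert np.array_equal(lf.views, brute_force_eia_to_ovi(eia.image, 2, 2, 2, 2))

    def test_random_grid_matches_brute_force(self, rng):
        image = rng.random((3 * 4, 5 * 2, 3)).astype(np.float32)
        eia = iim.ElementalImageArray(image, lenses_x=5, lenses_y=3,
                                      px_per_ei_x=2, px_per_ei_y=4)
        lf = iim.eia_to_ovi(eia)
        assert np.array_equal(lf.views, brute_force_eia_to_ovi(eia.image, 3, 5, 4, 2))

    def test_single_lens_degenerate(self, rng):
        image = rng.random((3, 3, 3)).astype(np.float32)
        eia = iim.ElementalImageArray(image, lenses_x=1, lenses_y=1,
                                      px_per_ei_x=3, px_per_ei_y=3)
        lf = iim.eia_to_ovi(eia)
        assert (lf.n_rows, lf.n_cols, lf.height, lf.width) == (3, 3, 1, 1)

    def test_is_pixel_permutation(self, rng):
        image = rng.random((4 * 3, 4 * 3, 3)).astype(np.float32)
        eia = iim.ElementalImageArray(image, lenses_x=4, lenses_y=4,
                                      px_per_ei_x=3, px_per_ei_y=3)
        lf = iim.eia_to_ovi(eia)
        assert np.array_equal(np.sort(lf.views.ravel()), np.sort(image.ravel()))

    def test_round_trip_bit_exact(self, rng):
        image = rng.random((5 * 4, 5 * 4, 3)).astype(np.float32)
        eia = iim.ElementalImageArray(image, lenses_x=5, lenses_y=5,
                                      px_per_ei_x=4, px_per_ei_y=4)
        back = iim.ovi_to_eia(iim.eia_to_ovi(eia))
        assert np.array_equal(back.image, eia.image)
        assert (back.lenses_x, back.px_per_ei_x) == (5, 4)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lens grid"):
            iim.ElementalImageArray(np.zeros((10, 10, 3)), lenses_x=3, lenses_y=3,
                                    px_per_ei_x=3, px_per_ei_y=3)


class TestRoiCrop:
    def test_full_grid_identity(self, plane_scene):
        lf = plane_scene.lightfield
        out = iim.crop_roi_views(lf, 9, 9)
        assert np.array_equal(out.views, lf.views)

    def test_centered_odd_to_odd(self):
        lf = iim.LightField(np.zeros((9, 9, 2, 2, 3)))
        lf.views[4, 4] = 0.5
        out = iim.crop_roi_views(lf, 3)
        assert out.views[1, 1, 0, 0, 0] == 0.5

    def test_even_parity_bias_bottom_right(self):
        # 4x4 -> 3x3: margin 1 is odd; extra view dropped from top/left
        lf = iim.LightField((np.arange(16).reshape(4, 4, 1, 1, 1) / 15.0
                             * np.ones((1, 1, 1, 1, 3))))
        out = iim.crop_roi_views(lf, 3)
        expect = lf.views[0:3, 0:3]  # (4-3)//2 == 0 -> keep rows 0..2
        assert np.array_equal(out.views, expect)

    def test_too_large_roi_rejected(self, plane_scene):
        with pytest.raises(ValueError, match="exceeds"):
            iim.crop_roi_views(plane_scene.lightfield, 11)


class TestStarSelection:
    def test_paper_geometry_indices(self):
        lf = iim.LightField(np.zeros((39, 39, 1, 1, 3)))
        stacks = iim.select_star_views(lf, 9, 4)
        assert stacks.indices == [3, 7, 11, 15, 19, 23, 27, 31, 35]

    def test_dense_interval_one_full_arms(self, plane_scene):
        stacks = iim.select_star_views(plane_scene.lightfield, 9, 1)
        assert stacks.indices == list(range(9))
        v = plane_scene.lightfield.views
        assert np.array_equal(stacks.horizontal, v[4, :])
        assert np.array_equal(stacks.vertical, v[:, 4])
        assert np.array_equal(stacks.diagonal, np.stack([v[k, k] for k in range(9)]))
        assert np.array_equal(stacks.antidiagonal, np.stack([v[8 - k, k] for k in range(9)]))

    def test_central_view_is_middle_element(self, plane_scene):
        stacks = iim.select_star_views(plane_scene.lightfield, 9, 1)
        for arm in (stacks.horizontal, stacks.vertical, stacks.diagonal, stacks.antidiagonal):
            assert np.array_equal(arm[4], stacks.center_view)

    def test_span_exceeding_grid_rejected(self):
        lf = iim.LightField(np.zeros((39, 39, 1, 1, 3)))
        with pytest.raises(ValueError, match="41"):
            iim.select_star_views(lf, 9, 5)

    def test_non_square_grid_rejected(self):
        lf = iim.LightField(np.zeros((5, 7, 1, 1, 3)))
        with pytest.raises(ValueError, match="square"):
            iim.select_star_views(lf, 3, 1)

    @settings(deadline=None, max_examples=25)
    @given(side=st.integers(3, 41).filter(lambda s: s % 2 == 1),
           n=st.integers(1, 9).filter(lambda n: n % 2 == 1),
           interval=st.integers(1, 6))
    def test_indices_always_in_bounds(self, side, n, interval):
        lf = iim.LightField(np.zeros((side, side, 1, 1, 3)))
        span = 1 + (n - 1) * interval
        if span > side:
            with pytest.raises(ValueError):
                iim.select_star_views(lf, n, interval)
        else:
            stacks = iim.select_star_views(lf, n, interval)
            assert all(0 <= k < side for k in stacks.indices)


class TestBrightnessCalibration:
    def test_fixed_point_when_already_matched(self, plane_scene):
        stacks = iim.select_star_views(plane_scene.lightfield, 9, 1)
        out = iim.calibrate_brightness(stacks)
        ref = stacks.center_view
        for k in range(9):
            assert out.horizontal[k].mean() == pytest.approx(ref.mean(), abs=1e-3)

    def test_halved_view_regains_reference_mean(self, rng):
        ref = rng.random((16, 16, 3)).astype(np.float32) * 0.5 + 0.25
        stack = np.stack([0.5 * ref])
        out = iim.calibrate_brightness(stack, reference=ref)
        assert out[0].mean() == pytest.approx(ref.mean(), abs=1e-6)
        assert out[0].std() == pytest.approx(ref.std(), abs=1e-6)

    def test_synthetic_vignette_inverted(self, rng):
        ref = (rng.random((24, 24, 3)) * 0.5 + 0.25).astype(np.float32)
        gains = np.linspace(0.7, 1.0, 5)
        stack = np.stack([g * ref for g in gains]).astype(np.float32)
        out = iim.calibrate_brightness(stack, reference=ref)
        for k in range(5):
            assert abs(out[k].mean() - ref.mean()) / ref.mean() < 0.01

    def test_zero_variance_view_offset_only(self, caplog):
        ref = np.random.default_rng(0).random((8, 8, 3)).astype(np.float32)
        flat = np.full((1, 8, 8, 3), 0.2, dtype=np.float32)
        import logging
        with caplog.at_level(logging.WARNING, logger="iimdepth.geometry"):
            out = iim.calibrate_brightness(flat, reference=ref)
        assert out[0].mean() == pytest.approx(ref.mean(), abs=1e-6)
        assert "zero-variance" in caplog.text
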