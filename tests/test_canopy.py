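from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from stripshade.canopy import (
    RasterGrid,
    bimodal_threshold,
    chm,
    exg,
    height_difference,
    interpolate_daily,
    polygon_mask,
    r_squared,
    read_polygons,
    read_raster,
    rmse,
    separate_species,
    strip_height,
    write_polygons,
    write_raster,
)


class TestExg:
    @pytest.mark.parametrize(
        "rgb, expected", [((0, 255, 0), 510), ((100, 100, 100), 0), ((120, 80, 60), -20)]
    )
    def test_pointwise(self, rgb, expected):
        r, g, b = (np.full((2, 2), c) for c in rgb)
        assert np.all(exg(r, g, b) == expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            exg(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))

    def test_negative_digital_numbers_rejected(self):
        with pytest.raises(ValueError):
            exg(np.full((2, 2), -1), np.zeros((2, 2)), np.zeros((2, 2)))


class TestBimodalThreshold:
    def test_separates_two_gaussians(self):
        rng = np.random.default_rng(7)
        values = np.r_[rng.normal(-50, 20, 5000), rng.normal(200, 30, 5000)]
        t = bimodal_threshold(values)
        # threshold must fall in the low-density valley between the modes
        assert 0 < t < 150
        labels = values > t
        truth = np.r_[np.zeros(5000, bool), np.ones(5000, bool)]
        assert (labels == truth).mean() > 0.99

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate|unimodal"):
            bimodal_threshold(np.full(1000, 3.0))

    def test_unimodal_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="unimodal|separated"):
            bimodal_threshold(rng.normal(0, 1, 5000))


class TestChm:
    def test_identical_grids_give_zero(self):
        g = RasterGrid(np.full((4, 4), 101.3), 0.05)
        assert np.all(chm(g, g).data == 0)

    def test_constant_offset(self):
        ref = RasterGrid(np.full((4, 4), 100.0), 0.05)
        dsm = RasterGrid(ref.data + 1.2, 0.05)
        assert np.allclose(chm(dsm, ref).data, 1.2)

    def test_negatives_clipped(self):
        ref = RasterGrid(np.full((2, 2), 100.0), 0.05)
        dsm = RasterGrid(np.full((2, 2), 99.5), 0.05)
        assert np.all(chm(dsm, ref).data == 0.0)

    def test_mismatch_rejected(self):
        ref = RasterGrid(np.zeros((4, 4)), 0.05)
        with pytest.raises(ValueError):
            chm(RasterGrid(np.zeros((4, 5)), 0.05), ref)
        with pytest.raises(ValueError):
            chm(RasterGrid(np.zeros((4, 4)), 0.10), ref)


class TestSeparateSpecies:
    def test_threshold_split(self):
        maize, soy = separate_species(np.array([0.6, 0.8, 1.4, 1.6]), 1.0)
        assert sorted(soy) == [0.6, 0.8]
        assert sorted(maize) == [1.4, 1.6]

    def test_empty_class_warns(self):
        with pytest.warns(UserWarning, match="empty class"):
            separate_species(np.array([0.1, 0.2]), 1.0)


class TestStripHeight:
    def test_constant_field(self):
        v = np.full(100, 1.5)
        assert strip_height(v, "maize") == 1.5
        assert strip_height(v, "soybean") == 1.5

    def test_uniform_grid_soybean_percentile(self):
        v = np.linspace(0.0, 1.0, 1001)
        assert strip_height(v, "soybean") == pytest.approx(0.90)

    def test_monotone_in_added_pixels(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 1.5, 500)
        base = strip_height(v, "soybean")
        assert strip_height(np.r_[v, 2.5], "soybean") >= base

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            strip_height(np.array([]), "maize")
        with pytest.raises(ValueError, match="crop"):
            strip_height(np.ones(5), "wheat")


class TestInterpolateDaily:
    DATES = [date(2021, 7, 5), date(2021, 7, 12), date(2021, 7, 20), date(2021, 7, 28)]

    def test_collinear_points_give_the_line(self):
        days = np.array([(d - self.DATES[0]).days for d in self.DATES], dtype=float)
        s = interpolate_daily(self.DATES, 0.5 + 0.02 * days)
        grid = np.arange(days[-1] + 1)
        assert np.allclose(s.to_numpy(), 0.5 + 0.02 * grid, atol=1e-9)

    def test_passes_through_measurements(self):
        h = np.array([0.4, 0.9, 1.0, 1.3])
        s = interpolate_daily(self.DATES, h)
        for d, v in zip(self.DATES, h):
            assert s.loc[pd.Timestamp(d)] == pytest.approx(v, abs=1e-12)

    def test_recovers_generating_values_between_knots(self):
        # a natural cubic spline reproduces a quadratic with zero end-curvature
        # trend closely; check against the generating polynomial at mid-days
        days = np.array([0.0, 7.0, 15.0, 23.0])
        f = lambda t: 0.5 + 0.04 * t
        s = interpolate_daily(self.DATES, f(days))
        assert s.loc[pd.Timestamp(self.DATES[0]) + pd.Timedelta(days=11)] == pytest.approx(
            f(11.0), abs=1e-9
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            interpolate_daily(self.DATES[:2], np.array([0.4, 0.9]))


class TestHeightDifference:
    def _series(self, values):
        idx = pd.date_range("2021-07-05", periods=len(values))
        return pd.Series(values, index=idx)

    def test_equal_heights_give_zero(self):
        m = self._series([1.0, 1.0, 1.0])
        out = height_difference(m, m, m)
        assert (out.north == 0).all() and (out.south == 0).all()

    def test_simple_difference(self):
        m = self._series([1.9] * 3)
        s = self._series([0.8] * 3)
        out = height_difference(m, m, s)
        assert np.allclose(out.north, 1.1)

    def test_negative_clipped_with_warning(self):
        m = self._series([0.5] * 3)
        s = self._series([0.8] * 3)
        with pytest.warns(UserWarning, match="clipped"):
            out = height_difference(m, m, s)
        assert (out.north == 0).all()

    def test_misaligned_dates_rejected(self):
        m = self._series([1.0] * 3)
        s = pd.Series([0.5] * 3, index=pd.date_range("2021-07-06", periods=3))
        with pytest.raises(ValueError, match="aligned"):
            height_difference(m, m, s)


class TestFitStatistics:
    def test_perfect_agreement(self):
        x = np.array([0.5, 1.0, 1.5])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert rmse(x, x) == 0.0

    def test_constant_offset_rmse(self):
        x = np.array([0.5, 1.0, 1.5])
        assert rmse(x + 0.1, x) == pytest.approx(0.1)

    def test_hand_computed_vector(self):
        est = np.array([1.1, 1.9, 3.2])
        meas = np.array([1.0, 2.0, 3.0])
        assert r_squared(est, meas) == pytest.approx(1.13, abs=1e-9)
        assert rmse(est, meas) == pytest.approx(np.sqrt(0.06 / 3), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.array([1.0, 2.0]), np.array([1.5, 1.5]))


class TestRasterVectorIO:
    def test_raster_round_trip(self, tmp_path):
        grid = RasterGrid(np.arange(12, dtype=np.float32).reshape(3, 4), 0.05, (1.0, 2.0))
        write_raster(tmp_path / "g.tif", grid)
        back = read_raster(tmp_path / "g.tif")
        assert np.array_equal(back.data, grid.data)
        assert back.pixel_size == grid.pixel_size and back.origin == grid.origin

    def test_polygon_round_trip(self, tmp_path):
        polys = {"soybean": box(0, 0, 2, 1), "maize_north": box(0, 1.5, 2, 2.5)}
        write_polygons(tmp_path / "p.geojson", polys)
        back = read_polygons(tmp_path / "p.geojson")
        assert set(back) == set(polys)
        assert back["soybean"].equals(polys["soybean"])

    def test_polygon_mask_selects_pixel_centers(self):
        grid = RasterGrid(np.zeros((4, 4)), 1.0, (0.0, 4.0))  # 4x4 m scene
        mask = polygon_mask(grid, box(0, 0, 4, 2))  # southern half
        assert mask.sum() == 8
        assert mask[2:, :].all() and not mask[:2, :].any()
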