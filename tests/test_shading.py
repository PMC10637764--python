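from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from stripshade.layout import StripLayout, RowGeometry, row_distances
from stripshade.shading import (
    DailyShadingResult,
    ShadingInterval,
    aggregate_strip,
    cumulate,
    daily_intervals,
    shading_capacity,
    shading_distance,
    shading_proportion,
    simulate_day,
    simulate_period,
)
from stripshade.solar import day_context

from .oracles import random_interval_set, riemann_sp

SITE = 43.267
MIDSUMMER = date(2021, 7, 20)


class TestShadingDistance:
    def test_no_height_no_shadow(self):
        assert shading_distance(0.0, 45.0, 120.0, 59.0) == 0.0

    def test_sun_parallel_to_rows(self):
        # beta + gamma - 90 = 90 puts the sun along the row axis
        assert shading_distance(1.0, 45.0, 121.0, 59.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_geometry(self):
        # tan(45) = 1 and a sun perpendicular to the rows: D_s = H_ms
        assert shading_distance(1.0, 45.0, 31.0, 59.0) == pytest.approx(1.0)

    def test_sun_below_horizon_is_sentinel(self):
        assert np.isnan(shading_distance(1.0, -5.0, 90.0, 59.0))

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            shading_distance(-0.5, 45.0, 90.0, 59.0)

    def test_noon_north_south_rows_no_cross_row_shadow(self):
        # at solar noon (beta = 180) with N-S rows the shadow runs along them
        assert shading_distance(1.5, 60.0, 180.0, 0.0) == pytest.approx(0.0, abs=1e-12)


class TestDailyIntervals:
    def test_no_height_no_intervals(self, midsummer_ctx, layout_2m3s):
        row = row_distances(layout_2m3s)[0]
        assert daily_intervals(midsummer_ctx, row, layout_2m3s, 0.0, 0.0) == []

    def test_row_at_origin_shaded_all_daylight(self, midsummer_ctx, layout_2m3s):
        row = RowGeometry(1, d_mr_south_source=1e-9, d_mr_north_source=1e-9, width=0.6)
        ivs = daily_intervals(midsummer_ctx, row, layout_2m3s, 1.0, 1.0)
        total = sum(iv.duration for iv in ivs)
        assert total == pytest.approx(midsummer_ctx.max_sunshine_duration, abs=0.1)

    def test_r1_pattern_and_finer_step_oracle(self, midsummer_ctx, layout_2m3s):
        # R1 mid-season: morning shading from the northern strip, a late
        # interval from the southern strip
        row = row_distances(layout_2m3s)[0]
        ivs = daily_intervals(midsummer_ctx, row, layout_2m3s, 1.2, 1.2, step_minutes=1.0)
        sources = [iv.source for iv in ivs]
        assert sources[0] == "north" and sources[-1] == "south"
        fine = daily_intervals(midsummer_ctx, row, layout_2m3s, 1.2, 1.2, step_minutes=1 / 60)
        assert len(fine) == len(ivs)
        for a, b in zip(ivs, fine):
            assert a.source == b.source
            assert a.start == pytest.approx(b.start, abs=2 / 60)
            assert a.end == pytest.approx(b.end, abs=2 / 60)

    def test_interval_invariants(self, midsummer_ctx, layout_2m3s):
        for row in row_distances(layout_2m3s):
            ivs = daily_intervals(midsummer_ctx, row, layout_2m3s, 1.0, 1.0)
            for iv in ivs:
                assert midsummer_ctx.sunrise_lst - 1e-9 <= iv.start < iv.end
                assert iv.end <= midsummer_ctx.sunset_lst + 1e-9
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start + 1e-12

    def test_nesting_of_closer_rows(self, midsummer_ctx, layout_2m3s):
        # a row strictly closer to both origins is shaded whenever a farther
        # row is shaded
        near = RowGeometry(1, 0.3, 0.3, 0.6)
        far = RowGeometry(2, 0.9, 0.9, 0.6)
        ivs_near = daily_intervals(midsummer_ctx, near, layout_2m3s, 1.2, 1.2)
        ivs_far = daily_intervals(midsummer_ctx, far, layout_2m3s, 1.2, 1.2)
        grid = np.linspace(midsummer_ctx.sunrise_lst, midsummer_ctx.sunset_lst, 2000)

        def covered(ivs):
            return np.any([(grid >= iv.start) & (grid <= iv.end) for iv in ivs], axis=0)

        far_mask, near_mask = covered(ivs_far), covered(ivs_near)
        assert np.all(near_mask[far_mask])


class TestShadingProportion:
    def test_no_intervals(self, midsummer_ctx):
        assert shading_proportion([], midsummer_ctx) == 0.0

    def test_full_daylight_is_one(self, midsummer_ctx):
        iv = ShadingInterval(midsummer_ctx.sunrise_lst, midsummer_ctx.sunset_lst, "north")
        assert shading_proportion([iv], midsummer_ctx) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_halves_sum_to_one(self, midsummer_ctx):
        am = ShadingInterval(midsummer_ctx.sunrise_lst, 12.0, "north")
        pm = ShadingInterval(12.0, midsummer_ctx.sunset_lst, "south")
        total = shading_proportion([am], midsummer_ctx) + shading_proportion([pm], midsummer_ctx)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_intervals_rejected(self, midsummer_ctx):
        ivs = [ShadingInterval(8.0, 11.0, "north"), ShadingInterval(10.0, 13.0, "south")]
        with pytest.raises(ValueError, match="overlap"):
            shading_proportion(ivs, midsummer_ctx)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_riemann_oracle(self, midsummer_ctx, seed):
        rng = np.random.default_rng(seed)
        ivs = random_interval_set(midsummer_ctx, rng)
        closed = shading_proportion(ivs, midsummer_ctx)
        assert closed == pytest.approx(riemann_sp(ivs, midsummer_ctx), abs=1e-3)

    def test_monotone_in_h_ms(self, midsummer_ctx, layout_2m3s):
        # per-row SP never decreases as the canopy-height difference grows
        for row in row_distances(layout_2m3s):
            sps = []
            for h in np.linspace(0.0, 3.0, 13):
                ivs = daily_intervals(midsummer_ctx, row, layout_2m3s, h, h)
                sps.append(shading_proportion(ivs, midsummer_ctx))
            assert all(b >= a - 1e-12 for a, b in zip(sps, sps[1:]))


class TestCapacityAndAggregation:
    @pytest.mark.parametrize("sp, ra, expected", [(0.0, 20.0, 0.0), (1.0, 17.5, 17.5), (0.5, 20.0, 10.0)])
    def test_product(self, sp, ra, expected):
        assert shading_capacity(sp, ra) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            shading_capacity(1.2, 10.0)
        with pytest.raises(ValueError):
            shading_capacity(0.5, -1.0)

    def test_equal_widths_give_mean(self):
        assert aggregate_strip([0.5, 0.2, 0.3], [0.6, 0.6, 0.6]) == pytest.approx(1 / 3)

    def test_single_row_identity(self):
        assert aggregate_strip([0.42], [0.6]) == pytest.approx(0.42)

    def test_weighting(self):
        assert aggregate_strip([1.0, 0.0], [3.0, 1.0]) == pytest.approx(0.75)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_strip([0.5, 0.2], [0.6])


class TestCumulate:
    def _result(self, d, row=1, sc=4.0):
        return DailyShadingResult(row, d, (), 0.0, 0.25, sc)

    def test_single_day(self):
        table = cumulate([self._result(MIDSUMMER)], pd.DataFrame([{"date": MIDSUMMER, "SP_strip": 0.25, "SC_strip": 4.0}]))
        assert table.csc_per_row.loc[1] == 4.0
        assert table.overall_csc == 4.0

    def test_constant_month(self):
        days = [MIDSUMMER + timedelta(days=k) for k in range(30)]
        daily = [self._result(d) for d in days]
        strip = pd.DataFrame([{"date": d, "SP_strip": 0.25, "SC_strip": 4.0} for d in days])
        table = cumulate(daily, strip)
        assert table.csc_per_row.loc[1] == pytest.approx(120.0)
        assert table.overall_csc == pytest.approx(120.0)

    def test_gap_rejected(self):
        days = [MIDSUMMER, MIDSUMMER + timedelta(days=2)]
        strip = pd.DataFrame([{"date": d, "SP_strip": 0, "SC_strip": 0} for d in days])
        with pytest.raises(ValueError, match="missing dates"):
            cumulate([self._result(d) for d in days], strip)


class TestSimulate:
    def test_zero_height_season_gives_zero_csc(self, layout_2m3s, growth_hms):
        hms = growth_hms * 0.0
        ra = pd.Series(15.0, index=hms.index)
        table = simulate_period(layout_2m3s, hms, ra)
        assert (table.csc_per_row == 0).all()
        assert table.overall_csc == 0.0

    def test_strip_values_are_row_means(self, layout_2m3s):
        results, sp_strip, sc_strip = simulate_day(MIDSUMMER, layout_2m3s, 1.2, 1.2, 17.0)
        assert sp_strip == pytest.approx(np.mean([r.sp for r in results]))
        assert sc_strip == pytest.approx(np.mean([r.sc for r in results]))
        for r in results:
            assert r.sc == pytest.approx(r.sp * 17.0)

    def test_missing_radiation_rejected(self, layout_2m3s, growth_hms):
        ra = pd.Series(15.0, index=growth_hms.index[:-2])
        with pytest.raises(ValueError, match="missing"):
            simulate_period(layout_2m3s, growth_hms, ra)
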