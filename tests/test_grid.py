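"""Gridded products: remapping, resampling, aggregation, encoding, trends."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from tllue.grid import (GridSpec, ProductSpec, aggregate_products, decode_int16,
                        eight_day_period_start, encode_int16,
                        interpolate_lai_daily, pixel_trend, product_filename,
                        read_product, remap_landcover, resample_nearest,
                        write_manifest, write_product)


def toy_raster(values, lats=None, lons=None):
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    lats = np.linspace(50, 40, ny) if lats is None else lats
    lons = np.linspace(-10, 0, nx) if lons is None else lons
    return xr.DataArray(values, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"))


class TestLandcoverRemap:
    def test_water_maps_to_nonvegetated(self):
        out = remap_landcover(np.full((3, 3), 210))
        from tllue.grid import igbp_to_pft
        assert np.all(igbp_to_pft(out) == None)  # noqa: E711

    def test_cropland_uniform(self):
        out = remap_landcover(np.full((2, 2), 10))
        assert np.all(out == 12)  # IGBP CRO

    def test_mixed_toy_raster_matches_hand_lookup(self):
        codes = np.array([[50, 70], [130, 255]])
        out = remap_landcover(codes)
        assert out[0, 0] == 2   # broadleaf evergreen -> EBF
        assert out[0, 1] == 1   # needleleaf evergreen -> ENF
        assert out[1, 0] == 10  # grassland -> GRA
        assert out[1, 1] == 0   # unknown code -> nodata

    def test_no_invented_classes(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([10, 50, 90, 130, 210], size=(10, 10))
        out = remap_landcover(codes)
        assert set(np.unique(out)) <= {12, 2, 5, 10, 17}


class TestResample:
    def test_identity_target(self):
        src = toy_raster(np.arange(16.0).reshape(4, 4),
                         lats=np.array([3.5, 2.5, 1.5, 0.5]),
                         lons=np.array([0.5, 1.5, 2.5, 3.5]))
        tgt = GridSpec(resolution=1.0, lon_min=0, lon_max=4, lat_min=0, lat_max=4)
        out = resample_nearest(src, tgt)
        assert np.array_equal(out.values, src.values)

    def test_two_by_two_to_single_cell(self):
        src = toy_raster(np.array([[1.0, 2.0], [3.0, 4.0]]),
                         lats=np.array([1.5, 0.5]), lons=np.array([0.5, 1.5]))
        tgt = GridSpec(resolution=2.0, lon_min=0, lon_max=2, lat_min=0, lat_max=2)
        out = resample_nearest(src, tgt)
        assert out.shape == (1, 1)
        assert out.values[0, 0] in {1.0, 2.0, 3.0, 4.0}

    def test_matches_bruteforce_nearest_center(self):
        rng = np.random.default_rng(8)
        src_lats = np.arange(49.96365, 48.0, -0.0727)
        src_lons = np.arange(10.03635, 12.0, 0.0727)
        vals = rng.integers(0, 5, size=(len(src_lats), len(src_lons))).astype(float)
        src = toy_raster(vals, lats=src_lats, lons=src_lons)
        tgt = GridSpec(resolution=0.05, lon_min=10.2, lon_max=10.7,
                       lat_min=48.5, lat_max=49.0)
        out = resample_nearest(src, tgt)
        for i, la in enumerate(tgt.lats):
            for j, lo in enumerate(tgt.lons):
                bi = np.argmin(np.abs(src_lats - la))
                bj = np.argmin(np.abs(src_lons - lo))
                assert out.values[i, j] == vals[bi, bj]

    def test_categorical_preserved(self):
        src = toy_raster(np.array([[1.0, 7.0], [9.0, 12.0]]))
        tgt = GridSpec(resolution=2.5, lon_min=-10, lon_max=0, lat_min=40, lat_max=50)
        out = resample_nearest(src, tgt)
        assert set(np.unique(out.values)) <= {1.0, 7.0, 9.0, 12.0}


class TestLaiInterpolation:
    def _stack(self, values, days):
        time = pd.to_datetime([f"2005-01-{d:02d}" for d in days])
        arr = np.array(values, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        return xr.DataArray(arr, coords={"time": time, "lat": [1.0, 0.0],
                                         "lon": [0.0, 1.0]},
                            dims=("time", "lat", "lon"))

    def test_constant_series(self):
        lai = self._stack([2.0, 2.0], [1, 17])
        out = interpolate_lai_daily(lai, pd.date_range("2005-01-01", "2005-01-17"))
        assert np.allclose(out.values, 2.0)

    def test_midpoint_linear(self):
        lai = self._stack([2.0, 4.0], [1, 17])
        out = interpolate_lai_daily(lai, pd.date_range("2005-01-01", "2005-01-17"))
        assert np.allclose(out.sel(time="2005-01-09").values, 3.0)

    def test_endpoints_held_constant(self):
        lai = self._stack([2.0, 4.0], [5, 13])
        out = interpolate_lai_daily(lai, pd.date_range("2005-01-01", "2005-01-20"))
        assert np.allclose(out.sel(time="2005-01-02").values, 2.0)
        assert np.allclose(out.sel(time="2005-01-19").values, 4.0)

    def test_irregular_stamps_match_numpy_interp(self):
        days = [2, 9, 11, 25]
        vals = [1.0, 3.0, 2.0, 5.0]
        lai = self._stack(vals, days)
        dates = pd.date_range("2005-01-02", "2005-01-25")
        out = interpolate_lai_daily(lai, dates)
        want = np.interp(dates.day.to_numpy(float), days, vals)
        assert np.allclose(out.values[:, 0, 0], want)


def daily_stack(values, start="2004-01-01"):
    n = values.shape[0]
    time = pd.date_range(start, periods=n, freq="D")
    return xr.DataArray(values, coords={"time": time, "lat": [1.0, 0.0],
                                        "lon": [0.0, 1.0]},
                        dims=("time", "lat", "lon"))


class TestAggregation:
    def test_eight_day_period_starts(self):
        assert list(eight_day_period_start(np.array([1, 8, 9, 16, 17, 361, 366]))) == \
            [1, 1, 9, 9, 17, 361, 361]

    def test_all_zero_days(self):
        daily = daily_stack(np.zeros((366, 2, 2)))
        for cadence in ("8day", "monthly", "annual"):
            agg = aggregate_products(daily, cadence)
            assert float(np.abs(agg).max()) == 0.0

    def test_constant_month_sum(self):
        daily = daily_stack(np.ones((31, 2, 2)), start="2005-01-01")
        monthly = aggregate_products(daily, "monthly")
        assert np.allclose(monthly.isel(time=0).values, 31.0)

    def test_temporal_additivity(self):
        rng = np.random.default_rng(17)
        daily = daily_stack(rng.uniform(0, 12, size=(365, 2, 2)), "2005-01-01")
        annual = aggregate_products(daily, "annual")
        monthly = aggregate_products(daily, "monthly")
        eight = aggregate_products(daily, "8day")
        assert np.allclose(annual.isel(time=0).values,
                           monthly.sum("time").values, rtol=1e-12)
        assert np.allclose(annual.isel(time=0).values,
                           eight.sum("period").values, rtol=1e-12)
        # MODIS-style grid: 46 periods, last one short (5 days in 2005)
        assert eight.sizes["period"] == 46


class TestEncoding:
    def test_round_half_away_from_zero(self):
        spec = ProductSpec("GPP", "monthly")
        stored = encode_int16(np.array([[123.45, -123.45], [0.05, -0.05]]),
                              spec.scale_factor)
        assert stored[0, 0] == 1235 and stored[0, 1] == -1235
        assert stored[1, 0] == 1 and stored[1, 1] == -1

    def test_round_trip_within_half_quantum(self):
        rng = np.random.default_rng(21)
        for cadence, quantum in (("monthly", 0.1), ("8day", 0.01)):
            spec = ProductSpec("GPP", cadence)
            vals = rng.uniform(0, 300, size=(5, 5))
            back = decode_int16(encode_int16(vals, spec.scale_factor),
                                spec.scale_factor)
            assert np.max(np.abs(back - vals)) <= quantum / 2 + 1e-12

    def test_overflow_names_pixel(self):
        with pytest.raises(OverflowError, match="pixel"):
            encode_int16(np.array([[1e6]]), 0.01)

    def test_nan_becomes_nodata(self):
        stored = encode_int16(np.array([[np.nan, 1.0]]), 0.1)
        assert stored[0, 0] == -32768


class TestProductFiles:
    @pytest.mark.parametrize("var,cadence,year,period,expected", [
        ("GPP", "annual", 1999, None, "GPP_v21_1999.tif"),
        ("Shade_GPP", "8day", 1999, 249, "Shade_GPP_v21_1999_249.tif"),
        ("Sun_GPP", "monthly", 1999, 1, "Sun_GPP_v21_1999_01.tif"),
    ])
    def test_archive_naming(self, var, cadence, year, period, expected):
        assert product_filename(var, cadence, year, period) == expected

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        raster = toy_raster(rng.uniform(0, 250, size=(6, 8)))
        spec = ProductSpec("GPP", "monthly")
        path = write_product(raster, spec, 2005, 7, tmp_path)
        assert path.name == "GPP_v21_2005_07.tif"
        back = read_product(path, spec)
        assert np.max(np.abs(back.values - raster.values)) <= 0.05 + 1e-12
        assert np.allclose(back["lat"].values, raster["lat"].values)
        assert np.allclose(back["lon"].values, raster["lon"].values)

    def test_annual_written_as_double(self, tmp_path):
        raster = toy_raster(np.full((3, 3), 1234.5678))
        spec = ProductSpec("GPP", "annual")
        path = write_product(raster, spec, 2005, None, tmp_path)
        back = read_product(path, spec)
        assert np.array_equal(back.values, raster.values)

    def test_manifest_lists_checksums(self, tmp_path):
        raster = toy_raster(np.ones((2, 2)))
        spec = ProductSpec("GPP", "annual")
        p = write_product(raster, spec, 2001, None, tmp_path)
        manifest = write_manifest([p], tmp_path / "manifest.json")
        import json
        entries = json.loads(manifest.read_text())
        assert "GPP_v21_2001.tif" in entries
        assert len(entries["GPP_v21_2001.tif"]) == 64


class TestPixelTrend:
    def _annual(self, values, years):
        return xr.DataArray(values, coords={"year": np.asarray(years, float),
                                            "lat": [1.0, 0.0], "lon": [0.0, 1.0]},
                            dims=("year", "lat", "lon"))

    def test_perfect_linear_trend_retained(self):
        years = np.arange(2000, 2010)
        vals = 100.0 + 20.0 * (years - 2000)[:, None, None] * np.ones((1, 2, 2))
        slope, pval, mask = pixel_trend(self._annual(vals, years))
        assert np.allclose(slope.values, 20.0)
        assert mask.values.all()

    def test_five_point_closed_form(self):
        years = np.array([2000, 2001, 2002, 2003, 2004])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vals = y[:, None, None] * np.ones((1, 2, 2))
        slope, pval, _ = pixel_trend(self._annual(vals, years))
        from scipy import stats
        lr = stats.linregress(years, y)
        assert slope.values[0, 0] == pytest.approx(lr.slope, rel=1e-12)
        assert pval.values[0, 0] == pytest.approx(lr.pvalue, rel=1e-10)

    def test_constant_series_masked(self):
        years = np.arange(2000, 2006)
        vals = np.full((6, 2, 2), 7.0)
        slope, _, mask = pixel_trend(self._annual(vals, years))
        assert np.allclose(slope.values, 0.0)
        assert not mask.values.any()

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(55)
        years = np.arange(2000, 2015)
        vals = rng.normal(0, 1, size=(len(years), 100, 100))
        da = xr.DataArray(vals, coords={"year": years.astype(float),
                                        "lat": np.arange(100.0),
                                        "lon": np.arange(100.0)},
                          dims=("year", "lat", "lon"))
        _, _, mask = pixel_trend(da)
        rate = mask.values.mean()
        assert abs(rate - 0.05) < 0.01
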