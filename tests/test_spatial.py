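"""Raster I/O, per-cell projection, classification, exposure summaries."""

import numpy as np
import pandas as pd
import pytest

from mycotherm import (
    FIG5_VIRULENCE,
    ClimateGrid,
    MonthlyStack,
    classify_performance,
    hours_in_ranges,
    project_response,
    read_grid,
    write_ascii_grid,
    write_flt_grid,
)
from mycotherm.spatial import (
    DEFAULT_MONTHS,
    GridDimensionError,
    GridParseError,
    UnsupportedDialectError,
    daily_hours_in_ranges,
    read_monthly_stack,
)

# Frozen hand evaluation of the virulence curve at its optimum (28.1 C),
# expressed as percent mortality.
PERCENT_AT_OPT = 74.35444


def uniform_stack(temp_mid, nrows=4, ncols=5, diurnal=4.0):
    geo = dict(cellsize=0.5, xllcorner=-50.0, yllcorner=-20.0)
    tmin = {m: ClimateGrid(values=np.full((nrows, ncols), temp_mid - diurnal / 2), **geo)
            for m in range(1, 13)}
    tmax = {m: ClimateGrid(values=np.full((nrows, ncols), temp_mid + diurnal / 2), **geo)
            for m in range(1, 13)}
    return MonthlyStack(tmin=tmin, tmax=tmax)


class TestAsciiGridIO:
    def grid(self):
        vals = np.array([[21.5, 22.25], [np.nan, 30.125]])
        return ClimateGrid(values=vals, cellsize=0.25, xllcorner=-51.0,
                           yllcorner=-15.5, nodata=-9999.0)

    def test_round_trip_preserves_geometry_and_values(self, tmp_path):
        g = self.grid()
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        back = read_grid(path)
        assert back.same_geometry(g)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)

    def test_nodata_cell_flagged(self, tmp_path):
        path = tmp_path / "g.asc"
        write_ascii_grid(self.grid(), path)
        back = read_grid(path)
        assert np.isnan(back.values[1, 0])
        assert "NODATA_value -9999" in path.read_text()

    def test_header_order_and_decimal_separator(self, tmp_path):
        path = tmp_path / "g.asc"
        write_ascii_grid(self.grid(), path)
        lines = path.read_text().splitlines()
        keys = [l.split()[0].lower() for l in lines[:6]]
        assert keys == ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                        "nodata_value"]
        assert "," not in path.read_text()

    def test_malformed_header_reports_key(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols two\nnrows 2\n")
        with pytest.raises(GridParseError, match="ncols"):
            read_grid(path)

    def test_row_length_mismatch(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n4 5\n"
        )
        with pytest.raises(GridDimensionError):
            read_grid(path)


class TestFlatBinaryIO:
    def test_round_trip(self, tmp_path):
        vals = np.array([[1.5, -3.25, 7.0], [np.nan, 0.0, 28.125]])
        g = ClimateGrid(values=vals, cellsize=0.1, xllcorner=-45.0, yllcorner=-30.0)
        path = tmp_path / "g.flt"
        write_flt_grid(g, path)
        back = read_grid(path)
        assert back.same_geometry(g)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-6)

    def test_big_endian_rejected_explicitly(self, tmp_path):
        path = tmp_path / "g.flt"
        np.zeros(4, dtype="<f4").tofile(path)
        path.with_suffix(".hdr").write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\nBYTEORDER MSBFIRST\n"
        )
        with pytest.raises(UnsupportedDialectError):
            read_grid(path)

    def test_payload_size_mismatch(self, tmp_path):
        path = tmp_path / "g.flt"
        np.zeros(3, dtype="<f4").tofile(path)
        path.with_suffix(".hdr").write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
        )
        with pytest.raises(GridDimensionError):
            read_grid(path)


class TestProjectResponse:
    def test_uniform_optimum_midpoint(self):
        stack = uniform_stack(28.1)
        perf = project_response(stack, FIG5_VIRULENCE)
        np.testing.assert_allclose(perf.mortality.values, PERCENT_AT_OPT, atol=1e-3)

    def test_uniform_at_lower_cardinal_zero(self):
        stack = uniform_stack(16.502, diurnal=0.0)
        perf = project_response(stack, FIG5_VIRULENCE)
        np.testing.assert_allclose(perf.mortality.values, 0.0, atol=1e-12)

    def test_nodata_propagates_from_any_layer(self):
        stack = uniform_stack(28.1)
        month = DEFAULT_MONTHS[0]
        vals = stack.tmax[month].values.copy()
        vals[1, 2] = np.nan
        tmax = dict(stack.tmax)
        tmax[month] = ClimateGrid(values=vals, cellsize=stack.geometry.cellsize,
                                  xllcorner=stack.geometry.xllcorner,
                                  yllcorner=stack.geometry.yllcorner)
        perf = project_response(MonthlyStack(tmin=stack.tmin, tmax=tmax),
                                FIG5_VIRULENCE)
        assert np.isnan(perf.mortality.values[1, 2])
        assert np.isfinite(perf.mortality.values[0, 0])

    def test_policies_differ_on_asymmetric_response(self):
        stack = uniform_stack(24.0, diurnal=10.0)  # evaluates at 19, 24, 29
        p_mid = project_response(stack, FIG5_VIRULENCE, policy="midpoint")
        p_min = project_response(stack, FIG5_VIRULENCE, policy="min")
        p_max = project_response(stack, FIG5_VIRULENCE, policy="max")
        p_two = project_response(stack, FIG5_VIRULENCE, policy="mean_of_two")
        assert p_min.mortality.values[0, 0] < p_mid.mortality.values[0, 0]
        assert p_max.mortality.values[0, 0] > p_mid.mortality.values[0, 0]
        expected_two = (p_min.mortality.values + p_max.mortality.values) / 2
        np.testing.assert_allclose(p_two.mortality.values, expected_two, atol=1e-9)

    def test_warming_toward_optimum_never_decreases_mortality(self):
        # monotone response below T_opt implies a monotone map
        cool = project_response(uniform_stack(22.0), FIG5_VIRULENCE)
        warm = project_response(uniform_stack(25.0), FIG5_VIRULENCE)
        assert np.all(warm.mortality.values >= cool.mortality.values)

    def test_percent_capped_at_100(self):
        from mycotherm import ThermalModelParams
        hot = ThermalModelParams(model_id="ratkowsky1", cc=50.0, k1=0.084,
                                 k2=0.09, T1=16.502, T2=36.051)
        perf = project_response(uniform_stack(28.0), hot)
        assert np.all(perf.mortality.values <= 100.0)

    def test_empty_months_rejected(self):
        with pytest.raises(ValueError):
            project_response(uniform_stack(28.0), FIG5_VIRULENCE, months=())


class TestClassifyPerformance:
    def classified(self, percent):
        vals = np.array([[percent]])
        grid = ClimateGrid(values=vals, cellsize=1.0, xllcorner=0.0, yllcorner=0.0)
        from mycotherm.spatial import PerformanceMap
        return classify_performance(PerformanceMap(mortality=grid))

    @pytest.mark.parametrize(
        "percent,label",
        [(5.0, "low"), (15.0, "moderate"), (30.0, "high"), (70.0, "very high"),
         (10.0, "moderate"), (25.0, "high"), (60.0, "very high")],
    )
    def test_band_assignment_half_open(self, percent, label):
        perf = self.classified(percent)
        assert perf.class_labels[perf.classes[0, 0]] == label

    def test_partition_every_valid_cell_one_class(self, rng):
        vals = rng.uniform(0, 100, size=(20, 20))
        vals[0, 0] = np.nan
        grid = ClimateGrid(values=vals, cellsize=1.0, xllcorner=0.0, yllcorner=0.0)
        from mycotherm.spatial import PerformanceMap
        perf = classify_performance(PerformanceMap(mortality=grid))
        valid = ~np.isnan(vals)
        assert np.all((perf.classes[valid] >= 0) & (perf.classes[valid] <= 3))
        assert perf.classes[0, 0] == -1

    def test_non_monotone_edges_rejected(self):
        from mycotherm.spatial import PerformanceMap
        grid = ClimateGrid(values=np.array([[50.0]]), cellsize=1.0,
                           xllcorner=0.0, yllcorner=0.0)
        with pytest.raises(ValueError):
            classify_performance(PerformanceMap(mortality=grid), edges=(25, 10, 60),
                                 labels=("a", "b", "c", "d"))


class TestHoursInRanges:
    def series(self, temps, start="2017-01-01"):
        idx = pd.date_range(start, periods=len(temps), freq="h")
        return pd.Series(temps, index=idx)

    def test_constant_day_in_single_band(self):
        table = daily_hours_in_ranges(self.series([22.0] * 24))
        assert table.iloc[0]["(20,25]"] == 24
        assert table.iloc[0].drop("(20,25]").sum() == 0

    def test_edge_reading_counted_in_lower_band(self):
        table = daily_hours_in_ranges(self.series([15.0]))
        assert table.iloc[0]["<=15"] == 1

    def test_extreme_band_six_hour_structure(self):
        # 6 h above 35 C, 18 h in the 26-30 band, as in hot-region days
        temps = [36.0] * 6 + [29.0] * 18
        table = daily_hours_in_ranges(self.series(temps))
        assert table.iloc[0][">35"] == 6
        assert table.iloc[0]["(25,30]"] == 18

    def test_daily_counts_conserve_observed_hours(self, rng):
        temps = rng.uniform(5, 40, size=24 * 10)
        temps[rng.choice(temps.size, 17, replace=False)] = np.nan  # gaps
        s = self.series(list(temps))
        daily = daily_hours_in_ranges(s)
        observed = s.dropna().groupby(s.dropna().index.normalize()).size()
        assert (daily.sum(axis=1) == observed.reindex(daily.index)).all()

    def test_monthly_mean_hours_per_day(self):
        temps = [22.0] * 24 * 4  # four identical January days
        table = hours_in_ranges(self.series(temps))
        assert table.loc[1, "(20,25]"] == pytest.approx(24.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            daily_hours_in_ranges(self.series([np.nan]))


class TestMonthlyStackIO:
    def test_directory_round_trip(self, tmp_path):
        from mycotherm import simulate_climate
        stack, _ = simulate_climate(nrows=5, ncols=6, seed=3)
        tmin_dir = tmp_path / "tmin"
        tmax_dir = tmp_path / "tmax"
        tmin_dir.mkdir()
        tmax_dir.mkdir()
        for m in range(1, 13):
            write_ascii_grid(stack.tmin[m], tmin_dir / f"tmin_{m:02d}.asc")
            write_ascii_grid(stack.tmax[m], tmax_dir / f"tmax_{m:02d}.asc")
        back = read_monthly_stack(tmin_dir, tmax_dir)
        # values survive to 6 significant digits
        np.testing.assert_allclose(back.tmin[7].values, stack.tmin[7].values,
                                   rtol=1e-5)

    def test_geometry_mismatch_rejected(self):
        g1 = ClimateGrid(values=np.zeros((2, 2)), cellsize=1.0, xllcorner=0.0,
                         yllcorner=0.0)
        g2 = ClimateGrid(values=np.zeros((3, 2)), cellsize=1.0, xllcorner=0.0,
                         yllcorner=0.0)
        tmin = {m: g1 for m in range(1, 13)}
        tmax = {m: (g2 if m == 5 else g1) for m in range(1, 13)}
        with pytest.raises(GridDimensionError):
            MonthlyStack(tmin=tmin, tmax=tmax)
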