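import numpy as np
import pandas as pd
import pytest
import shapely

from flywaykit.corridor import (
    CorridorModel,
    CoreLevel,
    build_corridor_polygon,
    choose_height,
    combine_weighted,
    select_window_height,
    width_profile,
    window_percentiles,
)
from flywaykit.geometry import polygon_metrics
from flywaykit.windows import WindowGrid


class TestCoreLevel:
    @pytest.mark.parametrize("level,lo,hi", [(50, 25.0, 75.0), (75, 12.5, 87.5), (95, 2.5, 97.5)])
    def test_symmetric_percentile_pairs(self, level, lo, hi):
        cl = CoreLevel(level)
        assert (cl.lower_pct, cl.upper_pct) == (lo, hi)
        assert cl.lower_pct + cl.upper_pct == 100.0


class TestWindowPercentiles:
    def test_constant_data_degenerate_edges(self):
        west, east = window_percentiles(np.full(40, 7.0), 50)
        assert west == east == 7.0

    def test_symmetric_data_symmetric_edges(self):
        xs = np.concatenate([-np.arange(1, 50), np.arange(1, 50), [0.0]])
        west, east = window_percentiles(xs, 95)
        assert west == pytest.approx(-east)

    def test_linear_interpolation_definition(self):
        west, east = window_percentiles(np.arange(1, 101), 50)
        assert (west, east) == pytest.approx((25.75, 75.25))

    def test_empty_window_flagged_missing(self):
        west, east = window_percentiles([], 95)
        assert np.isnan(west) and np.isnan(east)


class TestCombineWeighted:
    def test_weighted_average(self):
        assert combine_weighted(100.0, 300, 50.0, 100) == pytest.approx(87.5)

    def test_zero_weight_defers(self):
        assert combine_weighted(42.0, 10, float("nan"), 0) == 42.0
        assert combine_weighted(float("nan"), 0, 13.0, 5) == 13.0

    def test_equal_weights_arithmetic_mean(self):
        assert combine_weighted(10.0, 7, 20.0, 7) == 15.0

    def test_symmetry_under_dataset_swap(self):
        assert combine_weighted(3.0, 5, 11.0, 9) == combine_weighted(11.0, 9, 3.0, 5)

    def test_both_missing_flagged(self):
        assert np.isnan(combine_weighted(float("nan"), 0, float("nan"), 0))


def edges_frame(grid, west, east):
    return pd.DataFrame(
        {"window": np.arange(1, grid.count + 1), "west_x": west, "east_x": east}
    )


class TestBuildPolygon:
    def test_constant_edges_full_rectangle(self):
        grid = WindowGrid(0.0, 300e3, 13)
        poly = build_corridor_polygon(edges_frame(grid, -50e3, 50e3), grid)
        m = polygon_metrics(poly)
        assert m["area_ha"] == pytest.approx(39.0e6)
        assert poly.bounds == pytest.approx((-50e3, 0.0, 50e3, 3900e3))

    def test_single_window_quadrilateral(self):
        grid = WindowGrid(0.0, 300e3, 1)
        poly = build_corridor_polygon(edges_frame(grid, [-10e3], [10e3]), grid)
        assert len(poly.exterior.coords) == 4 + 1 + 2  # 2 mids + 4 squared corners

    def test_linearly_widening_edges_trapezoid_area(self):
        grid = WindowGrid(0.0, 100e3, 4)
        west = -np.array([10e3, 20e3, 30e3, 40e3])
        east = -west
        poly = build_corridor_polygon(edges_frame(grid, west, east), grid)
        # widths at vertex ordinates: squared ends + linear between midpoints
        widths = 2 * np.array([10e3, 10e3, 20e3, 30e3, 40e3, 40e3])
        ys = np.array([0.0, 50e3, 150e3, 250e3, 350e3, 400e3])
        expected = np.trapezoid(widths, ys)
        assert poly.area == pytest.approx(expected)

    def test_crossed_edges_rejected(self):
        grid = WindowGrid(0.0, 100e3, 2)
        with pytest.raises(ValueError, match="window"):
            build_corridor_polygon(edges_frame(grid, [0.0, 5e3], [10e3, -5e3]), grid)

    def test_interior_gap_interpolated(self):
        grid = WindowGrid(0.0, 100e3, 3)
        edges = pd.DataFrame({"window": [1, 3], "west_x": [-10e3, -30e3], "east_x": [10e3, 30e3]})
        poly = build_corridor_polygon(edges, grid)
        assert poly.bounds[1] == 0.0 and poly.bounds[3] == 300e3
        # midpoint of window 2 interpolates to +-20 km
        xs = shapely.intersection(poly, shapely.LineString([(-1e6, 150e3), (1e6, 150e3)]))
        assert xs.length == pytest.approx(40e3)

    def test_terminal_gap_truncates(self):
        grid = WindowGrid(0.0, 100e3, 3)
        edges = pd.DataFrame({"window": [1, 2], "west_x": [-10e3, -10e3], "east_x": [10e3, 10e3]})
        poly = build_corridor_polygon(edges, grid)
        assert poly.bounds[3] == pytest.approx(200e3)


class TestCorridorFit:
    def test_nesting_of_core_levels(self, sightings, telemetry_locations, grid):
        model = CorridorModel(sightings, telemetry_locations, grid=grid)
        res = model.fit(bands=False)
        p50, p75, p95 = (res.estimates[lv].polygon for lv in (50, 75, 95))
        assert p75.buffer(1e-6).covers(p50)
        assert p95.buffer(1e-6).covers(p75)

    def test_gaussian_window_spread_width_oracle(self):
        """95% half-width converges to 1.96 sigma per window at large n."""
        rng = np.random.default_rng(5)
        grid = WindowGrid(0.0, 300e3, 5)
        sigmas = np.array([30e3, 50e3, 70e3, 90e3, 110e3])
        n = 20000
        w = rng.integers(1, 6, n)
        df = pd.DataFrame(
            {"x": rng.standard_normal(n) * sigmas[w - 1], "y": grid.y_mid(w) + rng.uniform(-149e3, 149e3, n)}
        )
        res = CorridorModel(df, None, grid=grid).fit(bands=False)
        widths = res.estimates[95].widths_km.to_numpy() * 1e3
        assert np.allclose(widths, 2 * 1.96 * sigmas, rtol=0.03)

    def test_self_containment_near_level(self, sightings):
        res = CorridorModel(sightings, None, window_height=300e3).fit(bands=False)
        assert res.containment(95) == pytest.approx(0.95, abs=0.012)

    def test_degenerate_single_x_bootstrap_zero_width_bands(self):
        grid = WindowGrid(0.0, 300e3, 2)
        df = pd.DataFrame({"x": np.zeros(60), "y": np.tile([150e3, 450e3], 30)})
        res = CorridorModel(df, None, grid=grid).fit(bootstrap=50, seed=1)
        e = res.edge_table(95)
        assert np.allclose(e["cl_west_lo"], e["cl_west_hi"])
        assert np.allclose(e["cl_east_lo"], 0.0)

    def test_confidence_limits_bracket_point_estimates(self, sightings, grid):
        res = CorridorModel(sightings, None, grid=grid).fit(bootstrap=200, seed=2)
        e = res.edge_table(95)
        ok_w = (e["cl_west_lo"] <= e["west_x"]) & (e["west_x"] <= e["cl_west_hi"])
        ok_e = (e["cl_east_lo"] <= e["east_x"]) & (e["east_x"] <= e["cl_east_hi"])
        assert ok_w.mean() >= 0.9 and ok_e.mean() >= 0.9

    def test_band_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        grid = WindowGrid(0.0, 300e3, 3)

        def bandwidth(n):
            df = pd.DataFrame({"x": rng.standard_normal(n) * 50e3, "y": rng.uniform(0, 900e3, n)})
            e = CorridorModel(df, None, grid=grid).fit(bootstrap=150, seed=3).edge_table(95)
            return float((e["cl_west_hi"] - e["cl_west_lo"]).mean())

        assert bandwidth(4000) < bandwidth(250)

    def test_summary_reports_all_levels(self, sightings, grid):
        res = CorridorModel(sightings, None, grid=grid).fit(bands=False)
        summ = res.summary()
        assert list(summ.index) == [50, 75, 95]
        assert (summ["mean_width_km"].diff().dropna() > 0).all()


class TestWidthProfile:
    def test_rectangle_zero_sd(self):
        widths = pd.Series([80.0] * 5, index=pd.RangeIndex(1, 6))
        prof = width_profile(widths)
        assert prof["sd_km"] == 0.0
        assert prof["mean_km"] == prof["min_km"] == prof["max_km"] == 80.0

    def test_two_window_summary(self):
        prof = width_profile(pd.Series([25.0, 105.0], index=[1, 2]))
        assert prof["mean_km"] == 65.0
        assert (prof["min_km"], prof["min_window"]) == (25.0, 1)
        assert (prof["max_km"], prof["max_window"]) == (105.0, 2)


class TestHeightSelection:
    def diag(self, rows):
        return pd.DataFrame(rows, columns=["height_km", "containment", "frac_index", "passes"])

    def test_failing_containment_excluded_despite_best_shape(self):
        d = self.diag([(100, 0.93, 1.01, False), (200, 0.96, 1.05, True)])
        assert choose_height(d) == 200e3

    def test_tie_breaks_to_smaller_height(self):
        d = self.diag([(100, 0.96, 1.04, True), (200, 0.96, 1.04, True)])
        assert choose_height(d) == 100e3

    def test_no_passer_raises_with_diagnostics(self):
        d = self.diag([(100, 0.90, 1.01, False)])
        with pytest.raises(ValueError, match="containment"):
            choose_height(d)

    def test_diagnostics_row_per_candidate(self, sightings):
        h, diag = select_window_height(
            sightings, None, heights=(200e3, 400e3), bootstrap=30, seed=4, containment_target=0.90
        )
        assert len(diag) == 2
        assert set(diag.columns) == {"height_km", "containment", "frac_index", "passes"}
        assert h in (200e3, 400e3)
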