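import numpy as np
import pandas as pd
import pytest

from flywaykit.simulate import SyntheticScenario, simulate_sightings
from flywaykit.trend import (
    GibbsLinearModel,
    TwoStageTrendModel,
    build_design,
    centerline_offsets,
    median_by_window,
    median_difference_bootstrap,
    predict_year_positions,
    width_trend,
)
from flywaykit.windows import WindowGrid, assign_windows


def toy_locations(rng, n=400, windows=3, slope_m=1200.0, noise_m=50e3, year_span=(1942, 2016)):
    w = rng.integers(1, windows + 1, n)
    year = rng.integers(year_span[0], year_span[1] + 1, n)
    x = 10e3 * w + slope_m * (year - 1942) + rng.standard_normal(n) * noise_m
    return pd.DataFrame({"x": x, "year": year, "window": pd.array(w, dtype="Int64"),
                         "y": (w - 0.5) * 300e3})


class TestMedians:
    def test_odd_count_median(self):
        grid = WindowGrid(0.0, 300e3, 1)
        df = pd.DataFrame({"x": [1.0, 5.0, 9.0], "y": [150e3] * 3})
        assert median_by_window(df, grid).iloc[0] == 5.0

    def test_even_count_mean_of_central_pair(self):
        grid = WindowGrid(0.0, 300e3, 1)
        df = pd.DataFrame({"x": [1.0, 3.0, 7.0, 9.0], "y": [150e3] * 4})
        assert median_by_window(df, grid).iloc[0] == 5.0

    def test_matches_sort_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2)
        grid = WindowGrid(0.0, 300e3, 4)
        df = pd.DataFrame({"x": rng.standard_normal(500) * 1e4, "y": rng.uniform(0, 1200e3, 500)})
        med = median_by_window(df, grid)
        out = assign_windows(df, grid)
        for w in range(1, 5):
            xs = np.sort(out.loc[out["window"] == w, "x"].to_numpy())
            mid = (xs[(len(xs) - 1) // 2] + xs[len(xs) // 2]) / 2
            assert med.loc[w] == pytest.approx(mid)

    def test_empty_window_missing(self):
        grid = WindowGrid(0.0, 300e3, 2)
        df = pd.DataFrame({"x": [1.0], "y": [150e3]})
        med = median_by_window(df, grid)
        assert np.isnan(med.loc[2])


class TestMedianDifference:
    def grid(self):
        return WindowGrid(0.0, 300e3, 2)

    def frame(self, xs_km, n_per_window=60, seed=0):
        rng = np.random.default_rng(seed)
        n = n_per_window * 2
        w = np.repeat([1, 2], n_per_window)
        return pd.DataFrame({
            "x": xs_km * 1e3 + rng.standard_normal(n) * 20e3,
            "y": (w - 0.5) * 300e3,
        })

    def test_identical_datasets_difference_zero(self):
        a = self.frame(0.0, seed=1)
        out = median_difference_bootstrap(a, a.copy(), self.grid(), B=200, seed=2)
        assert np.allclose(out["difference_km"], 0.0)
        assert ((out["cl_lo_km"] <= 0) & (out["cl_hi_km"] >= 0)).all()

    def test_known_shift_recovered(self):
        opp = self.frame(10.0, n_per_window=400, seed=3)
        tel = self.frame(0.0, n_per_window=400, seed=4)
        out = median_difference_bootstrap(opp, tel, self.grid(), B=400, seed=5)
        assert out["difference_km"].to_numpy() == pytest.approx([10.0, 10.0], abs=4.0)
        assert ((out["cl_lo_km"] <= 10.0) & (out["cl_hi_km"] >= 10.0)).all()

    def test_sparse_window_flagged_unevaluated(self):
        opp = self.frame(0.0, n_per_window=10, seed=6)
        tel = self.frame(0.0, n_per_window=40, seed=7)
        out = median_difference_bootstrap(opp, tel, self.grid(), B=50, min_n=30, seed=8)
        assert (~out["evaluated"]).all()
        assert out["difference_km"].notna().all()  # still estimated, just flagged

    def test_too_few_resamples_rejected(self):
        a = self.frame(0.0)
        with pytest.raises(ValueError, match="B"):
            median_difference_bootstrap(a, a, self.grid(), B=1)


class TestGibbsSampler:
    def test_flat_prior_matches_least_squares(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(120), rng.standard_normal(120), rng.standard_normal(120)])
        beta = np.array([3.0, -2.0, 0.5])
        y = X @ beta + rng.standard_normal(120)
        res = GibbsLinearModel(y, X).fit(burn=300, keep=2000, seed=11)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        mcse = res.draws.std(axis=0, ddof=1) / np.sqrt(400)  # conservative ESS
        assert np.all(np.abs(res.params - ols) < 3 * mcse + 1e-9)

    def test_near_degenerate_prior_dominates(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((50, 1))
        y = X[:, 0] * 5.0 + rng.standard_normal(50)
        res = GibbsLinearModel(
            y, X, prior_mean=np.array([0.0]), prior_var=np.array([1e-10])
        ).fit(burn=200, keep=500, seed=13)
        assert abs(res.params[0]) < 1e-3

    def test_known_variance_conjugate_closed_form(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(80)
        y = 2.0 * x + rng.standard_normal(80)
        m0, v0, s2 = 0.5, 4.0, 1.0
        res = GibbsLinearModel(
            y, x[:, None], prior_mean=np.array([m0]), prior_var=np.array([v0]), sigma2=s2
        ).fit(burn=200, keep=4000, seed=15)
        prec = x @ x / s2 + 1 / v0
        post_mean = (x @ y / s2 + m0 / v0) / prec
        assert res.params[0] == pytest.approx(post_mean, abs=4 * np.sqrt(1 / prec / 4000) * 3)
        assert res.params_var[0] == pytest.approx(1 / prec, rel=0.15)

    def test_no_likelihood_limit_returns_prior(self):
        res = GibbsLinearModel(
            np.empty(0), np.empty((0, 2)),
            prior_mean=np.array([1.5, -2.0]), prior_var=np.array([0.25, 0.04]),
        ).fit(burn=100, keep=3000, seed=16)
        assert res.params == pytest.approx([1.5, -2.0], abs=0.05)
        assert res.params_var == pytest.approx([0.25, 0.04], rel=0.2)

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        y = np.zeros(30)
        with pytest.raises(ValueError, match="rank"):
            GibbsLinearModel(y, X)

    def test_credible_interval_coverage_calibrated(self):
        """Nominal 95% CIs cover the true slope at the nominal rate."""
        rng = np.random.default_rng(17)
        cover = 0
        reps = 500
        for _ in range(reps):
            x = rng.uniform(0, 74, 60)
            y = 1.2 * x + rng.standard_normal(60) * 30
            res = GibbsLinearModel(y, np.column_stack([np.ones(60), x])).fit(burn=100, keep=400, seed=rng)
            lo, hi = res.conf_int()[1]
            cover += lo <= 1.2 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.025)


class TestDesignAndTwoStage:
    def test_design_cell_means_structure(self):
        rng = np.random.default_rng(20)
        df = toy_locations(rng)
        d = build_design(df, WindowGrid(0.0, 300e3, 3))
        assert d.X.shape[1] == 2 * len(d.windows)
        assert sorted(d.slope_cols) == d.windows
        j = d.slope_cols[d.windows[0]]
        mask = d.X[:, j] != 0
        assert np.array_equal(d.X[mask, j - 1], np.ones(mask.sum()))

    def test_single_year_window_dropped(self):
        rng = np.random.default_rng(21)
        df = toy_locations(rng, windows=2)
        df.loc[df["window"] == 2, "year"] = 2000
        d = build_design(df, WindowGrid(0.0, 300e3, 2))
        assert d.windows == [1]
        assert d.n_dropped == int((df["window"] == 2).sum())

    def test_two_stage_known_variance_matches_pooled(self):
        """Prior updating equals a pooled fit in the conjugate limit."""
        rng = np.random.default_rng(22)
        s2 = 1.0
        x1, x2 = rng.standard_normal(60), rng.standard_normal(40)
        y1 = 3.0 * x1 + rng.standard_normal(60) * np.sqrt(s2)
        y2 = 3.0 * x2 + rng.standard_normal(40) * np.sqrt(s2)
        r1 = GibbsLinearModel(y1, x1[:, None], sigma2=s2).fit(burn=200, keep=6000, seed=23)
        r2 = GibbsLinearModel(
            y2, x2[:, None], prior_mean=r1.params, prior_var=r1.params_var, sigma2=s2
        ).fit(burn=200, keep=6000, seed=24)
        prec_pooled = (x1 @ x1 + x2 @ x2) / s2
        mean_pooled = (x1 @ y1 + x2 @ y2) / s2 / prec_pooled
        assert r2.params[0] == pytest.approx(mean_pooled, abs=0.03)
        assert r2.params_var[0] == pytest.approx(1 / prec_pooled, rel=0.2)

    def test_stage2_no_more_diffuse_than_prior(self):
        rng = np.random.default_rng(25)
        opp = toy_locations(rng, n=600)
        tel = toy_locations(rng, n=400, year_span=(2010, 2016))
        grid = WindowGrid(0.0, 300e3, 3)
        res = TwoStageTrendModel(opp, tel, grid).fit(burn=300, keep=1500, seed=26)
        assert np.all(res.stage2.params_var <= res.prior_var * 1.15)

    def test_slope_recovery_and_excludes_zero(self):
        rng = np.random.default_rng(27)
        opp = toy_locations(rng, n=2000, slope_m=1200.0, noise_m=40e3)
        tel = toy_locations(rng, n=800, slope_m=1200.0, noise_m=40e3, year_span=(2010, 2016))
        grid = WindowGrid(0.0, 300e3, 3)
        table = TwoStageTrendModel(opp, tel, grid).fit(burn=400, keep=2000, seed=28).slope_table()
        assert table["slope_mean_km_per_year"].to_numpy() == pytest.approx(1.2, abs=0.25)
        assert table["excludes_zero"].all()

    def test_shift_invariance_of_slopes_and_predictions(self):
        rng = np.random.default_rng(29)
        opp = toy_locations(rng, n=800)
        tel = toy_locations(rng, n=300, year_span=(2010, 2016))
        grid = WindowGrid(0.0, 300e3, 3)
        res_a = TwoStageTrendModel(opp, tel, grid).fit(burn=300, keep=1200, seed=30)
        shift = 250e3
        opp_s, tel_s = opp.copy(), tel.copy()
        opp_s["x"] += shift
        tel_s["x"] += shift
        res_b = TwoStageTrendModel(opp_s, tel_s, grid).fit(burn=300, keep=1200, seed=30)
        a, b = res_a.slope_table(), res_b.slope_table()
        assert b["slope_mean_km_per_year"].to_numpy() == pytest.approx(
            a["slope_mean_km_per_year"].to_numpy(), abs=1e-9
        )
        pa, pb = res_a.predict(), res_b.predict()
        assert pb["pred_1980_km"].to_numpy() - pa["pred_1980_km"].to_numpy() == pytest.approx(250.0, abs=1e-9)


class TestOffsets:
    def frame(self):
        return pd.DataFrame(
            {"x": [0.0, 5e3, -5e3], "y": [150e3] * 3, "window": pd.array([1, 1, 1], dtype="Int64")}
        )

    def test_zero_offset_counts_east(self):
        cl = pd.Series([0.0], index=[1])
        out = centerline_offsets(self.frame(), cl)
        assert out.loc[0, "signed_offset"] == 0.0
        assert out.loc[0, "side"] == "east"

    def test_symmetric_points(self):
        out = centerline_offsets(self.frame(), pd.Series([0.0], index=[1]))
        assert out["signed_offset"].tolist() == [0.0, 5e3, -5e3]
        assert out["side"].tolist() == ["east", "east", "west"]

    def test_mirror_symmetry_of_magnitudes(self):
        df = self.frame()
        cl = pd.Series([0.0], index=[1])
        fwd = centerline_offsets(df, cl)
        mirrored = df.assign(x=-df["x"])
        rev = centerline_offsets(mirrored, cl)
        assert np.allclose(np.sort(fwd["abs_offset"]), np.sort(rev["abs_offset"]))

    def test_missing_centerline_skips_with_log(self):
        df = self.frame()
        df.loc[2, "window"] = 2
        out = centerline_offsets(df, pd.Series([0.0, np.nan], index=[1, 2]))
        assert len(out) == 2


@pytest.fixture(scope="module")
def contraction_fit():
    scn = SyntheticScenario(drift_km_per_year=0.0)  # west contraction 0.9, east stable
    grid = WindowGrid(scn.y_south_m, scn.window_height_m, scn.n_windows)
    opp, _ = simulate_sightings(scn, n=6000, seed=31)
    # telemetry-era locations: same generative process, recent years only
    scn_tel = SyntheticScenario(drift_km_per_year=0.0, years_opp=(2010, 2016))
    tel, _ = simulate_sightings(scn_tel, n=1500, seed=35)
    tel = tel.assign(source="telemetry")
    combined = pd.concat([assign_windows(opp, grid), assign_windows(tel, grid)], ignore_index=True)
    cl = median_by_window(combined, grid)
    offsets = centerline_offsets(combined, cl)
    return scn, grid, offsets


class TestWidthTrend:

    def test_west_contraction_recovered(self, contraction_fit):
        scn, grid, offsets = contraction_fit
        res = width_trend(offsets, "west", grid, burn=400, keep=1500, seed=36)
        t = res.slope_table()
        truth = scn.true_slopes()["west_offset"].reindex(t.index)
        covered = (t["cl_lo"] <= truth) & (truth <= t["cl_hi"])
        assert covered.mean() >= 0.6
        assert t["slope_mean_km_per_year"].mean() == pytest.approx(0.9, abs=0.2)

    def test_stable_east_flank_near_zero(self, contraction_fit):
        _, grid, offsets = contraction_fit
        t = width_trend(offsets, "east", grid, burn=400, keep=1500, seed=37).slope_table()
        assert abs(t["slope_mean_km_per_year"].mean()) < 0.2
        assert (~t["excludes_zero"]).mean() >= 0.5

    def test_absolute_offset_narrowing(self, contraction_fit):
        scn, grid, offsets = contraction_fit
        t = width_trend(offsets, "all_abs", grid, burn=400, keep=1500, seed=38).slope_table()
        assert t["slope_mean_km_per_year"].mean() == pytest.approx(-0.45, abs=0.2)

    def test_unknown_subset_rejected(self, contraction_fit):
        _, grid, offsets = contraction_fit
        with pytest.raises(ValueError, match="subset"):
            width_trend(offsets, "north", grid)


class TestPredictions:
    def results_with_slope(self, slope_m):
        rng = np.random.default_rng(40)
        df = toy_locations(rng, n=900, slope_m=slope_m, noise_m=5e3)
        grid = WindowGrid(0.0, 300e3, 3)
        d = build_design(df, grid)
        return GibbsLinearModel(d.y, d.X, columns=d.columns).fit(burn=300, keep=1500, seed=41)

    def test_zero_slope_identical_predictions(self):
        res = self.results_with_slope(0.0)
        preds = predict_year_positions(res, years=(1980, 2014))
        assert preds["difference_km"].to_numpy() == pytest.approx(0.0, abs=1.5)

    def test_unit_slope_34km_difference(self):
        res = self.results_with_slope(1000.0)
        preds = predict_year_positions(res, years=(1980, 2014))
        assert preds["difference_km"].to_numpy() == pytest.approx(34.0, abs=1.5)

    def test_extrapolation_warns(self):
        res = self.results_with_slope(0.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_year_positions(res, years=(1930, 2014))
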