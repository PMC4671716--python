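"""Prais-Winsten/PCSE estimator: design building, rho, transform, sandwich."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ecotrade.panel import (
    ModelSpec,
    PanelDataset,
    PanelError,
    PraisWinstenPCSE,
    build_design,
    contemporaneous_covariance,
    descriptive_stats,
    estimate_rho,
    fit_listwise_ols,
    pcse_covariance,
    prais_winsten_transform,
)


def _panel_frame(R=3, T=5, seed=0, missing=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(R):
        for t in range(T):
            rows.append(
                {
                    "country": f"C{i}",
                    "year": 2000 + t,
                    "y": rng.normal(5.0, 1.0),
                    "x1": rng.normal(0.0, 1.0),
                    "x2": rng.normal(2.0, 0.5),
                }
            )
    df = pd.DataFrame(rows)
    if missing:
        for col, idx in missing.items():
            df.loc[idx, col] = np.nan
    return df


class TestPanelDataset:
    def test_duplicate_keys_rejected(self):
        df = _panel_frame()
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(PanelError, match="duplicate"):
            PanelDataset(dup, log_vars=())

    def test_year_gaps_become_missing_rows(self):
        df = _panel_frame(R=1, T=4)
        df = df[df.year != 2002]  # drop the middle year
        panel = PanelDataset(df, log_vars=())
        assert len(panel.frame) == 4
        assert panel.frame.loc[panel.frame.year == 2002, "y"].isna().all()

    def test_log_transform_registry(self):
        df = _panel_frame(R=1, T=3)
        df["y"] = [1.0, np.e, np.e**2]
        panel = PanelDataset(df, log_vars=("y",))
        np.testing.assert_allclose(panel.transformed("y"), [0.0, 1.0, 2.0])

    def test_nonpositive_logged_value_names_country_year(self):
        df = _panel_frame(R=1, T=3)
        df.loc[1, "y"] = -1.0
        panel = PanelDataset(df, log_vars=("y",))
        with pytest.raises(PanelError, match="C0 2001"):
            panel.transformed("y")

    def test_csv_round_trip(self, tmp_path):
        df = _panel_frame(missing={"x1": [2]})
        panel = PanelDataset(df, log_vars=())
        panel.to_csv(tmp_path / "p.csv")
        back = PanelDataset.from_csv(tmp_path / "p.csv", log_vars=())
        pd.testing.assert_frame_equal(
            back.frame, panel.frame, check_exact=False, rtol=1e-12
        )


class TestBuildDesign:
    def test_intercept_plus_regressor(self):
        panel = PanelDataset(_panel_frame(R=1, T=3), log_vars=())
        d = build_design(panel, ModelSpec("y", ("x1",)))
        assert d.X.shape == (3, 2)
        assert list(d.X.columns) == ["const", "x1"]

    def test_country_dummies_drop_reference_level(self):
        panel = PanelDataset(_panel_frame(R=2, T=4), log_vars=())
        d = build_design(panel, ModelSpec("y", ("x1",), ("country",)))
        dummies = [c for c in d.X.columns if c.startswith("country_")]
        assert len(dummies) == 1

    def test_duplicate_regressor_dropped_and_reported(self):
        panel = PanelDataset(_panel_frame(), log_vars=())
        with pytest.warns(UserWarning, match="duplicate"):
            d = build_design(panel, ModelSpec("y", ("x1", "x2", "x1")))
        assert d.dropped_terms == ["x1"]
        assert list(d.X.columns) == ["const", "x1", "x2"]

    def test_missing_rows_excluded(self):
        panel = PanelDataset(_panel_frame(missing={"x1": [0, 7]}), log_vars=())
        d = build_design(panel, ModelSpec("y", ("x1",)))
        assert len(d.y) == 13

    def test_collinear_column_dropped_with_warning(self):
        df = _panel_frame()
        df["x3"] = 2.0 * df["x1"]
        panel = PanelDataset(df, log_vars=())
        with pytest.warns(UserWarning, match="collinear"):
            d = build_design(panel, ModelSpec("y", ("x1", "x3")))
        assert "x3" in d.dropped_terms

    def test_row_order_invariance(self):
        df = _panel_frame(seed=3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        spec = ModelSpec("y", ("x1", "x2"), ("year",))
        r1 = PraisWinstenPCSE(PanelDataset(df, log_vars=()), spec).fit()
        r2 = PraisWinstenPCSE(PanelDataset(shuffled, log_vars=()), spec).fit()
        pd.testing.assert_series_equal(r1.params, r2.params)
        pd.testing.assert_series_equal(r1.bse, r2.bse)


class TestEstimateRho:
    def test_exact_half_decay(self):
        years = np.arange(2000, 2010)
        e = 0.5 ** np.arange(10) * 3.0
        countries = np.repeat("A", 10)
        assert estimate_rho(e, countries, years) == pytest.approx(0.5, abs=1e-14)

    def test_two_pair_hand_computation(self):
        e = np.array([1.0, 0.6, 0.36])
        rho = estimate_rho(e, np.repeat("A", 3), np.array([2000, 2001, 2002]))
        assert rho == pytest.approx(0.6, abs=1e-14)

    def test_iid_null_large_sample(self):
        rng = np.random.default_rng(123)
        R, T = 50, 200
        e = rng.normal(0, 1, R * T)
        countries = np.repeat([f"C{i}" for i in range(R)], T)
        years = np.tile(np.arange(T), R)
        assert abs(estimate_rho(e, countries, years)) < 0.02

    def test_gap_breaks_pairs(self):
        # only one consecutive pair: (2000, 2001); 2003 is isolated
        e = np.array([1.0, 0.25, 9.0])
        years = np.array([2000, 2001, 2003])
        rho = estimate_rho(e, np.repeat("A", 3), years)
        assert rho == pytest.approx(0.25)

    def test_no_pairs_raises(self):
        with pytest.raises(PanelError, match="consecutive"):
            estimate_rho(
                np.array([1.0, 2.0]), np.array(["A", "B"]),
                np.array([2000, 2000]),
            )


class TestPraisWinstenTransform:
    def test_rho_zero_is_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        yt, Xt = prais_winsten_transform(
            y, X, np.repeat("A", 3), np.array([2000, 2001, 2002]), 0.0
        )
        np.testing.assert_array_equal(yt, y)
        np.testing.assert_array_equal(Xt, X)

    def test_constant_column_arithmetic(self):
        X = np.ones((3, 1))
        y = np.zeros(3)
        _, Xt = prais_winsten_transform(
            y, X, np.repeat("A", 3), np.array([2000, 2001, 2002]), 0.5
        )
        np.testing.assert_allclose(
            Xt[:, 0], [np.sqrt(0.75), 0.5, 0.5]
        )

    def test_gap_restarts_first_observation_rule(self):
        X = np.ones((4, 1))
        y = np.array([1.0, 2.0, 5.0, 6.0])
        yt, Xt = prais_winsten_transform(
            y, X, np.repeat("A", 4), np.array([2000, 2001, 2005, 2006]), 0.4
        )
        s = np.sqrt(1 - 0.16)
        np.testing.assert_allclose(yt, [s * 1.0, 2.0 - 0.4, s * 5.0, 6.0 - 2.0])

    def test_whitening_of_simulated_ar1(self):
        rng = np.random.default_rng(7)
        T = 2000
        rho = 0.7
        eps = rng.normal(0, 1, T)
        u = np.empty(T)
        u[0] = eps[0] / np.sqrt(1 - rho**2)
        for t in range(1, T):
            u[t] = rho * u[t - 1] + eps[t]
        yt, _ = prais_winsten_transform(
            u, np.ones((T, 1)), np.repeat("A", T), np.arange(T), rho
        )
        r = np.corrcoef(yt[:-1], yt[1:])[0, 1]
        assert abs(r) < 0.03


class TestPCSECovariance:
    def test_single_country_reduces_to_classical_form(self):
        rng = np.random.default_rng(1)
        T = 30
        X = np.column_stack([np.ones(T), rng.normal(0, 1, T)])
        e = rng.normal(0, 2, T)
        countries = np.repeat("A", T)
        years = np.arange(T)
        V = pcse_covariance(X, e, countries, years)
        s2 = np.mean(e**2)
        expected = s2 * np.linalg.inv(X.T @ X)
        np.testing.assert_allclose(V, expected, rtol=1e-10)

    def test_identical_residual_series_gives_equal_cov_entries(self):
        T = 10
        e = np.sin(np.arange(T))
        residuals = np.concatenate([e, e])
        countries = np.repeat(["A", "B"], T)
        years = np.tile(np.arange(T), 2)
        sigma = contemporaneous_covariance(residuals, countries, years)
        assert sigma.loc["A", "B"] == pytest.approx(sigma.loc["A", "A"])
        assert sigma.loc["A", "B"] == pytest.approx(sigma.loc["B", "B"])

    def test_dense_omega_oracle_balanced_panel(self):
        # independent dense-matrix computation of the sandwich on R=4, T=10
        rng = np.random.default_rng(42)
        R, T = 4, 10
        n = R * T
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 2))])
        e = rng.normal(0, 1, n)
        countries = np.repeat([f"C{i}" for i in range(R)], T)
        years = np.tile(np.arange(T), R)
        V = pcse_covariance(X, e, countries, years)
        # oracle: explicit n x n Omega built from Sigma-hat
        E = e.reshape(R, T)
        sigma = (E @ E.T) / T
        omega = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                if years[a] == years[b]:
                    ia = a // T
                    ib = b // T
                    omega[a, b] = sigma[ia, ib]
        xtx_inv = np.linalg.inv(X.T @ X)
        expected = xtx_inv @ X.T @ omega @ X @ xtx_inv
        np.testing.assert_allclose(V, expected, rtol=1e-8)

    def test_pairwise_uses_overlapping_years_only(self):
        e = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        countries = np.array(["A", "A", "A", "B", "B"])
        years = np.array([2000, 2001, 2002, 2001, 2002])
        sigma = contemporaneous_covariance(e, countries, years, "pairwise")
        # overlap years 2001, 2002: (2*10 + 3*20)/2 = 40
        assert sigma.loc["A", "B"] == pytest.approx(40.0)
        # A variance over its own 3 years
        assert sigma.loc["A", "A"] == pytest.approx((1 + 4 + 9) / 3)

    def test_listwise_restricts_to_jointly_observed_years(self):
        e = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        countries = np.array(["A", "A", "A", "B", "B"])
        years = np.array([2000, 2001, 2002, 2001, 2002])
        sigma = contemporaneous_covariance(e, countries, years, "listwise")
        assert sigma.loc["A", "A"] == pytest.approx((4 + 9) / 2)


class TestFit:
    def test_degenerate_settings_equal_classical_ols(self):
        df = _panel_frame(R=4, T=8, seed=5)
        panel = PanelDataset(df, log_vars=())
        spec = ModelSpec("y", ("x1", "x2"))
        res = PraisWinstenPCSE(panel, spec).fit(rho=0.0, cov_type="classical")
        X = sm.add_constant(df[["x1", "x2"]])
        ols = sm.OLS(df["y"], X).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), ols.params.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            res.bse.to_numpy(), ols.bse.to_numpy(), atol=1e-10
        )

    def test_rho_estimated_on_planted_ar1(self):
        rng = np.random.default_rng(11)
        R, T, rho = 30, 40, 0.6
        rows = []
        for i in range(R):
            u = np.empty(T)
            eps = rng.normal(0, 0.5, T)
            u[0] = eps[0] / np.sqrt(1 - rho**2)
            for t in range(1, T):
                u[t] = rho * u[t - 1] + eps[t]
            x = rng.normal(0, 1, T)
            for t in range(T):
                rows.append({"country": f"C{i}", "year": 2000 + t,
                             "y": 1.0 + 2.0 * x[t] + u[t], "x1": x[t]})
        panel = PanelDataset(pd.DataFrame(rows), log_vars=())
        res = PraisWinstenPCSE(panel, ModelSpec("y", ("x1",))).fit()
        assert res.rho == pytest.approx(rho, abs=0.08)
        assert res.params["x1"] == pytest.approx(2.0, abs=0.05)

    def test_wald_excludes_intercept_and_dummies(self):
        panel = PanelDataset(_panel_frame(R=4, T=6, seed=2), log_vars=())
        res = PraisWinstenPCSE(
            panel, ModelSpec("y", ("x1", "x2"), ("year",))
        ).fit()
        assert res.wald_df == 2
        b = res.params[["x1", "x2"]].to_numpy()
        V = res.cov_params.loc[["x1", "x2"], ["x1", "x2"]].to_numpy()
        assert res.wald_chi2 == pytest.approx(b @ np.linalg.solve(V, b))

    def test_summary_mentions_key_diagnostics(self):
        panel = PanelDataset(_panel_frame(R=4, T=6), log_vars=())
        res = PraisWinstenPCSE(panel, ModelSpec("y", ("x1",))).fit()
        text = res.summary()
        assert "panel-corrected" in text
        assert "AR(1)" in text and "Wald" in text


class TestListwiseOLS:
    def test_complete_panel_matches_pooled_ols_point_estimates(self):
        df = _panel_frame(R=3, T=6, seed=9)
        panel = PanelDataset(df, log_vars=())
        spec = ModelSpec("y", ("x1", "x2"), (), "listwise_ols", "listwise")
        res = fit_listwise_ols(panel, spec)
        pw = PraisWinstenPCSE(
            panel, ModelSpec("y", ("x1", "x2"))
        ).fit(rho=0.0, cov_type="classical")
        np.testing.assert_allclose(
            res.params.to_numpy(), pw.params.to_numpy(), atol=1e-12
        )
        assert np.isfinite(res.rsquared_adj)

    def test_missing_cell_drops_exactly_one_row(self):
        full = fit_listwise_ols(
            PanelDataset(_panel_frame(seed=1), log_vars=()),
            ModelSpec("y", ("x1",), (), "listwise_ols", "listwise"),
        )
        holed = fit_listwise_ols(
            PanelDataset(_panel_frame(seed=1, missing={"x1": [4]}), log_vars=()),
            ModelSpec("y", ("x1",), (), "listwise_ols", "listwise"),
        )
        assert holed.nobs == full.nobs - 1

    def test_noiseless_linear_data_is_exact(self):
        df = _panel_frame(R=2, T=10, seed=3)
        df["y"] = 1.0 + 3.0 * df["x1"] - 2.0 * df["x2"]
        res = fit_listwise_ols(
            PanelDataset(df, log_vars=()),
            ModelSpec("y", ("x1", "x2"), (), "listwise_ols", "listwise"),
        )
        np.testing.assert_allclose(
            res.params.to_numpy(), [1.0, 3.0, -2.0], atol=1e-10
        )
        assert res.rsquared == pytest.approx(1.0)


class TestDescriptiveStats:
    def test_logged_variable_moments(self):
        df = _panel_frame(R=1, T=3)
        df["y"] = [1.0, np.e, np.e**2]
        stats_ = descriptive_stats(PanelDataset(df, log_vars=("y",)))
        assert stats_.loc["y", "mean"] == pytest.approx(1.0)
        assert stats_.loc["y", "sd"] == pytest.approx(1.0)

    def test_all_missing_variable_reports_zero_count(self):
        df = _panel_frame(R=1, T=3)
        df["z"] = np.nan
        stats_ = descriptive_stats(PanelDataset(df, log_vars=()))
        assert stats_.loc["z", "n_obs"] == 0
        assert np.isnan(stats_.loc["z", "mean"])

    def test_counts_match_planted_missingness(self, small_world):
        panel = small_world["panel"]
        stats_ = descriptive_stats(panel)
        for var in panel.variables:
            assert stats_.loc[var, "n_obs"] == panel.frame[var].notna().sum()
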