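"""Spline basis, crossbasis convolution, quasi-Poisson fit, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from heatmort.heatwave_calendar import determine_hot_season
from heatmort.stage1_dlnm import (
    LagBasis,
    NaturalCubicSpline,
    NoExposureVariationError,
    build_crossbasis,
    cross_validate_last_year,
    fit_first_stage,
    natural_cubic_spline_basis,
    pooled_r2,
    season_year,
    trend_df_for_years,
)
from heatmort.synthetic_world import WorldConfig, simulate_community


class TestNaturalCubicSpline:
    def test_second_derivative_vanishes_at_and_beyond_boundaries(self):
        # outward finite differences so the stencil stays in the linear tail
        spline = NaturalCubicSpline.from_df(4, (0.0, 10.0))
        h = 0.5  # exact in the linear tail, so a wide stencil is fine
        f = lambda x: spline.transform([x])[0]
        for x0, sign in ((0.0, -1), (10.0, +1), (-2.0, -1), (13.0, +1)):
            second = (f(x0) - 2 * f(x0 + sign * h) + f(x0 + 2 * sign * h)) / h**2
            assert np.all(np.abs(second) < 1e-8)

    def test_df1_is_linear_in_x(self):
        x = np.linspace(0, 10, 50)
        basis = natural_cubic_spline_basis(x, 1)
        assert basis.shape == (50, 1)
        assert abs(np.corrcoef(basis[:, 0], x)[0, 1]) == pytest.approx(1.0)

    def test_linear_function_reproduced_exactly(self):
        # linear functions lie in the natural-spline space
        x = np.linspace(0, 10, 200)
        basis = natural_cubic_spline_basis(x, 4, include_constant=True)
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        assert np.max(np.abs(basis @ coef - x)) < 1e-10

    def test_column_count_equals_df(self):
        x = np.linspace(0, 1, 30)
        for df in (1, 2, 3, 5):
            assert natural_cubic_spline_basis(x, df).shape[1] == df

    def test_df_exceeding_support_rejected(self):
        with pytest.raises(ValueError):
            natural_cubic_spline_basis([0.0, 1.0, 2.0], 3)


class TestLagBasis:
    def test_default_shape_and_rank(self):
        lb = LagBasis()
        assert lb.basis_matrix.shape == (11, 4)
        assert np.linalg.matrix_rank(lb.basis_matrix) == 4
        assert np.allclose(lb.basis_matrix[:, 0], 1.0)

    def test_cumulative_contrast_is_column_sums(self):
        lb = LagBasis()
        np.testing.assert_allclose(lb.cumulative_contrast, lb.basis_matrix.sum(axis=0))


class TestBuildCrossbasis:
    def test_zero_indicator_gives_zero_matrix(self):
        lb = LagBasis()
        assert not np.any(build_crossbasis(np.zeros(50), lb))

    def test_saturated_indicator_gives_cumulative_contrast_rows(self):
        lb = LagBasis()
        cb = build_crossbasis(np.ones(40), lb)
        np.testing.assert_allclose(
            cb[10:], np.broadcast_to(lb.cumulative_contrast, (30, 4))
        )

    def test_single_pulse_reproduces_basis_rows(self):
        lb = LagBasis()
        ind = np.zeros(30)
        ind[5] = 1.0
        cb = build_crossbasis(ind, lb)
        for lag in range(11):
            np.testing.assert_allclose(cb[5 + lag], lb.basis_matrix[lag])
        assert not np.any(cb[:5]) and not np.any(cb[16:])


class TestSeasonYear:
    def test_wrapping_season_is_contiguous(self):
        from heatmort.heatwave_calendar import HotSeason

        idx = pd.date_range("2005-01-01", "2007-12-31", freq="D")
        season = HotSeason(community="c", months=(11, 12, 1, 2))
        sy = season_year(idx, season)
        dec31 = sy[(idx.month == 12) & (idx.day == 31) & (idx.year == 2005)]
        jan01 = sy[(idx.month == 1) & (idx.day == 1) & (idx.year == 2006)]
        assert dec31[0] == jan01[0] == 2005

    @pytest.mark.parametrize("years,expected", [(5, 1), (10, 1), (15, 2), (25, 3)])
    def test_trend_df_one_per_decade_with_floor(self, years, expected):
        assert trend_df_for_years(years) == expected


def _simulate(seed, **kw):
    defaults = dict(n_communities=1, years_observed=15, seed=seed)
    defaults.update(kw)
    cfg = WorldConfig(**defaults)
    records, thr = simulate_community(cfg)
    season = determine_hot_season(records["temperature"])
    return cfg, records, season


class TestFitFirstStage:
    def test_contrast_identity_saturated_vs_unexposed(self, fitted_community):
        # the fitted cumulative RR equals the model rate ratio between a
        # fully saturated lag window and a clean one, holding nuisances fixed
        _, _, _, _, fit = fitted_community
        lb = LagBasis()
        k = lb.n_columns
        lp_diff = lb.cumulative_contrast @ fit.beta[1: 1 + k]
        assert np.exp(lp_diff) == pytest.approx(fit.rr, rel=1e-12)

    def test_estimate_near_truth_single_community(self, fitted_community):
        _, _, _, _, fit = fitted_community
        lo, hi = fit.rr_ci()
        assert lo < 1.25 * 1.1 and hi > 1.25 * 0.9

    def test_irls_matches_direct_likelihood_optimum(self, fitted_community):
        from scipy.optimize import minimize
        from heatmort.stage1_dlnm import _design_matrix, _hot_season_frame
        from heatmort.stage1_dlnm import NaturalCubicSpline, trend_df_for_years

        _, records, _, season, fit = fitted_community
        lb = LagBasis()
        sub, cross = _hot_season_frame(records, season, lb)
        season_spline = NaturalCubicSpline.from_df(
            4, (1.0, float(sub["day_of_season"].max()))
        )
        total_years = (records.index[-1] - records.index[0]).days / 365.25
        trend_spline = NaturalCubicSpline.from_df(
            trend_df_for_years(total_years), (0.0, float(total_years))
        )
        X, _ = _design_matrix(sub, cross, season_spline, trend_spline, records.index[0])
        y = sub["deaths"].to_numpy(dtype=float)

        # optimise on rescaled columns for conditioning, map back afterwards
        scale = np.abs(X).max(axis=0)
        Z = X / scale

        def negloglik(gamma):
            eta = Z @ gamma
            return float(np.sum(np.exp(eta)) - y @ eta)

        def grad(gamma):
            return Z.T @ (np.exp(Z @ gamma) - y)

        start = np.zeros(Z.shape[1])
        start[0] = np.log(y.mean())
        res = minimize(negloglik, start, jac=grad, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 5000})
        np.testing.assert_allclose(res.x / scale, fit.beta, rtol=1e-5, atol=1e-7)

    def test_dispersion_scales_variance_not_estimate(self, fitted_community):
        import statsmodels.api as sm
        from heatmort.stage1_dlnm import _design_matrix, _hot_season_frame
        from heatmort.stage1_dlnm import NaturalCubicSpline, trend_df_for_years

        _, records, _, season, fit = fitted_community
        lb = LagBasis()
        sub, cross = _hot_season_frame(records, season, lb)
        season_spline = NaturalCubicSpline.from_df(
            4, (1.0, float(sub["day_of_season"].max()))
        )
        total_years = (records.index[-1] - records.index[0]).days / 365.25
        trend_spline = NaturalCubicSpline.from_df(
            trend_df_for_years(total_years), (0.0, float(total_years))
        )
        X, _ = _design_matrix(sub, cross, season_spline, trend_spline, records.index[0])
        y = sub["deaths"].to_numpy(dtype=float)
        plain = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-9)  # phi := 1
        c = lb.cumulative_contrast
        k = lb.n_columns
        theta1 = float(c @ np.asarray(plain.params)[1: 1 + k])
        v1 = float(c @ np.asarray(plain.cov_params())[1: 1 + k, 1: 1 + k] @ c)
        assert theta1 == pytest.approx(fit.theta, rel=1e-9)
        assert fit.v / v1 == pytest.approx(fit.dispersion, rel=1e-9)

    def test_no_heatwaves_refused(self):
        cfg, records, season = _simulate(4000)
        records = records.copy()
        records["heatwave"] = 0
        with pytest.raises(NoExposureVariationError):
            fit_first_stage(records, season)

    def test_short_series_refused(self):
        cfg, records, season = _simulate(4001, years_observed=2)
        one_season = records.loc[records.index.year == records.index.year[0]]
        with pytest.raises(ValueError):
            fit_first_stage(one_season, season)


class TestCrossValidation:
    def test_signal_dominated_limit_has_near_perfect_r2(self):
        pairs = []
        for seed in range(4):
            cfg, records, season = _simulate(
                4100 + seed, years_observed=10, baseline_deaths_per_day=1e5
            )
            pred, obs = cross_validate_last_year(records, season)
            if len(pred):
                pairs.append((pred, obs))
        assert sum(len(p) for p, _ in pairs) >= 5
        assert pooled_r2(pairs) > 0.99

    def test_pure_noise_has_near_zero_r2(self):
        pairs = []
        for seed in range(8):
            cfg, records, season = _simulate(
                4200 + seed, years_observed=10,
                true_log_rr_cumulative=0.0, seasonal_mortality_amplitude=0.0,
                dow_effects=(1.0,) * 7,
            )
            pred, obs = cross_validate_last_year(records, season)
            if len(pred):
                pairs.append((pred, obs))
        assert abs(pooled_r2(pairs)) < 0.1

    def test_well_specified_world_has_high_pooled_r2(self):
        # baselines spanning an order of magnitude, as in multi-city panels
        pairs = []
        for i, base in enumerate(np.geomspace(20, 200, 12)):
            cfg, records, season = _simulate(
                4300 + i, years_observed=10,
                true_log_rr_cumulative=float(np.log(1.3)),
                baseline_deaths_per_day=float(base),
            )
            pred, obs = cross_validate_last_year(records, season)
            if len(pred):
                pairs.append((pred, obs))
        assert pooled_r2(pairs) >= 0.8

    def test_requires_three_seasons(self):
        cfg, records, season = _simulate(4400, years_observed=2)
        with pytest.raises(ValueError):
            cross_validate_last_year(records, season)
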