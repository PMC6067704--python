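"""Generator contracts: determinism, calendar integrity, injected effects."""

import numpy as np
import pandas as pd
import pytest

from heatmort.heatwave_calendar import compute_threshold, detect_heatwaves
from heatmort.synthetic_world import (
    WorldConfig,
    generate_deaths,
    generate_modelled_series,
    generate_population,
    generate_temperature,
    generate_world,
    heatwave_log_rate,
)

from conftest import daily_index


class TestGenerateTemperature:
    def test_noise_free_limit_is_constant_at_climate_mean(self):
        cfg = WorldConfig(
            n_communities=1, seasonal_amplitude=0.0, daily_sd=1e-12, climate_mean=17.5
        )
        t = generate_temperature(cfg, 0, daily_index(years=2))
        assert np.allclose(t.to_numpy(), 17.5, atol=1e-9)

    def test_deseasonalised_lag1_autocorrelation_near_zero_without_ar(self):
        cfg = WorldConfig(n_communities=1, ar1_coef=0.0, seed=99)
        idx = daily_index(years=10)
        t = generate_temperature(cfg, 0, idx)
        doy = idx.dayofyear.to_numpy()
        seasonal = cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - cfg.peak_doy) / 365.25
        )
        resid = t.to_numpy() - seasonal - cfg.climate_mean
        r = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(r) < 0.05

    def test_same_seed_reproduces_series(self):
        cfg = WorldConfig(n_communities=2, seed=7)
        idx = daily_index(years=3)
        a = generate_temperature(cfg, 1, idx)
        b = generate_temperature(cfg, 1, idx)
        pd.testing.assert_series_equal(a, b)

    def test_empty_range_rejected(self):
        cfg = WorldConfig(n_communities=1)
        with pytest.raises(ValueError):
            generate_temperature(cfg, 0, pd.DatetimeIndex([]))

    def test_calendar_includes_leap_days(self):
        cfg = WorldConfig(n_communities=1, years_observed=4, obs_start_year=2001)
        idx = pd.date_range("2001-01-01", "2004-12-31", freq="D")
        t = generate_temperature(cfg, 0, idx)
        assert len(t) == 3 * 365 + 366
        assert pd.Timestamp("2004-02-29") in t.index


class TestGenerateDeaths:
    def test_null_effect_balances_heatwave_and_other_days(self):
        cfg = WorldConfig(
            n_communities=1, true_log_rr_cumulative=0.0,
            seasonal_mortality_amplitude=0.0, dow_effects=(1.0,) * 7, seed=21,
        )
        idx = daily_index(years=10)
        t = generate_temperature(cfg, 0, idx)
        cal = detect_heatwaves(t, compute_threshold(t))
        deaths = generate_deaths(cfg, t, cal.indicator)
        hw = deaths[cal.indicator == 1]
        other = deaths[cal.indicator == 0]
        se = np.sqrt(hw.var() / len(hw) + other.var() / len(other))
        assert abs(hw.mean() - other.mean()) < 3 * se

    def test_homogeneous_poisson_recovers_baseline(self):
        cfg = WorldConfig(
            n_communities=1, seasonal_mortality_amplitude=0.0,
            dow_effects=(1.0,) * 7, baseline_deaths_per_day=25.0, seed=22,
        )
        idx = daily_index(years=10)
        t = generate_temperature(cfg, 0, idx)
        deaths = generate_deaths(cfg, t, np.zeros(len(t)))
        se = np.sqrt(25.0 / len(deaths))
        assert abs(deaths.mean() - 25.0) < 4 * se

    def test_sustained_heatwave_saturates_at_cumulative_rr(self):
        # closed form: on a >= 11-day plateau the lag sum is the full log RR
        cfg = WorldConfig(
            n_communities=1, true_log_rr_cumulative=float(np.log(1.2)),
            seasonal_mortality_amplitude=0.0, dow_effects=(1.0,) * 7,
            baseline_deaths_per_day=30.0, seed=23,
        )
        n = 10_000
        idx = pd.date_range("2001-01-01", periods=n, freq="D")
        t = pd.Series(30.0, index=idx)
        deaths = generate_deaths(cfg, t, np.ones(n))
        # discard the 10-day ramp-in
        rate = deaths.iloc[10:].mean()
        expected = 30.0 * 1.2
        se = np.sqrt(expected / (n - 10))
        assert abs(rate - expected) < 4 * se

    def test_lag_rate_additivity_is_exact_before_sampling(self):
        cfg = WorldConfig(n_communities=1, true_log_rr_cumulative=float(np.log(1.3)))
        ind = np.ones(40)
        contrib = heatwave_log_rate(cfg, ind)
        assert abs(contrib[11:].max() - np.log(1.3)) < 1e-12
        assert abs(contrib[11:].min() - np.log(1.3)) < 1e-12

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(n_communities=1, baseline_deaths_per_day=-1.0)

    def test_misaligned_indicator_rejected(self):
        cfg = WorldConfig(n_communities=1)
        idx = daily_index(years=1)
        t = generate_temperature(cfg, 0, idx)
        with pytest.raises(ValueError):
            generate_deaths(cfg, t, np.zeros(10))


class TestGenerateModelledSeries:
    def test_unbiased_unwarmed_model_matches_observed_monthly_means(self):
        from scipy import stats

        cfg = WorldConfig(
            n_communities=1, gcm_bias_mean=0.0, gcm_bias_sd_ratio=1.0,
            rcp_warming={"flat": 0.0}, n_gcms=1, seed=31,
            obs_start_year=1971, years_observed=50,
        )
        idx = pd.date_range("1971-01-01", "2020-12-31", freq="D")
        obs = generate_temperature(cfg, 0, idx)
        mod = generate_modelled_series(cfg, 0, "flat").loc[:"2020-12-31"]
        for month in (1, 7):
            o = obs[obs.index.month == month]
            m = mod[mod.index.month == month]
            t, p = stats.ttest_ind(o.to_numpy(), m.to_numpy())
            assert p > 1e-4  # same seasonal model, independent draws

    def test_configured_bias_appears_in_calibration_period_mean(self):
        cfg = WorldConfig(
            n_communities=1, gcm_bias_mean=2.0, gcm_bias_sd_ratio=1.0,
            rcp_warming={"flat": 0.0}, n_gcms=1, seed=32,
            obs_start_year=1971, years_observed=50,
        )
        idx = pd.date_range("1971-01-01", "2020-12-31", freq="D")
        obs = generate_temperature(cfg, 0, idx)
        mod = generate_modelled_series(cfg, 0, "flat").loc[:"2020-12-31"]
        assert mod.mean() - obs.mean() == pytest.approx(2.0, abs=0.2)

    def test_warming_trend_magnitude(self):
        cfg = WorldConfig(
            n_communities=1, rcp_warming={"hot": 0.5}, n_gcms=1,
            gcm_warming_spread=0.0, seed=33,
        )
        mod = generate_modelled_series(cfg, 0, "hot")
        early = mod.loc["1971":"1980"].mean()
        late = mod.loc["2090":"2099"].mean()
        assert late - early == pytest.approx(0.5 * 11.9, abs=0.4)

    def test_unknown_warming_level_rejected(self):
        cfg = WorldConfig(n_communities=1)
        with pytest.raises(ValueError):
            generate_modelled_series(cfg, 0, "rcp999")


class TestGeneratePopulation:
    def test_zero_growth_is_constant(self):
        cfg = WorldConfig(n_communities=1, population_growth={"flat": 0.0})
        pop = generate_population(cfg, "flat")
        assert pop.nunique() == 1
        assert pop.index[0] == 1950 and pop.index[-1] == 2099

    def test_variant_ordering_and_ratio_growth(self):
        cfg = WorldConfig(n_communities=1)
        high = generate_population(cfg, "high")
        med = generate_population(cfg, "median")
        low = generate_population(cfg, "low")
        after = high.index > 1950
        assert (high[after] >= med[after]).all()
        assert (med[after] >= low[after]).all()
        ratio = (high / low)[after]
        assert (np.diff(ratio.to_numpy()) > 0).all()

    def test_continuous_compounding_closed_form(self):
        cfg = WorldConfig(
            n_communities=1, population_growth={"g1": 0.01}, population_base=1000.0
        )
        pop = generate_population(cfg, "g1")
        assert pop.loc[2050] / 1000.0 == pytest.approx(np.exp(1.0), abs=1e-9)

    def test_unknown_variant_rejected(self):
        cfg = WorldConfig(n_communities=1)
        with pytest.raises(ValueError, match="variant"):
            generate_population(cfg, "fancy")


class TestGenerateWorld:
    def test_world_is_deterministic_in_config(self, small_world):
        from heatmort.synthetic_world import generate_world

        again = generate_world(small_world.config)
        cid = sorted(small_world.observed)[0]
        pd.testing.assert_frame_equal(small_world.observed[cid], again.observed[cid])
        key = next(iter(small_world.modelled[cid]))
        pd.testing.assert_series_equal(
            small_world.modelled[cid][key], again.modelled[cid][key]
        )

    def test_calendar_integrity_and_integer_deaths(self, small_world):
        cfg = small_world.config
        expected_days = len(
            pd.date_range(
                f"{cfg.obs_start_year}-01-01",
                f"{cfg.obs_start_year + cfg.years_observed - 1}-12-31",
            )
        )
        for cid, rec in small_world.observed.items():
            assert len(rec) == expected_days
            assert (rec.index.to_series().diff().dropna() == pd.Timedelta("1D")).all()
            deaths = rec["deaths"]
            assert (deaths >= 0).all()
            assert (deaths == deaths.astype(int)).all()

    def test_modelled_grid_complete(self, small_world):
        cfg = small_world.config
        for cid in small_world.observed:
            keys = set(small_world.modelled[cid])
            assert keys == {
                (g, r) for g in cfg.gcm_labels() for r in cfg.rcp_warming
            }

    def test_truth_records_thresholds_and_rr(self, small_world):
        for cid in small_world.observed:
            assert cid in small_world.truth.log_rr
            assert np.isfinite(small_world.truth.thresholds[cid].value)

    def test_lag_profile_validation(self):
        with pytest.raises(ValueError):
            WorldConfig(lag_weight_profile=(1.0,) * 11)
        with pytest.raises(ValueError):
            WorldConfig(lag_weight_profile=(0.5, 0.5))
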