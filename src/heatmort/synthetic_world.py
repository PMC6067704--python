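"""Synthetic study-world generator.

Builds complete, internally consistent inputs for the projection
pipeline: observed daily temperature (sinusoidal seasonality plus AR(1)
noise), daily all-cause death counts (Poisson or gamma-frailty
overdispersed, with seasonal baseline, day-of-week effects and an
injected lag-distributed multiplicative heatwave effect), warmed and
biased "modelled" temperature series for an ensemble of pseudo-GCMs
under several emission-like warming levels, and smooth annual
population trajectories for three fertility variants.

Every quantity is a pure function of the :class:`WorldConfig`,
including its seed, so downstream estimators can be validated against
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .heatwave_calendar import (
    HeatwaveThreshold,
    compute_threshold,
    detect_heatwaves,
    determine_hot_season,
)

DAYS_PER_YEAR = 365.25

DEFAULT_LAG_WEIGHTS = tuple(w / 28.0 for w in (7, 6, 5, 4, 3, 2, 1, 0, 0, 0, 0))

# stream ids keeping the per-purpose RNGs independent
_STREAM_OBS_TEMP = 1
_STREAM_DEATHS = 2
_STREAM_MODELLED = 3
_STREAM_FRAILTY = 4


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Temperatures are in degrees Celsius, rates per day, growth rates as
    fractions per year.  ``lag_weight_profile`` distributes the total
    heatwave log relative risk over lags 0..10 and must sum to one, so
    a sustained exposure saturating the lag window multiplies the death
    rate by exactly ``exp(true_log_rr_cumulative)``.
    """

    n_communities: int = 10
    years_observed: int = 15
    obs_start_year: int = 2001
    n_countries: int = 4
    climate_mean: float = 18.0
    climate_spread: float = 5.0
    seasonal_amplitude: float = 8.0
    peak_doy: int = 200
    ar1_coef: float = 0.6
    daily_sd: float = 2.0
    baseline_deaths_per_day: float = 30.0
    seasonal_mortality_amplitude: float = 0.15
    mortality_peak_doy: int = 20
    dow_effects: tuple = (1.00, 0.99, 0.99, 1.00, 1.00, 1.01, 1.01)
    true_log_rr_cumulative: float = float(np.log(1.15))
    log_rr_sd: float = 0.0
    lag_weight_profile: tuple = DEFAULT_LAG_WEIGHTS
    overdispersion: float = 1.0
    n_gcms: int = 5
    gcm_warming_spread: float = 0.15
    rcp_warming: Mapping[str, float] = field(
        default_factory=lambda: {"rcp26": 0.10, "rcp45": 0.25, "rcp60": 0.35, "rcp85": 0.50}
    )
    gcm_bias_mean: float = 1.0
    gcm_bias_sd_ratio: float = 1.2
    population_base: float = 100_000.0
    population_growth: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.000, "median": 0.004, "high": 0.008}
    )
    population_base_year: int = 1950
    modelled_start_year: int = 1971
    modelled_end_year: int = 2099
    seed: int = 12345

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weight_profile, dtype=float)
        if w.shape != (11,):
            raise ValueError("lag_weight_profile must have length 11")
        if (w < 0).any():
            raise ValueError("lag weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weight_profile must sum to 1 within 1e-12")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.daily_sd <= 0:
            raise ValueError("daily_sd must be > 0")
        if self.population_base <= 0:
            raise ValueError("population_base must be > 0")
        if self.baseline_deaths_per_day < 0:
            raise ValueError("baseline deaths must be nonnegative")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion multiplier must be >= 1")

    # -- deterministic per-community attributes -------------------------

    def community_ids(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_communities)]

    def community_climate_means(self) -> np.ndarray:
        """Evenly spread long-term means so communities differ climatically."""
        if self.n_communities == 1:
            return np.array([self.climate_mean])
        return self.climate_mean + np.linspace(
            -self.climate_spread, self.climate_spread, self.n_communities
        )

    def community_log_rrs(self) -> np.ndarray:
        """True community log RRs: common value plus optional heterogeneity."""
        if self.log_rr_sd == 0.0:
            return np.full(self.n_communities, self.true_log_rr_cumulative)
        rng = np.random.default_rng([self.seed, 99])
        return self.true_log_rr_cumulative + self.log_rr_sd * rng.standard_normal(
            self.n_communities
        )

    def gcm_labels(self) -> list[str]:
        return [f"gcm{g + 1}" for g in range(self.n_gcms)]

    def gcm_warming_multipliers(self) -> np.ndarray:
        """Per-GCM multiplicative spread on the warming trend."""
        if self.n_gcms == 1:
            return np.array([1.0])
        return 1.0 + self.gcm_warming_spread * np.linspace(-1, 1, self.n_gcms)


@dataclass
class WorldTruth:
    """Ground truth injected by the generator, for validation."""

    log_rr: dict[str, float]
    lag_weights: np.ndarray
    thresholds: dict[str, HeatwaveThreshold]
    gcm_bias_mean: float
    gcm_bias_sd_ratio: float
    gcm_warming: dict[tuple[str, str], float]  # (gcm, rcp) -> deg C per decade


@dataclass
class SyntheticWorld:
    """Full set of pipeline inputs plus the generating truth."""

    config: WorldConfig
    observed: dict[str, pd.DataFrame]  # community -> (temperature, deaths) daily
    metadata: pd.DataFrame
    modelled: dict[str, dict[tuple[str, str], pd.Series]]  # community -> (gcm, rcp)
    population: dict[str, pd.Series]  # variant -> annual national persons
    truth: WorldTruth

    def community_population(self, community: str, variant: str) -> pd.Series:
        """National trajectory rescaled to the community's reference population."""
        nat = self.population[variant]
        ref = self.metadata.loc[community, "reference_population"]
        base = nat.loc[self.config.obs_start_year: self.config.obs_start_year
                       + self.config.years_observed - 1].mean()
        return nat * (ref / base)


def _season_cycle(dates: pd.DatetimeIndex, amplitude: float, peak_doy: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)


def _ar1_noise(n: int, ar1: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with innovation standard deviation ``sd``."""
    innov = rng.normal(0.0, sd, size=n)
    if ar1 == 0.0:
        return innov
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - ar1 * ar1))
    for t in range(1, n):
        eps[t] = ar1 * eps[t - 1] + innov[t]
    return eps


def generate_temperature(
    config: WorldConfig,
    community: int | str,
    date_range: pd.DatetimeIndex,
) -> pd.Series:
    """Observed-style daily mean temperature for one community.

    T_t = mu + A cos(2 pi (doy - peak)/365.25) + eps_t with AR(1) eps.
    Deterministic given the config seed and community.
    """
    if len(date_range) == 0:
        raise ValueError("date_range is empty")
    ci = _community_index(config, community)
    mu = config.community_climate_means()[ci]
    rng = np.random.default_rng([config.seed, _STREAM_OBS_TEMP, ci])
    seasonal = _season_cycle(date_range, config.seasonal_amplitude, config.peak_doy)
    noise = _ar1_noise(len(date_range), config.ar1_coef, config.daily_sd, rng)
    return pd.Series(mu + seasonal + noise, index=date_range, name="temperature")


def _community_index(config: WorldConfig, community: int | str) -> int:
    if isinstance(community, str):
        return config.community_ids().index(community)
    return int(community)


def heatwave_log_rate(
    config: WorldConfig,
    indicator: np.ndarray,
    log_rr: float | None = None,
) -> np.ndarray:
    """Lag-distributed log rate contribution of the heatwave indicator.

    Convolves the 0/1 exposure with ``lag_weight_profile`` scaled by the
    cumulative log RR; a window fully saturated by exposure contributes
    exactly the cumulative log RR.  Pre-sample history is taken as
    unexposed.
    """
    lrr = config.true_log_rr_cumulative if log_rr is None else log_rr
    weights = np.asarray(config.lag_weight_profile, dtype=float) * lrr
    return np.convolve(indicator.astype(float), weights)[: len(indicator)]


def generate_deaths(
    config: WorldConfig,
    temperature: pd.Series,
    heatwave_indicator: pd.Series | np.ndarray,
    community: int | str = 0,
    log_rr: float | None = None,
) -> pd.Series:
    """Daily death counts with seasonal, day-of-week and heatwave effects.

    Counts are Poisson; when ``config.overdispersion`` phi > 1 a gamma
    frailty with mean 1 multiplies the rate so the quasi-Poisson
    dispersion at the baseline rate is approximately phi.
    """
    if config.baseline_deaths_per_day < 0:
        raise ValueError("negative baseline death rate")
    dates = temperature.index
    ind = np.asarray(
        heatwave_indicator.reindex(dates).to_numpy()
        if isinstance(heatwave_indicator, pd.Series)
        else heatwave_indicator
    )
    if len(ind) != len(dates):
        raise ValueError("heatwave indicator not aligned to temperature dates")
    ci = _community_index(config, community)
    log_lambda = (
        np.log(config.baseline_deaths_per_day)
        + config.seasonal_mortality_amplitude
        * np.cos(2 * np.pi * (dates.dayofyear.to_numpy() - config.mortality_peak_doy) / DAYS_PER_YEAR)
        + np.log(np.asarray(config.dow_effects))[dates.dayofweek.to_numpy()]
        + heatwave_log_rate(config, ind, log_rr=log_rr)
    )
    lam = np.exp(log_lambda)
    rng = np.random.default_rng([config.seed, _STREAM_DEATHS, ci])
    if config.overdispersion > 1.0:
        # gamma frailty targeting quasi-Poisson dispersion phi at the baseline rate
        shape = config.baseline_deaths_per_day / (config.overdispersion - 1.0)
        frailty_rng = np.random.default_rng([config.seed, _STREAM_FRAILTY, ci])
        lam = lam * frailty_rng.gamma(shape, 1.0 / shape, size=len(lam))
    deaths = rng.poisson(lam)
    return pd.Series(deaths, index=dates, name="deaths")


def generate_modelled_series(
    config: WorldConfig,
    community: int | str,
    rcp: str,
    gcm: int | str = 0,
) -> pd.Series:
    """Pseudo-GCM daily temperature 1971-2099 for one scenario cell.

    An independent draw from the community's seasonal AR(1) model, with
    an additive mean bias, inflated daily anomalies, and a linear
    warming trend of ``rcp_warming[rcp]`` deg C per decade (times a
    per-GCM multiplier), anchored at the modelled start year.
    """
    if rcp not in config.rcp_warming:
        raise ValueError(f"warming level not configured for scenario {rcp!r}")
    ci = _community_index(config, community)
    gi = config.gcm_labels().index(gcm) if isinstance(gcm, str) else int(gcm)
    dates = pd.date_range(
        f"{config.modelled_start_year}-01-01",
        f"{config.modelled_end_year}-12-31",
        freq="D",
    )
    mu = config.community_climate_means()[ci]
    ri = sorted(config.rcp_warming).index(rcp)
    rng = np.random.default_rng([config.seed, _STREAM_MODELLED, ci, gi, ri])
    seasonal = _season_cycle(dates, config.seasonal_amplitude, config.peak_doy)
    noise = _ar1_noise(len(dates), config.ar1_coef, config.daily_sd, rng)
    warming_per_decade = config.rcp_warming[rcp] * config.gcm_warming_multipliers()[gi]
    decades = (dates - dates[0]).days.to_numpy() / (10 * DAYS_PER_YEAR)
    values = (
        mu
        + config.gcm_bias_mean
        + seasonal
        + config.gcm_bias_sd_ratio * noise
        + warming_per_decade * decades
    )
    return pd.Series(values, index=dates, name="temperature")


def generate_population(
    config: WorldConfig,
    variant: str,
    taper_years: float | None = None,
) -> pd.Series:
    """Annual national population 1950-2099 under one fertility variant.

    Continuously compounded exponential growth; an optional taper makes
    the instantaneous growth rate decay exponentially with time scale
    ``taper_years``, keeping trajectories smooth and ordered in the
    growth rate.
    """
    if variant not in config.population_growth:
        raise ValueError(
            f"unknown population variant {variant!r}; "
            f"expected one of {sorted(config.population_growth)}"
        )
    g = config.population_growth[variant]
    years = np.arange(config.population_base_year, config.modelled_end_year + 1)
    t = (years - config.population_base_year).astype(float)
    if taper_years is None:
        cum_growth = g * t
    else:
        # integral of g * exp(-u / taper) from 0 to t
        cum_growth = g * taper_years * (1.0 - np.exp(-t / taper_years))
    pop = config.population_base * np.exp(cum_growth)
    return pd.Series(pop, index=pd.Index(years, name="year"), name="population")


def simulate_community(
    config: WorldConfig,
    community: int | str = 0,
) -> tuple[pd.DataFrame, "HeatwaveThreshold"]:
    """Observed records for a single community, with the heatwave indicator.

    Returns a daily DataFrame (temperature, deaths, heatwave) over the
    observed window, plus the 95th-percentile threshold used to inject
    the mortality effect.  Convenient for single-community simulation
    studies where the full world is not needed.
    """
    dates = pd.date_range(
        f"{config.obs_start_year}-01-01",
        f"{config.obs_start_year + config.years_observed - 1}-12-31",
        freq="D",
    )
    ci = _community_index(config, community)
    temp = generate_temperature(config, ci, dates)
    thr = compute_threshold(temp, community=str(community), percentile=0.95)
    cal = detect_heatwaves(temp, thr)
    log_rr = config.community_log_rrs()[ci]
    deaths = generate_deaths(config, temp, cal.indicator, community=ci, log_rr=log_rr)
    records = pd.DataFrame(
        {"temperature": temp, "deaths": deaths, "heatwave": cal.indicator}
    )
    return records, thr


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the complete synthetic study world.

    Per community: observed temperature and deaths over the observed
    window, the year-round 95th-percentile heatwave threshold used to
    inject the mortality effect, modelled series for every pseudo-GCM x
    warming level, and metadata (country and climate-zone labels,
    hot-season climatology, reference population).
    """
    ids = config.community_ids()
    obs_dates = pd.date_range(
        f"{config.obs_start_year}-01-01",
        f"{config.obs_start_year + config.years_observed - 1}-12-31",
        freq="D",
    )
    log_rrs = config.community_log_rrs()
    observed: dict[str, pd.DataFrame] = {}
    modelled: dict[str, dict[tuple[str, str], pd.Series]] = {}
    thresholds: dict[str, HeatwaveThreshold] = {}
    meta_rows = []
    clim_means = config.community_climate_means()
    zone_edges = np.quantile(clim_means, [1 / 3, 2 / 3]) if len(ids) > 2 else None
    gcm_truth: dict[tuple[str, str], float] = {}
    mults = config.gcm_warming_multipliers()

    for ci, cid in enumerate(ids):
        temp = generate_temperature(config, ci, obs_dates)
        thr = compute_threshold(temp, community=cid, percentile=0.95)
        thresholds[cid] = thr
        cal = detect_heatwaves(temp, thr)
        deaths = generate_deaths(config, temp, cal.indicator, community=ci,
                                 log_rr=log_rrs[ci])
        observed[cid] = pd.DataFrame({"temperature": temp, "deaths": deaths})

        modelled[cid] = {}
        for gi, gcm in enumerate(config.gcm_labels()):
            for rcp in config.rcp_warming:
                modelled[cid][(gcm, rcp)] = generate_modelled_series(config, ci, rcp, gi)
                gcm_truth[(gcm, rcp)] = config.rcp_warming[rcp] * mults[gi]

        season = determine_hot_season(temp, community=cid)
        in_season = temp[season.contains(temp.index)]
        if zone_edges is None:
            zone = "temperate"
        elif clim_means[ci] <= zone_edges[0]:
            zone = "cool"
        elif clim_means[ci] <= zone_edges[1]:
            zone = "temperate"
        else:
            zone = "warm"
        meta_rows.append(
            {
                "community": cid,
                "country": f"country{ci % config.n_countries}",
                "climate_zone": zone,
                "hot_season_mean": float(in_season.mean()),
                "hot_season_range": float(in_season.max() - in_season.min()),
                "reference_population": config.population_base,
            }
        )

    metadata = pd.DataFrame(meta_rows).set_index("community")
    population = {v: generate_population(config, v) for v in config.population_growth}
    truth = WorldTruth(
        log_rr={cid: float(log_rrs[ci]) for ci, cid in enumerate(ids)},
        lag_weights=np.asarray(config.lag_weight_profile, dtype=float),
        thresholds=thresholds,
        gcm_bias_mean=config.gcm_bias_mean,
        gcm_bias_sd_ratio=config.gcm_bias_sd_ratio,
        gcm_warming=gcm_truth,
    )
    return SyntheticWorld(
        config=config,
        observed=observed,
        metadata=metadata,
        modelled=modelled,
        population=population,
        truth=truth,
    )
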