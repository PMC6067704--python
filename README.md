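# heatmort

Estimation of community-specific heatwave–mortality associations from
daily time series, and projection of heatwave-related excess deaths
under climate-change, adaptation and population scenarios.

## The problem

Heatwaves — runs of at least two consecutive days with daily mean
temperature above a community's 95th percentile of year-round daily
temperature — raise all-cause mortality. Quantifying how much that
burden will change under future warming requires chaining several
pieces of machinery:

1. **Stage 1 (per community).** A quasi-Poisson time-series regression
   of hot-season daily death counts on the binary heatwave indicator
   entered through a distributed-lag basis (lags 0–10 days; a constant
   column plus a 3-df natural cubic spline of lag), controlling for
   seasonality (4-df natural cubic spline of day-of-season), long-term
   trend (1 df per 10 years) and day of the week. The cumulative lag
   0–10 log relative risk is θᵢ = cᵀβ̂ with variance vᵢ = cᵀV̂c, where
   c sums the lag basis over all lags.
2. **Stage 2 (pooling).** A random-effects meta-regression
   θᵢ = Xᵢγ + uᵢ + εᵢ, uᵢ ~ N(0, τ²), εᵢ ~ N(0, vᵢ), with country,
   climate-zone and hot-season temperature meta-predictors; τ² by REML.
   Community relative risks are the BLUPs
   Xᵢγ̂ + λᵢ(θᵢ − Xᵢγ̂), λᵢ = τ²/(τ² + vᵢ).
3. **Climate input.** Modelled daily temperature series per GCM × RCP
   are recalibrated against observations so monthly means and the daily
   variability around them match, while the model's own warming trend
   passes through unchanged.
4. **Projection.** Annual excess deaths per scenario cell:
   EDHW(y) = N(y) · (RR − 1) · HWN(y), with N(y) = POP(y) · MR the
   expected non-heatwave daily deaths and HWN(y) the detected heatwave
   days. Period means over 1971–2020 (baseline) and 2031–2080 (future)
   give the percent change, under two adaptation assumptions (threshold
   fixed vs tracking the future 95th percentile) and three population
   variants.
5. **Uncertainty.** 1,000 Monte-Carlo samples of each community's
   pooled coefficient × the GCM ensemble give empirical 95% confidence
   intervals (2.5th/97.5th percentiles of the pooled distribution) and
   a within-/between-GCM variance decomposition.

Because the mortality archives and GCM grids such analyses rest on are
not redistributable, the package ships a seeded synthetic-world
generator (`heatmort.synthetic_world`) producing observed series,
pseudo-GCM series and population trajectories with known ground truth,
so every stage can be validated by parameter recovery.

## Worked example

```python
from heatmort import PipelineConfig, WorldConfig, run_pipeline

config = PipelineConfig(
    world=WorldConfig(n_communities=6, years_observed=12, n_countries=3,
                      n_gcms=5, rcp_warming={"rcp45": 0.25, "rcp85": 0.50},
                      seed=2024),
    n_draws=1000,
    seed=2024,
    outdir="example_output",
)
result = run_pipeline(config)
print(result.stage1_table[["community", "rr", "ci_low", "ci_high", "dispersion"]].round(3))
```

The synthetic world injects a cumulative heatwave relative risk of 1.15
in every community; the stage-1 fits recover it within their confidence
intervals, with quasi-Poisson dispersion near 1 (the generator is
Poisson by default):

```
community    rr  ci_low  ci_high  dispersion
     C000 1.195   1.128    1.266       0.983
     C001 1.153   1.073    1.239       1.016
     C002 1.216   1.133    1.305       1.006
     C003 1.172   1.107    1.241       0.995
     C004 1.113   1.041    1.190       0.998
     C005 1.171   1.096    1.252       1.011
```

The ensemble summary (all communities pooled, median population
variant) shows the qualitative pattern the projection is built to
expose — the percent increase in heatwave-related excess deaths grows
with the emission pathway, hypothetical adaptation offsets most (but
not all) of it, and the uncertainty is dominated by between-GCM spread
(within/between SD ratio well below 1):

```
  rcp              adaptation  point  eci_low  eci_high  ratio
rcp45           no_adaptation  197.9    166.7     272.2    0.0
rcp45 hypothetical_adaptation   42.5     26.5      62.5    0.1
rcp85           no_adaptation  488.7    393.8     660.1    0.0
rcp85 hypothetical_adaptation   60.6     46.1      83.5    0.1
```

`point` is the GCM-ensemble mean percent change 2031–2080 vs 1971–2020;
`eci_low`/`eci_high` bound the empirical 95% confidence interval across
1,000 coefficient draws × 5 pseudo-GCMs.

The same chain is available from the shell:

```bash
heatmort all --config config.yaml --seed 2024 --outdir out/
```

with subcommands `simulate`, `fit`, `pool`, `calibrate`, `project`,
`uncertainty` running the deterministic chain up to each stage. Output
tables: `stage1_fits.csv`, `blups.csv`, `calibration.csv`,
`projections.csv`, `country_projections.csv`, `ensemble_summary.csv`
and a `manifest.json` recording the config hash and seed.

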