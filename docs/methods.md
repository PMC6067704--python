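# Methods

This note documents the statistical models implemented in `heatmort`,
the defaults and numerical choices, what the synthetic-data generator
emulates, and the package's known limitations.

## Heatwave definition and hot season

A heatwave day belongs to a maximal run of at least `min_duration`
(default 2) consecutive days with daily mean temperature **strictly
above** the community threshold. The threshold is the empirical
percentile (default 0.95) of year-round daily temperatures over a
configurable reference period (default: the full observed span).
Percentiles use the order statistic at rank h = (n−1)p + 1 with linear
interpolation between adjacent order statistics; this choice is fixed
and shared by every percentile in the package (thresholds, adaptive
future thresholds, empirical confidence intervals) so results are
reproducible to the bit.

Strict exceedance means ties at the threshold are excluded. Missing
temperatures break runs (conservative: an unknown day is never part of
a heatwave); communities with more than 10% missing temperatures are
flagged in the logs. Runs crossing New Year contribute their days to
each calendar year separately in the annual heatwave-day counts (HWN);
episode counts attribute a run to its start year.

The hot season is the set of 4 **consecutive** calendar months
(cyclically, so a Nov–Feb season is allowed) maximising the
climatological monthly mean temperature, ties broken toward the
earliest starting month. Consecutiveness is a design choice: the 4
hottest months individually are almost always consecutive under
seasonal climate, and a contiguous window gives a well-defined
day-of-season index for the stage-1 seasonality spline.

## Stage 1: community quasi-Poisson regression

For hot-season days t:

log E[deaths_t] = α + Σⱼ βⱼ Qⱼ(t) + s₁(day-of-season; 4 df)
                + s₂(time; 1 df / 10 years) + δ_dow(t)

where Q is the crossbasis: column j at day t is
Σ_{l=0..10} HW(t−l) · B[l, j], the convolution of the year-round binary
heatwave indicator with a lag basis B. The lag basis has 4 columns: a
constant in the lag dimension plus a 3-df natural cubic spline of lag
with boundary knots {0, 10} and internal knots at 10/3 and 20/3. A
binary exposure needs the constant column to represent a uniform lag
effect; the total of 4 lag df matches the seasonality spline's
granularity. The alternative parameterisation (4-df spline, no
constant) can be supplied via `LagBasis(basis_matrix=...)`.

Lag history entering the hot season is taken from the **year-round**
indicator — a heatwave just before the season's first day counts —
with zeros only before the true start of the data.

Natural cubic splines are implemented in truncated-power form with the
second derivative constrained to zero at and beyond the boundary knots;
internal knots are equally spaced strictly between the boundaries, and
a df-column basis has df − 1 internal knots. The day-of-season spline's
knots are placed on the pooled day-of-season range (1..season length);
the trend spline covers the full observed span with
max(1, round(years/10)) df (half-up rounding). Day-of-week enters as 6
indicators against a Monday reference.

Fitting is iteratively reweighted least squares (Poisson likelihood)
with convergence tolerance 1e-9 and at most 50 iterations;
non-convergence raises. Dispersion φ is the Pearson estimator
(Pearson χ² / residual df) and the coefficient covariance is the IRLS
covariance inflated by φ, so setting φ := 1 leaves θ unchanged and
divides v by exactly φ. The residual deviance is reported per fit as a
goodness-of-fit diagnostic. A community with no heatwave day in its
series is refused with an explicit "no exposure variation" error.

The cumulative lag 0–10 log relative risk is θ = cᵀβ_lag with
v = cᵀV_lag c, where c sums the lag basis over lags 0..10; exp(θ) is
exactly the model rate ratio between a day whose 11-day lag window is
fully saturated with heatwave exposure and an identical day with none.

**Cross-validation.** The last hot season is held out, the model refit,
and deaths predicted on the held-out season's heatwave days; quality is
the squared Pearson correlation of pooled (predicted, observed) pairs
across communities. Pooled R² is dominated by between-community
differences in death counts: when all communities share one baseline
rate, within-community Poisson noise caps R² well below 1 even for a
perfectly specified model, whereas baselines spanning an order of
magnitude (as in real multi-city panels) yield R² above 0.9. The test
suite exercises both regimes.

## Stage 2: random-effects meta-regression and BLUPs

θᵢ = Xᵢγ + uᵢ + εᵢ with uᵢ ~ N(0, τ²), εᵢ ~ N(0, vᵢ). Predictors:
intercept, country indicators, climate-zone indicators (first-level
reference coding), and the community's hot-season mean and range of
temperature, unstandardised. Columns that are collinear with earlier
ones — or that would leave fewer than two residual degrees of freedom —
are dropped with a logged warning; indicators for a level carried by a
single community are likewise dropped (they would be confounded with
that community's residual).

τ² is estimated by REML: the profile restricted log-likelihood

−½ [ Σ log(vᵢ+τ²) + log|Xᵀ W X| + Σ wᵢ (θᵢ − Xᵢγ̂)² ],  wᵢ = 1/(vᵢ+τ²)

is maximised over τ² ≥ 0 by bounded scalar optimisation (tolerance
1e-10), snapping to 0 when the boundary is no worse. A
DerSimonian–Laird moment estimator (negative values truncated to zero)
is available as `method="mom"` for degenerate fits. γ̂ is then weighted
least squares with weights wᵢ and covariance (XᵀWX)⁻¹.

BLUPs: with λᵢ = τ²/(τ² + vᵢ),
mean = Xᵢγ̂ + λᵢ(θᵢ − Xᵢγ̂) and
variance = λᵢvᵢ + (1 − λᵢ)² XᵢV̂_γXᵢᵀ. The BLUP always lies between the
community's own estimate and its meta-prediction. Pooling is univariate
on the scalar cumulative log RR (not multivariate over the 4 lag
coefficients), because the projection consumes only the cumulative
relative risk; this is a deliberate simplification relative to
multivariate pooling of full lag curves. Meta-prediction is applied to
the historical estimates only.

## Recalibration of modelled temperature

For each calendar month m over a calibration period (default: the full
observed overlap): offset C_m = mean_obs(m) − mean_mod(m), and scale
s_m = SD of observed daily anomalies about their year-month means
divided by the modelled counterpart (anomaly SDs use ddof = 0; s_m is
floored at 0.1 and capped at 10 with a warning). The correction is

corrected_t = M_t + C_m + s_m · (modelled_t − M_t)

where M_t is the model's own mean within day t's specific year-month.
Anchoring anomalies to *running* year-month means (not climatological
means) is what preserves the model's warming signal: within every
year-month the corrected mean exceeds the modelled mean by exactly C_m,
so trends in the model's monthly means pass through unchanged. The map
is monotone affine within each year-month, hence rank-preserving. This
is a transparent simplification of the full ISIMIP-style
transfer-function approach; no smoothing is applied across month
boundaries.

A known finite-window property follows from estimating C_m on a window
inside the baseline period: within the calibration window the
year-month means lose about 1/W of their between-year variance to the
estimated offset (W = window length in years) while years outside gain
it, and because exceedance of a high threshold is convex in the yearly
mean, calibration-window years carry slightly fewer detected heatwave
days. In a stationary no-warming world this puts a small positive bias
(about +1% at a 12-year window against 50-year periods) on the null
percent change — far inside the projection's Monte-Carlo uncertainty,
and diagnosed explicitly in the test suite.

## Projection

Per community and scenario cell (RCP × GCM × adaptation × population
variant): EDHW(y) = N(y) · (RR − 1) · HWN(y), with

- MR = mean daily deaths on observed **non-heatwave** days divided by
  mean population over the observed years; N(y) = MR · POP(y);
- RR the stage-2 BLUP relative risk, held constant over time;
- HWN(y) from run detection on the recalibrated modelled series. The
  baseline period (default 1971–2020) always uses the current
  (observed-data) threshold under both adaptation assumptions;
  adaptation changes only the future (2031–2080) threshold, to the 95th
  percentile of the modelled series within the future period. The
  modelled corrected series is used for both periods, since
  observations do not span the full baseline.
- POP(y): the national trajectory of the chosen variant rescaled so its
  observed-years mean equals the community's reference population.

Period summaries are annual means over each period; percent change is
100 · (future − baseline)/baseline, with a flagged NaN sentinel when the
baseline is zero. Country aggregates sum annual excess deaths across
communities first and recompute the percent change from the sums —
never averaging community-level percent changes.

## Monte-Carlo uncertainty

Coefficient uncertainty is propagated by drawing n (default 1,000)
samples of each community's BLUP log RR from N(blup mean, blup var);
sampling is at the BLUP level rather than re-drawing stage-1
coefficient vectors, keeping the draw dimension scalar per community
(re-drawing the 4 lag coefficients would be the multivariate
extension). Draws use common random numbers across scenario cells (one
stream per community) so scenario contrasts are not noise-dominated.
The point estimate is the GCM-ensemble mean at the central
coefficients; the 95% eCI is the 2.5th/97.5th empirical percentile of
the pooled draws × GCMs distribution, using the same anchored-linear
percentile as everywhere else. The variance decomposition reports the
mean within-GCM SD across draws, the SD of per-GCM draw means, and
their ratio (flagged infinite when GCMs are identical).

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as plausible mid-latitude values:

- **Temperature**: T_t = μ + A·cos(2π(doy − peak)/365.25) + ε_t, with
  AR(1) ε (coefficient 0.6, innovation SD 2 °C), amplitude 8 °C, peak
  at day 200 (northern-hemisphere-like, so the hot season is a
  contiguous mid-year block); community means spread ±5 °C around
  18 °C. Calendars are exact (leap days included).
- **Deaths**: Poisson with log-rate = log(baseline 30/day) + a seasonal
  cycle (amplitude 0.15 on the log scale, peaking in winter) + log
  day-of-week factors + the lag-distributed heatwave effect: the
  0/1 indicator convolved with an 11-point decaying weight profile
  summing to 1, scaled by the cumulative log RR (default log 1.15), so
  a ≥11-day heatwave plateau multiplies the rate by exactly the target
  RR. An optional gamma frailty (mean 1, shape baseline/(φ−1)) targets
  quasi-Poisson dispersion φ at the baseline rate, letting dispersion
  recovery be tested at φ ≈ 1 and φ = 2.
- **Pseudo-GCMs** (default 5, mirroring the usual CMIP5 subset):
  independent draws of the same seasonal AR(1) model plus an additive
  mean bias (default +1 °C), an anomaly-SD inflation (default 1.2), and
  a linear warming trend per RCP-like level (defaults 0.10/0.25/0.35/
  0.50 °C per decade) with a ±15% per-GCM multiplier so the ensemble
  has genuine between-model spread.
- **Population**: continuously compounded exponential trajectories
  1950–2099 per variant (defaults 0/0.4/0.8% per year for low/median/
  high), with an optional exponential taper of the growth rate;
  trajectories are ordered in the growth rate at every year. Annual
  totals suffice for the projection, so no cohort demography is
  modelled.

All randomness derives from a single seed expanded into per-purpose,
per-community streams; the whole world is a pure function of its
config. The generator does **not** emulate spatial correlation between
communities, humidity or pollution confounding, demographic structure,
changing baseline mortality, or non-stationary variance in the climate
— so passing tests demonstrate correctness of the estimation machinery
under the model's own assumptions, not robustness to the ways real data
violate them.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down worlds chosen
to keep parameter-recovery checks sharp: 200 replicate communities for
stage-1 recovery (truth RR 1.25, 15 hot seasons, 30 deaths/day), 500
null replicates for CI coverage, 200 communities for REML recovery
(τ² = 0.02), and 6–12 community worlds with 5 pseudo-GCMs for
end-to-end runs. REML optima are validated against a 10⁴-point grid
scan of the restricted likelihood; heatwave detection against an
independent brute-force run-length scan; percentiles against the closed
form. Degenerate inputs (empty series, missing months, no exposure
variation, rank-deficient designs, zero baselines) raise explicit
errors rather than propagating silently; ties in the hot-season search
break to the earliest month; the REML boundary τ² = 0 is preferred when
the likelihood is flat.

## Limitations

- The exposure is the binary heatwave indicator; no continuous
  temperature–mortality dose-response curve, no cold effects, no
  intensity-weighted heatwave definitions.
- The recalibration is a monthly shift/scale stand-in for the full
  ISIMIP transfer-function method (no daily interpolation across month
  boundaries, no grid handling).
- RR is held fixed over time within a scenario; effect modification by
  future heatwave intensity is out of scope.
- Population before 1950 or after 2099 is never extrapolated; period
  bounds are validated against the population series.
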