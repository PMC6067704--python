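"""End-to-end orchestration: simulate/ingest -> detect -> fit -> pool ->
recalibrate -> project -> uncertainty.

All randomness flows from a single root seed expanded into per-purpose,
per-community streams, so a config (including its seed) fully
determines every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .gcm_recalibration import CalibrationParams, recalibrate
from .heatwave_calendar import (
    HYPOTHETICAL_ADAPTATION,
    NO_ADAPTATION,
    HeatwaveCalendar,
    HeatwaveThreshold,
    HotSeason,
    compute_threshold,
    detect_heatwaves,
    determine_hot_season,
)
from .scenario_projection import (
    ExcessDeathSummary,
    ScenarioCell,
    aggregate_to_country,
    annual_hwn_series,
    estimate_baseline_mortality,
    project_excess_deaths,
    summary_row,
)
from .stage1_dlnm import (
    FirstStageFit,
    LagBasis,
    NoExposureVariationError,
    first_stage_table,
    fit_first_stage,
)
from .stage2_meta import MetaFit, blup_table, build_meta_design, fit_meta_regression
from .synthetic_world import SyntheticWorld, WorldConfig, generate_world
from .uncertainty_mc import MonteCarloEnsemble, decompose_variance

logger = logging.getLogger(__name__)

STAGES = ["simulate", "fit", "pool", "calibrate", "project", "uncertainty"]


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline, serialisable to YAML."""

    world: WorldConfig | None = field(default_factory=WorldConfig)
    input_daily: str | None = None
    input_metadata: str | None = None
    input_modelled: str | None = None
    input_population: str | None = None
    percentile: float = 0.95
    min_duration: int = 2
    meta_method: str = "reml"
    adaptations: tuple = (NO_ADAPTATION, HYPOTHETICAL_ADAPTATION)
    baseline_period: tuple = (1971, 2020)
    future_period: tuple = (2031, 2080)
    n_draws: int = 1000
    seed: int = 0
    outdir: str = "heatmort_output"

    def __post_init__(self) -> None:
        b, f = tuple(self.baseline_period), tuple(self.future_period)
        if not (b[0] <= b[1] < f[0] <= f[1]):
            raise ValueError("analysis periods must be ordered and non-overlapping")
        self.baseline_period, self.future_period = b, f
        self.adaptations = tuple(self.adaptations)
        if isinstance(self.world, dict):
            self.world = WorldConfig(**self.world)
        if self.world is None:
            for p in (self.input_daily, self.input_metadata,
                      self.input_modelled, self.input_population):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path missing or not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("world") is not None:
            d["world"]["rcp_warming"] = dict(d["world"]["rcp_warming"])
            d["world"]["population_growth"] = dict(d["world"]["population_growth"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's outputs."""

    config: PipelineConfig
    world: SyntheticWorld | None
    observed: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    thresholds: dict[str, HeatwaveThreshold]
    hot_seasons: dict[str, HotSeason]
    calendars: dict[str, HeatwaveCalendar]
    fits: dict[str, FirstStageFit] = field(default_factory=dict)
    meta_fit: MetaFit | None = None
    stage1_table: pd.DataFrame | None = None
    blups: pd.DataFrame | None = None
    calibration: dict[str, dict[tuple[str, str], CalibrationParams]] = field(default_factory=dict)
    corrected: dict[str, dict[tuple[str, str], pd.Series]] = field(default_factory=dict)
    calibration_table: pd.DataFrame | None = None
    projections: pd.DataFrame | None = None
    country_projections: pd.DataFrame | None = None
    ensemble_table: pd.DataFrame | None = None

    def blup_for(self, community: str) -> tuple[float, float]:
        row = self.blups.set_index("community").loc[community]
        return float(row["blup_log_rr"]), float(row["blup_var"])


def _load_inputs(config: PipelineConfig):
    if config.world is not None:
        world = generate_world(config.world)
        modelled = world.modelled
        population = world.population
        return world, world.observed, world.metadata, modelled, population
    observed = hio.read_daily_csv(config.input_daily)
    metadata = hio.read_metadata_csv(config.input_metadata)
    modelled = hio.read_modelled_csv(config.input_modelled)
    population = hio.read_population_csv(config.input_population)
    return None, observed, metadata, modelled, population


def _community_population(result: PipelineResult, community: str, variant: str,
                          population: dict[str, pd.Series]) -> pd.Series:
    """National trajectory rescaled to the community's reference population."""
    nat = population[variant]
    ref = float(result.metadata.loc[community, "reference_population"])
    obs_years = result.observed[community].index.year.unique()
    base = float(nat.reindex(obs_years).dropna().mean())
    return nat * (ref / base)


def run_pipeline(
    config: PipelineConfig,
    through: str = "uncertainty",
    write: bool = True,
) -> PipelineResult:
    """Run the chain up to and including ``through`` and write outputs.

    Rerunning with an identical config reproduces identical outputs.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    last = STAGES.index(through)
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages_completed": [],
        "incomplete": None,
    }

    world, observed, metadata, modelled, population = _load_inputs(config)

    thresholds, hot_seasons, calendars = {}, {}, {}
    for cid in sorted(observed):
        temp = observed[cid]["temperature"]
        thresholds[cid] = compute_threshold(temp, community=cid, percentile=config.percentile)
        hot_seasons[cid] = determine_hot_season(temp, community=cid)
        calendars[cid] = detect_heatwaves(temp, thresholds[cid], config.min_duration)
        logger.info(
            "community %s: threshold %.2f degC, %d heatwave days, hot season %s",
            cid, thresholds[cid].value, calendars[cid].total_heatwave_days,
            hot_seasons[cid].months,
        )
    result = PipelineResult(
        config=config, world=world, observed=observed, metadata=metadata,
        thresholds=thresholds, hot_seasons=hot_seasons, calendars=calendars,
    )
    manifest["stages_completed"].append("simulate")
    if write and world is not None:
        hio.write_daily_csv(observed, outdir / "daily.csv")
        hio.write_metadata_csv(metadata, outdir / "metadata.csv")
        hio.write_population_csv(population, outdir / "population.csv")

    try:
        if last >= STAGES.index("fit"):
            _stage_fit(result)
            manifest["stages_completed"].append("fit")
            if write:
                result.stage1_table.to_csv(outdir / "stage1_fits.csv", index=False)
        if last >= STAGES.index("pool"):
            _stage_pool(result)
            manifest["stages_completed"].append("pool")
            if write:
                result.blups.to_csv(outdir / "blups.csv", index=False)
        if last >= STAGES.index("calibrate"):
            _stage_calibrate(result, modelled)
            manifest["stages_completed"].append("calibrate")
            if write:
                result.calibration_table.to_csv(outdir / "calibration.csv", index=False)
        if last >= STAGES.index("project"):
            _stage_project(result, population)
            manifest["stages_completed"].append("project")
            if write:
                result.projections.to_csv(outdir / "projections.csv", index=False)
                result.country_projections.to_csv(
                    outdir / "country_projections.csv", index=False
                )
        if last >= STAGES.index("uncertainty"):
            _stage_uncertainty(result, population)
            manifest["stages_completed"].append("uncertainty")
            if write:
                result.ensemble_table.to_csv(outdir / "ensemble_summary.csv", index=False)
    except Exception as exc:
        manifest["incomplete"] = f"{type(exc).__name__}: {exc}"
        if write:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    if write:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _stage_fit(result: PipelineResult) -> None:
    lag_basis = LagBasis()
    for cid in sorted(result.observed):
        records = result.observed[cid].copy()
        records["heatwave"] = result.calendars[cid].indicator
        try:
            fit = fit_first_stage(
                records, result.hot_seasons[cid], lag_basis, community=cid
            )
        except NoExposureVariationError as exc:
            logger.warning("skipping %s: %s", cid, exc)
            continue
        result.fits[cid] = fit
    if not result.fits:
        raise RuntimeError("stage fit: no community could be fitted")
    result.stage1_table = first_stage_table(list(result.fits.values()))


def _stage_pool(result: PipelineResult) -> None:
    fitted = sorted(result.fits)
    meta = result.metadata.loc[fitted]
    design = build_meta_design(meta)
    theta = np.array([result.fits[c].theta for c in fitted])
    v = np.array([result.fits[c].v for c in fitted])
    result.meta_fit = fit_meta_regression(theta, v, design, method=result.config.meta_method)
    result.blups = blup_table(result.meta_fit, theta, v)


def _stage_calibrate(result: PipelineResult, modelled) -> None:
    rows = []
    for cid in sorted(result.fits):
        obs_temp = result.observed[cid]["temperature"]
        result.corrected[cid] = {}
        result.calibration[cid] = {}
        for key in sorted(modelled[cid]):
            corrected, params = recalibrate(obs_temp, modelled[cid][key])
            result.corrected[cid][key] = corrected
            result.calibration[cid][key] = params
            for m in range(1, 13):
                rows.append(
                    {
                        "community": cid, "gcm": key[0], "rcp": key[1], "month": m,
                        "offset": params.offset[m], "scale": params.scale[m],
                    }
                )
    result.calibration_table = pd.DataFrame(rows)


def _scenario_grid(result: PipelineResult, population) -> list[ScenarioCell]:
    some = next(iter(result.corrected.values()))
    gcms = sorted({g for g, _ in some})
    rcps = sorted({r for _, r in some})
    return [
        ScenarioCell(rcp=r, gcm=g, adaptation=a, population_variant=vv)
        for r in rcps for g in gcms
        for a in result.config.adaptations for vv in sorted(population)
    ]


def _stage_project(result: PipelineResult, population) -> None:
    cfg = result.config
    rows, country_rows = [], []
    cells = _scenario_grid(result, population)
    summaries: dict[tuple, list[ExcessDeathSummary]] = {}
    hwn_cache: dict[tuple, pd.Series] = {}
    for cid in sorted(result.fits):
        blup_lrr, _ = result.blup_for(cid)
        rr = float(np.exp(blup_lrr))
        country = str(result.metadata.loc[cid, "country"])
        baselines = {
            vv: estimate_baseline_mortality(
                result.observed[cid], result.calendars[cid],
                _community_population(result, cid, vv, population), community=cid,
            )
            for vv in sorted(population)
        }
        for cell in cells:
            key = (cid, cell.gcm, cell.rcp, cell.adaptation)
            if key not in hwn_cache:
                hwn_cache[key] = annual_hwn_series(
                    result.corrected[cid][(cell.gcm, cell.rcp)],
                    result.thresholds[cid], cell.adaptation,
                    cfg.baseline_period, cfg.future_period, cfg.min_duration,
                )
            summary = project_excess_deaths(
                cell,
                result.corrected[cid][(cell.gcm, cell.rcp)],
                rr,
                baselines[cell.population_variant],
                result.thresholds[cid],
                _community_population(result, cid, cell.population_variant, population),
                cfg.baseline_period, cfg.future_period, cfg.min_duration,
                hwn=hwn_cache[key],
            )
            rows.append(summary_row(summary, country=country))
            summaries.setdefault((country, cell), []).append(summary)
    for (country, cell), group in sorted(
        summaries.items(), key=lambda kv: (kv[0][0],) + dataclasses.astuple(kv[0][1])
    ):
        agg = aggregate_to_country(group, label=country)
        country_rows.append(summary_row(agg, country=country))
    result.projections = pd.DataFrame(rows)
    result.country_projections = pd.DataFrame(country_rows)
    result._hwn_cache = hwn_cache  # reused by the uncertainty stage


def _stage_uncertainty(result: PipelineResult, population) -> None:
    """Monte-Carlo eCIs for country-level percent change and future excess deaths.

    Coefficient draws use common random numbers per community across
    scenario cells; within a cell the metric is evaluated for every
    draw x GCM and pooled.
    """
    cfg = result.config
    hwn_cache = result._hwn_cache
    fitted = sorted(result.fits)
    byear = range(cfg.baseline_period[0], cfg.baseline_period[1] + 1)
    fyear = range(cfg.future_period[0], cfg.future_period[1] + 1)

    # per-community coefficient draws, common across scenario cells
    draws = {}
    for ci, cid in enumerate(fitted):
        mean, var = result.blup_for(cid)
        rng = np.random.default_rng([cfg.seed, 7, ci])
        draws[cid] = mean + np.sqrt(var) * rng.standard_normal(cfg.n_draws)

    some = next(iter(result.corrected.values()))
    gcms = sorted({g for g, _ in some})
    rcps = sorted({r for _, r in some})
    countries = sorted(result.metadata.loc[fitted, "country"].unique())

    # scalar factors: per (community, gcm, rcp, adaptation, variant),
    # mean annual N * HWN over each period -- EDHW is that times (RR - 1)
    base_fac: dict[tuple, float] = {}
    fut_fac: dict[tuple, float] = {}
    mrs = {
        cid: estimate_baseline_mortality(
            result.observed[cid], result.calendars[cid],
            _community_population(result, cid, sorted(population)[0], population),
            community=cid,
        ).mr
        for cid in fitted
    }
    for cid in fitted:
        for g in gcms:
            for r in rcps:
                for a in cfg.adaptations:
                    hwn = hwn_cache[(cid, g, r, a)]
                    for vv in sorted(population):
                        pop = _community_population(result, cid, vv, population)
                        nh = mrs[cid] * pop.reindex(hwn.index) * hwn
                        base_fac[(cid, g, r, a, vv)] = float(nh.loc[byear[0]:byear[-1]].mean())
                        fut_fac[(cid, g, r, a, vv)] = float(nh.loc[fyear[0]:fyear[-1]].mean())

    rows = []
    for country in countries + ["TOTAL"]:
        members = (
            fitted
            if country == "TOTAL"
            else [c for c in fitted if result.metadata.loc[c, "country"] == country]
        )
        for r in rcps:
            for a in cfg.adaptations:
                for vv in sorted(population):
                    draw_pct = np.empty((cfg.n_draws, len(gcms)))
                    draw_fut = np.empty((cfg.n_draws, len(gcms)))
                    point_pct, point_fut = [], []
                    for j, g in enumerate(gcms):
                        bmat = np.array([base_fac[(c, g, r, a, vv)] for c in members])
                        fmat = np.array([fut_fac[(c, g, r, a, vv)] for c in members])
                        excess = np.column_stack([np.expm1(draws[c]) for c in members])
                        base_tot = excess @ bmat
                        fut_tot = excess @ fmat
                        with np.errstate(divide="ignore", invalid="ignore"):
                            draw_pct[:, j] = 100.0 * (fut_tot - base_tot) / base_tot
                        draw_fut[:, j] = fut_tot
                        central = np.array(
                            [np.expm1(result.blup_for(c)[0]) for c in members]
                        )
                        cb, cf = central @ bmat, central @ fmat
                        point_pct.append(100.0 * (cf - cb) / cb if cb != 0 else np.nan)
                        point_fut.append(cf)
                    for metric, dmat, points in (
                        ("percent_change", draw_pct, point_pct),
                        ("future_excess_deaths", draw_fut, point_fut),
                    ):
                        ens = MonteCarloEnsemble(
                            draws=dmat, gcms=gcms,
                            point_estimate=float(np.mean(points)), seed=cfg.seed,
                        )
                        dec = decompose_variance(ens) if len(gcms) > 1 else None
                        lo, hi = ens.eci
                        rows.append(
                            {
                                "country": country, "rcp": r, "adaptation": a,
                                "variant": vv, "metric": metric,
                                "point": ens.point_estimate,
                                "eci_low": lo, "eci_high": hi,
                                "within_sd": dec.within_gcm_sd if dec else np.nan,
                                "between_sd": dec.between_gcm_sd if dec else np.nan,
                                "ratio": dec.ratio if dec else np.nan,
                            }
                        )
    result.ensemble_table = pd.DataFrame(rows)
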