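"""Projection of heatwave-related excess deaths under climate scenarios.

For each community and scenario cell (emission pathway x GCM x
adaptation assumption x population variant) annual excess deaths are

    EDHW(y) = N(y) * (RR - 1) * HWN(y)

where N(y) = POP(y) * MR is the expected number of deaths on
non-heatwave days in year y (MR is the historical daily mortality rate
on non-heatwave days), RR the community's pooled relative risk, and
HWN(y) the number of heatwave days detected in the bias-corrected
modelled series.  Period summaries average annual excess deaths over
the baseline (1971-2020) and future (2031-2080) periods, and the
percent change compares the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heatwave_calendar import (
    HYPOTHETICAL_ADAPTATION,
    NO_ADAPTATION,
    HeatwaveCalendar,
    HeatwaveThreshold,
    detect_heatwaves,
    future_threshold,
)

logger = logging.getLogger(__name__)

BASELINE_PERIOD = (1971, 2020)
FUTURE_PERIOD = (2031, 2080)

#: sentinel for a percent change with zero baseline (0/0)
PERCENT_CHANGE_UNDEFINED = float("nan")


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the scenario grid."""

    rcp: str
    gcm: str
    adaptation: str
    population_variant: str

    def __post_init__(self) -> None:
        if self.adaptation not in (NO_ADAPTATION, HYPOTHETICAL_ADAPTATION):
            raise ValueError(f"unknown adaptation assumption {self.adaptation!r}")


@dataclass
class BaselineMortality:
    """Historical daily mortality rate on non-heatwave days."""

    community: str
    mr: float  # deaths per person per day
    reference_population: float

    def n_of(self, population: float) -> float:
        """Expected non-heatwave daily deaths at a given population."""
        return population * self.mr


@dataclass
class ExcessDeathSummary:
    """Annual excess deaths and period summaries for one scenario cell."""

    community: str
    cell: ScenarioCell | None
    annual_edhw: pd.Series  # indexed by year
    baseline_years: tuple[int, int] = BASELINE_PERIOD
    future_years: tuple[int, int] = FUTURE_PERIOD

    @property
    def period_mean_baseline(self) -> float:
        lo, hi = self.baseline_years
        return float(self.annual_edhw.loc[lo:hi].mean())

    @property
    def period_mean_future(self) -> float:
        lo, hi = self.future_years
        return float(self.annual_edhw.loc[lo:hi].mean())

    @property
    def percent_change(self) -> float:
        base = self.period_mean_baseline
        if base == 0.0:
            return PERCENT_CHANGE_UNDEFINED
        return 100.0 * (self.period_mean_future - base) / base


def estimate_baseline_mortality(
    records: pd.DataFrame,
    calendar: HeatwaveCalendar,
    population: pd.Series,
    community: str = "",
) -> BaselineMortality:
    """Daily mortality rate on non-heatwave days, per person.

    MR = mean daily deaths over observed non-heatwave days, divided by
    the mean population over the observed years.
    """
    ind = calendar.indicator.reindex(records.index).fillna(0).to_numpy()
    non_hw = records.loc[ind == 0, "deaths"]
    if non_hw.empty:
        raise ValueError(f"community {community or '?'}: no non-heatwave days")
    years = records.index.year.unique()
    pop = population.reindex(years).dropna()
    if pop.empty:
        raise ValueError("population series does not overlap the observed records")
    mean_pop = float(pop.mean())
    mr = float(non_hw.mean()) / mean_pop
    return BaselineMortality(
        community=community, mr=mr, reference_population=mean_pop
    )


def annual_hwn_series(
    corrected: pd.Series,
    current_threshold: HeatwaveThreshold,
    adaptation: str,
    baseline_period: tuple[int, int] = BASELINE_PERIOD,
    future_period: tuple[int, int] = FUTURE_PERIOD,
    min_duration: int = 2,
) -> pd.Series:
    """Heatwave days per year in the corrected modelled series.

    The baseline period always uses the current (observed-data)
    threshold; the future period uses either the same threshold (no
    adaptation) or the future 95th percentile (hypothetical
    adaptation).  Adaptation concerns future acclimatisation only.
    """
    base_cal = detect_heatwaves(corrected, current_threshold, min_duration)
    fut_thr = future_threshold(
        corrected,
        adaptation,
        current_threshold,
        future_period=(f"{future_period[0]}-01-01", f"{future_period[1]}-12-31"),
    )
    fut_cal = (
        base_cal
        if fut_thr.value == current_threshold.value
        else detect_heatwaves(corrected, fut_thr, min_duration)
    )
    years = np.arange(corrected.index[0].year, corrected.index[-1].year + 1)
    hwn = np.array(
        [
            fut_cal.annual_hwn.get(int(y), 0)
            if future_period[0] <= y <= future_period[1]
            else base_cal.annual_hwn.get(int(y), 0)
            for y in years
        ],
        dtype=float,
    )
    return pd.Series(hwn, index=pd.Index(years, name="year"), name="hwn")


def project_excess_deaths(
    cell: ScenarioCell,
    corrected_series: pd.Series,
    rr: float,
    baseline: BaselineMortality,
    current_threshold: HeatwaveThreshold,
    population: pd.Series,
    baseline_period: tuple[int, int] = BASELINE_PERIOD,
    future_period: tuple[int, int] = FUTURE_PERIOD,
    min_duration: int = 2,
    hwn: pd.Series | None = None,
) -> ExcessDeathSummary:
    """Annual EDHW = N * (RR - 1) * HWN over both analysis periods.

    ``hwn`` may be supplied to reuse a precomputed heatwave-day series
    (it depends only on the corrected series, thresholds and adaptation
    assumption, not on RR or population).
    """
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    first, last = corrected_series.index[0].year, corrected_series.index[-1].year
    if first > baseline_period[0] or last < future_period[1]:
        raise ValueError("corrected series does not cover both analysis periods")
    if hwn is None:
        hwn = annual_hwn_series(
            corrected_series, current_threshold, cell.adaptation,
            baseline_period, future_period, min_duration,
        )
    pop = population.reindex(hwn.index)
    if pop.isna().any():
        missing = hwn.index[pop.isna()]
        raise ValueError(
            f"population series missing years {missing[0]}..{missing[-1]}"
        )
    n_daily = baseline.mr * pop
    annual = n_daily * (rr - 1.0) * hwn
    summary = ExcessDeathSummary(
        community=baseline.community,
        cell=cell,
        annual_edhw=annual,
        baseline_years=baseline_period,
        future_years=future_period,
    )
    if summary.period_mean_baseline == 0.0:
        logger.warning(
            "community %s cell %s: zero baseline excess deaths, percent change undefined",
            baseline.community, cell,
        )
    return summary


def aggregate_to_country(
    summaries: list[ExcessDeathSummary], label: str = ""
) -> ExcessDeathSummary:
    """Sum annual excess deaths across communities sharing a scenario cell.

    The percent change is recomputed from the aggregated sums, not
    averaged over community-level percent changes.
    """
    if not summaries:
        raise ValueError("nothing to aggregate")
    cells = {s.cell for s in summaries}
    if len(cells) > 1:
        raise ValueError(f"cannot aggregate across scenario cells: {cells}")
    first = summaries[0]
    total = sum((s.annual_edhw for s in summaries[1:]), first.annual_edhw.copy())
    return ExcessDeathSummary(
        community=label or "+".join(s.community for s in summaries),
        cell=first.cell,
        annual_edhw=total,
        baseline_years=first.baseline_years,
        future_years=first.future_years,
    )


def summary_row(s: ExcessDeathSummary, country: str = "") -> dict:
    cell = s.cell
    return {
        "community": s.community,
        "country": country,
        "rcp": cell.rcp if cell else "",
        "gcm": cell.gcm if cell else "",
        "adaptation": cell.adaptation if cell else "",
        "variant": cell.population_variant if cell else "",
        "period_mean_baseline": s.period_mean_baseline,
        "period_mean_future": s.period_mean_future,
        "percent_change": s.percent_change,
    }
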