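"""Heatwave definition and detection.

A heatwave is a run of at least ``min_duration`` (default 2) consecutive
days on which the daily mean temperature strictly exceeds a
community-specific threshold, by default the 95th percentile of the
year-round daily temperature distribution.  This module derives
thresholds, scans daily series for heatwave runs, counts heatwave days
per year (HWN), and selects each community's hot season (the four
hottest consecutive calendar months).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NO_ADAPTATION = "no_adaptation"
HYPOTHETICAL_ADAPTATION = "hypothetical_adaptation"


@dataclass(frozen=True)
class HeatwaveThreshold:
    """Absolute temperature threshold defining heatwave days for one community."""

    community: str
    value: float
    percentile: float = 0.95
    source_period: tuple[pd.Timestamp, pd.Timestamp] | None = None
    assumption: str = NO_ADAPTATION

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError(f"percentile must be in (0, 1), got {self.percentile}")
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")


@dataclass
class HeatwaveCalendar:
    """Per-day heatwave indicator plus run structure and annual summaries.

    ``indicator`` is a 0/1 integer series on the same daily index as the
    input temperatures.  ``runs`` lists (start date, length in days) of
    each maximal heatwave episode.  ``annual_hwn[y]`` is the number of
    heatwave days falling in calendar year ``y`` (a run crossing New
    Year contributes days to both years); ``annual_event_count[y]``
    counts episodes by their start year.
    """

    community: str
    indicator: pd.Series
    runs: list[tuple[pd.Timestamp, int]] = field(default_factory=list)
    annual_hwn: dict[int, int] = field(default_factory=dict)
    annual_event_count: dict[int, int] = field(default_factory=dict)

    @property
    def total_heatwave_days(self) -> int:
        return int(self.indicator.sum())

    def hwn_for_years(self, years: Sequence[int]) -> int:
        """Total heatwave days over a set of calendar years."""
        return sum(self.annual_hwn.get(int(y), 0) for y in years)


@dataclass(frozen=True)
class HotSeason:
    """The four hottest consecutive calendar months of a community.

    Months may wrap the year boundary (e.g. (11, 12, 1, 2) in the
    southern hemisphere).
    """

    community: str
    months: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.months)) != 4:
            raise ValueError("hot season must consist of 4 distinct months")

    def contains(self, dates: pd.DatetimeIndex | pd.Series) -> np.ndarray:
        """Boolean mask of dates falling inside the hot season."""
        months = dates.month if isinstance(dates, pd.DatetimeIndex) else dates.dt.month
        return np.isin(np.asarray(months), self.months)

    @property
    def wraps_year(self) -> bool:
        """True when the season straddles New Year (e.g. Nov-Feb)."""
        return self.months[0] > self.months[3]


def empirical_percentile(values, p: float) -> float:
    """Order statistic at rank h = (n-1)p + 1 with linear interpolation.

    This is the interpolation rule anchored to ranks 1..n (numpy's
    ``linear`` method).  Missing values are dropped first.

    >>> empirical_percentile(range(1, 101), 0.95)
    95.05
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"percentile fraction must lie in (0, 1), got {p}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot compute a percentile of an empty sample")
    return float(np.quantile(arr, p, method="linear"))


def compute_threshold(
    temperature: pd.Series,
    community: str = "",
    percentile: float = 0.95,
    period: tuple | None = None,
    assumption: str = NO_ADAPTATION,
) -> HeatwaveThreshold:
    """Threshold at the given percentile of year-round daily temperatures.

    ``period`` optionally restricts the sample to a (start, end) date
    interval (inclusive); default uses the full series.
    """
    t = temperature
    if period is not None:
        t = t.loc[pd.Timestamp(period[0]): pd.Timestamp(period[1])]
        if t.empty:
            raise ValueError("temperature series has no overlap with the requested period")
    frac_missing = float(t.isna().mean())
    if frac_missing > 0.10:
        logger.warning(
            "community %s: %.1f%% of temperatures missing in threshold period",
            community, 100 * frac_missing,
        )
    value = empirical_percentile(t.to_numpy(), percentile)
    span = (t.index[0], t.index[-1])
    return HeatwaveThreshold(
        community=community, value=value, percentile=percentile,
        source_period=span, assumption=assumption,
    )


def detect_heatwaves(
    temperature: pd.Series,
    threshold: HeatwaveThreshold | float,
    min_duration: int = 2,
) -> HeatwaveCalendar:
    """Flag heatwave days: maximal runs of strict exceedance >= min_duration.

    The input must be a daily series with no missing *dates*; missing
    temperatures are allowed and break runs (a day with unknown
    temperature never belongs to a heatwave).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    if isinstance(threshold, HeatwaveThreshold):
        community, thr = threshold.community, threshold.value
    else:
        community, thr = "", float(threshold)
    idx = temperature.index
    if len(idx) > 1:
        deltas = np.diff(idx.to_numpy().astype("datetime64[D]").astype(int))
        if (deltas != 1).any():
            raise ValueError("temperature series has missing or duplicated dates")

    temps = temperature.to_numpy(dtype=float)
    exceed = np.zeros(temps.shape, dtype=bool)
    finite = np.isfinite(temps)
    exceed[finite] = temps[finite] > thr

    indicator = np.zeros(temps.shape, dtype=np.int64)
    runs: list[tuple[pd.Timestamp, int]] = []
    # run-length encode the exceedance mask
    if exceed.any():
        padded = np.concatenate(([False], exceed, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = changes[::2], changes[1::2]
        for s, e in zip(starts, ends):
            if e - s >= min_duration:
                indicator[s:e] = 1
                runs.append((idx[s], int(e - s)))

    ind_series = pd.Series(indicator, index=idx, name="heatwave")
    years = idx.year.to_numpy()
    annual_hwn = {
        int(y): int(c)
        for y, c in zip(*np.unique(years[indicator == 1], return_counts=True))
    }
    annual_event_count: dict[int, int] = {}
    for start, _length in runs:
        annual_event_count[start.year] = annual_event_count.get(start.year, 0) + 1
    return HeatwaveCalendar(
        community=community, indicator=ind_series, runs=runs,
        annual_hwn=annual_hwn, annual_event_count=annual_event_count,
    )


def determine_hot_season(temperature: pd.Series, community: str = "") -> HotSeason:
    """Pick the 4 consecutive calendar months (cyclic) with the hottest climatology.

    Monthly climatological means are grand means over all days in each
    calendar month across years.  Ties break toward the earliest
    starting month.  Requires all 12 months to be represented.
    """
    months_present = temperature.index.month.unique()
    if len(months_present) < 12:
        raise ValueError(
            f"need data from all 12 calendar months, got {len(months_present)}"
        )
    clim = temperature.groupby(temperature.index.month).mean()
    clim = clim.reindex(range(1, 13))
    if clim.isna().any():
        raise ValueError("at least one calendar month has no temperature data")
    means = clim.to_numpy()
    best_start, best_mean = 0, -np.inf
    for start in range(12):
        window = [(start + k) % 12 for k in range(4)]
        m = means[window].mean()
        if m > best_mean + 1e-12:
            best_start, best_mean = start, m
    months = tuple((best_start + k) % 12 + 1 for k in range(4))
    return HotSeason(community=community, months=months)  # type: ignore[arg-type]


def future_threshold(
    modelled: pd.Series,
    assumption: str,
    current: HeatwaveThreshold,
    future_period: tuple = ("2031-01-01", "2080-12-31"),
) -> HeatwaveThreshold:
    """Threshold to apply in the future period under an adaptation assumption.

    ``no_adaptation`` keeps the current absolute threshold.
    ``hypothetical_adaptation`` recomputes the same percentile on the
    modelled temperatures within the future period, so the flagged-day
    rate tracks the (warmer) future distribution.
    """
    if assumption == NO_ADAPTATION:
        return current
    if assumption != HYPOTHETICAL_ADAPTATION:
        raise ValueError(f"unknown adaptation assumption: {assumption!r}")
    window = modelled.loc[pd.Timestamp(future_period[0]): pd.Timestamp(future_period[1])]
    if window.empty:
        raise ValueError("modelled series has no overlap with the future period")
    value = empirical_percentile(window.to_numpy(), current.percentile)
    return HeatwaveThreshold(
        community=current.community,
        value=value,
        percentile=current.percentile,
        source_period=(window.index[0], window.index[-1]),
        assumption=HYPOTHETICAL_ADAPTATION,
    )
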