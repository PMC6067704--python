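"""Bias correction of modelled daily temperature against observations.

Modelled (pseudo-GCM) series are recalibrated so that, over a
calibration period, their monthly means and the daily variability
around those means match the observed series.  The correction is a
per-calendar-month affine map applied to anomalies about the model's
*running* year-month mean, so the warming trend carried by the model's
own monthly means is preserved:

    corrected_t = M_t + C_m + s_m * (modelled_t - M_t)

where M_t is the model mean within day t's specific year-month, C_m the
monthly mean bias (observed minus modelled over the calibration
period), and s_m the ratio of observed to modelled anomaly standard
deviations for calendar month m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SCALE_FLOOR = 0.1
_SCALE_CAP = 10.0


@dataclass
class CalibrationParams:
    """Per-calendar-month offset (deg C) and anomaly scale factors."""

    offset: dict[int, float]
    scale: dict[int, float]
    calibration_period: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self) -> None:
        if sorted(self.offset) != list(range(1, 13)) or sorted(self.scale) != list(
            range(1, 13)
        ):
            raise ValueError("calibration needs all 12 calendar months")
        if any(s <= 0 for s in self.scale.values()):
            raise ValueError("anomaly scale factors must be positive")


def _monthly_stats(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Calendar-month means and anomaly SDs about year-month means."""
    ym = series.index.to_period("M")
    anomalies = series - series.groupby(ym).transform("mean")
    month = series.index.month
    return series.groupby(month).mean(), anomalies.groupby(month).std(ddof=0)


def estimate_calibration(
    observed: pd.Series,
    modelled: pd.Series,
    period: tuple | None = None,
) -> CalibrationParams:
    """Estimate monthly offsets and anomaly scales over a calibration period.

    Defaults to the full overlap of the two series.  Scales are floored
    at 0.1 and capped at 10 (a warning is logged when that triggers).
    """
    if period is None:
        start = max(observed.index[0], modelled.index[0])
        end = min(observed.index[-1], modelled.index[-1])
    else:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    obs = observed.loc[start:end].dropna()
    mod = modelled.loc[start:end].dropna()
    if obs.empty or mod.empty:
        raise ValueError("calibration period not covered by both series")
    obs_mean, obs_sd = _monthly_stats(obs)
    mod_mean, mod_sd = _monthly_stats(mod)
    months = set(obs_mean.index) & set(mod_mean.index)
    if months != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - months)
        raise ValueError(f"calibration period is missing calendar months {missing}")

    offset, scale = {}, {}
    for m in range(1, 13):
        offset[m] = float(obs_mean[m] - mod_mean[m])
        s = float(obs_sd[m] / mod_sd[m]) if mod_sd[m] > 0 else 1.0
        if not (_SCALE_FLOOR <= s <= _SCALE_CAP):
            logger.warning(
                "month %d anomaly scale %.3g outside [%g, %g]; clipped",
                m, s, _SCALE_FLOOR, _SCALE_CAP,
            )
            s = float(np.clip(s, _SCALE_FLOOR, _SCALE_CAP))
        scale[m] = s
    return CalibrationParams(
        offset=offset, scale=scale, calibration_period=(start, end)
    )


def apply_calibration(modelled: pd.Series, params: CalibrationParams) -> pd.Series:
    """Apply the monthly affine correction about running year-month means.

    Within each specific year-month the corrected mean exceeds the
    modelled mean by exactly C_m, so long-term trends in the model's
    monthly means pass through unchanged.
    """
    ym = modelled.index.to_period("M")
    running_mean = modelled.groupby(ym).transform("mean")
    month = modelled.index.month
    offsets = np.array([params.offset[m] for m in range(1, 13)])[month - 1]
    scales = np.array([params.scale[m] for m in range(1, 13)])[month - 1]
    corrected = running_mean + offsets + scales * (modelled - running_mean)
    corrected.name = modelled.name
    return corrected


def recalibrate(
    observed: pd.Series,
    modelled: pd.Series,
    period: tuple | None = None,
) -> tuple[pd.Series, CalibrationParams]:
    """Estimate and apply the correction in one step."""
    params = estimate_calibration(observed, modelled, period)
    return apply_calibration(modelled, params), params
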