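"""Stage 1: community-specific heatwave-mortality regression.

For each community, a quasi-Poisson time-series regression is fitted to
hot-season daily death counts.  The binary heatwave indicator enters
through a distributed-lag basis over lags 0-10 days (a constant column
plus a 3-df natural cubic spline of lag, 4 columns in total), so the
coefficient contrast summing the basis over all lags yields the
cumulative lag 0-10 log relative risk theta with variance v.  Nuisance
control: a 4-df natural cubic spline of day-of-season, a long-term
trend spline with 1 df per 10 years, and day-of-week indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .heatwave_calendar import HotSeason

logger = logging.getLogger(__name__)


class NoExposureVariationError(ValueError):
    """Raised when a community has no heatwave days to identify the effect."""


class NaturalCubicSpline:
    """Natural cubic spline basis with fixed knots, re-evaluable on new data.

    Columns: x itself plus one curvature term per internal knot, built
    from truncated cubics constrained to be linear beyond the boundary
    knots (second derivative zero at and outside the boundaries).  With
    K knots in total the basis has K - 1 columns; a df-column basis
    therefore uses df - 1 internal knots equally spaced strictly
    between the boundaries.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.size < 2 or np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing, length >= 2")
        self.knots = knots

    @classmethod
    def from_df(cls, df: int, boundary: tuple[float, float]) -> "NaturalCubicSpline":
        lo, hi = float(boundary[0]), float(boundary[1])
        if df < 1:
            raise ValueError("df must be >= 1")
        if not lo < hi:
            raise ValueError("boundary min must be < max")
        internal = np.linspace(lo, hi, df + 1)[1:-1]  # df - 1 interior knots
        return cls(np.concatenate(([lo], internal, [hi])))

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.knots
        K = len(k)
        cols = [x]

        def d(j: int) -> np.ndarray:
            num = np.clip(x - k[j], 0, None) ** 3 - np.clip(x - k[-1], 0, None) ** 3
            return num / (k[-1] - k[j])

        if K > 2:
            dKm1 = d(K - 2)
            for j in range(K - 2):
                cols.append(d(j) - dKm1)
        return np.column_stack(cols)


def natural_cubic_spline_basis(
    x,
    df: int,
    boundary: tuple[float, float] | None = None,
    include_constant: bool = False,
) -> np.ndarray:
    """Evaluate a df-column natural cubic spline basis at x.

    Internal knots are equally spaced strictly between the boundary
    knots (data min/max when ``boundary`` is omitted).  With
    ``include_constant`` a leading column of ones is prepended.
    """
    x = np.asarray(x, dtype=float)
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    if df >= len(np.unique(x)):
        raise ValueError(
            f"df={df} too large for {len(np.unique(x))} distinct x values"
        )
    basis = NaturalCubicSpline.from_df(df, boundary).transform(x)
    if include_constant:
        basis = np.column_stack([np.ones(len(x)), basis])
    return basis


@dataclass
class LagBasis:
    """Distributed-lag basis over lags 0..max_lag for a binary exposure.

    Default: one constant column plus a 3-df natural cubic spline of
    lag with boundary knots {0, max_lag}, giving 4 columns in total.
    ``cumulative_contrast`` sums the basis over lags; applied to the
    lag-block coefficients it yields the cumulative log relative risk.
    """

    max_lag: int = 10
    basis_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.basis_matrix is None:
            lags = np.arange(self.max_lag + 1, dtype=float)
            spline = NaturalCubicSpline.from_df(3, (0.0, float(self.max_lag)))
            self.basis_matrix = np.column_stack(
                [np.ones(self.max_lag + 1), spline.transform(lags)]
            )
        self.basis_matrix = np.asarray(self.basis_matrix, dtype=float)
        if self.basis_matrix.shape[0] != self.max_lag + 1:
            raise ValueError("basis must have max_lag + 1 rows")
        if np.linalg.matrix_rank(self.basis_matrix) < self.basis_matrix.shape[1]:
            raise ValueError("lag basis columns are linearly dependent")

    @property
    def n_columns(self) -> int:
        return self.basis_matrix.shape[1]

    @property
    def cumulative_contrast(self) -> np.ndarray:
        return self.basis_matrix.sum(axis=0)


def build_crossbasis(indicator, lag_basis: LagBasis) -> np.ndarray:
    """Convolve the 0/1 exposure with the lag basis.

    Column j at day t is sum_l indicator(t - l) * basis[l, j]; history
    before the start of the series is taken as unexposed.
    """
    ind = np.asarray(
        indicator.to_numpy() if isinstance(indicator, pd.Series) else indicator,
        dtype=float,
    )
    n = len(ind)
    out = np.empty((n, lag_basis.n_columns))
    for j in range(lag_basis.n_columns):
        out[:, j] = np.convolve(ind, lag_basis.basis_matrix[:, j])[:n]
    return out


@dataclass
class FirstStageFit:
    """Stage-1 result for one community."""

    community: str
    beta: np.ndarray
    covariance: np.ndarray
    dispersion: float
    theta: float
    v: float
    residual_deviance: float
    n_days: int
    colnames: list[str]

    @property
    def rr(self) -> float:
        return float(np.exp(self.theta))

    def rr_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = np.sqrt(self.v)
        return float(np.exp(self.theta - z * se)), float(np.exp(self.theta + z * se))


def season_year(dates: pd.DatetimeIndex, hot_season: HotSeason) -> np.ndarray:
    """Label each date with the year its hot season belongs to.

    For a season wrapping New Year (e.g. Nov-Feb), months before the
    wrap keep their calendar year and months after it are assigned to
    the previous year, so one season forms one contiguous block.
    """
    years = dates.year.to_numpy().copy()
    if hot_season.wraps_year:
        head_months = [m for m in hot_season.months if m >= hot_season.months[0]]
        after_wrap = ~np.isin(dates.month.to_numpy(), head_months)
        years = np.where(after_wrap, years - 1, years)
    return years


def _hot_season_frame(
    records: pd.DataFrame, hot_season: HotSeason, lag_basis: LagBasis
) -> tuple[pd.DataFrame, np.ndarray]:
    """Subset records to hot-season days, with lag history from the full year."""
    cross_full = build_crossbasis(records["heatwave"], lag_basis)
    mask = hot_season.contains(records.index)
    sub = records.loc[mask].copy()
    sub["season_year"] = season_year(records.index, hot_season)[mask]
    sub["day_of_season"] = sub.groupby("season_year").cumcount() + 1
    return sub, cross_full[mask]


def _design_matrix(
    sub: pd.DataFrame,
    cross: np.ndarray,
    season_spline: NaturalCubicSpline,
    trend_spline: NaturalCubicSpline,
    trend_origin: pd.Timestamp,
) -> tuple[np.ndarray, list[str]]:
    n = len(sub)
    parts = [np.ones((n, 1)), cross]
    names = ["intercept"] + [f"lag{j}" for j in range(cross.shape[1])]

    seas = season_spline.transform(sub["day_of_season"].to_numpy())
    parts.append(seas)
    names += [f"season{j}" for j in range(seas.shape[1])]

    tyears = (sub.index - trend_origin).days.to_numpy() / 365.25
    trend = trend_spline.transform(tyears)
    parts.append(trend)
    names += [f"trend{j}" for j in range(trend.shape[1])]

    dow = sub.index.dayofweek.to_numpy()
    for d in range(1, 7):  # Monday is the reference level
        parts.append((dow == d).astype(float)[:, None])
        names.append(f"dow{d}")
    return np.column_stack(parts), names


def trend_df_for_years(n_years: float) -> int:
    """1 df per 10 years of data, floored at 1 (half-up rounding)."""
    return max(1, int(np.floor(n_years / 10.0 + 0.5)))


def fit_first_stage(
    records: pd.DataFrame,
    hot_season: HotSeason,
    lag_basis: LagBasis | None = None,
    community: str = "",
    season_df: int = 4,
    maxiter: int = 50,
) -> FirstStageFit:
    """Quasi-Poisson hot-season regression; returns cumulative log RR.

    ``records`` is a daily DataFrame indexed by date with columns
    ``temperature``, ``deaths`` and a 0/1 ``heatwave`` indicator over
    the whole year (lag history entering the hot season is taken from
    the year-round indicator).  The model is fitted by iteratively
    reweighted least squares with a Pearson dispersion estimate; the
    covariance of the coefficients is the IRLS covariance inflated by
    the dispersion.
    """
    lag_basis = lag_basis or LagBasis()
    for col in ("deaths", "heatwave"):
        if col not in records.columns:
            raise ValueError(f"records must contain a {col!r} column")
    sub, cross = _hot_season_frame(records, hot_season, lag_basis)
    if not np.any(cross):
        raise NoExposureVariationError(
            f"community {community or '?'}: no heatwave days, no exposure variation"
        )
    n_years = sub["season_year"].nunique()
    if n_years < 2:
        raise ValueError("need at least 2 hot seasons of data")

    season_spline = NaturalCubicSpline.from_df(
        season_df, (1.0, float(sub["day_of_season"].max()))
    )
    total_years = (records.index[-1] - records.index[0]).days / 365.25
    tdf = trend_df_for_years(total_years)
    trend_origin = records.index[0]
    tmax = (records.index[-1] - trend_origin).days / 365.25
    trend_spline = NaturalCubicSpline.from_df(tdf, (0.0, float(tmax)))

    X, names = _design_matrix(sub, cross, season_spline, trend_spline, trend_origin)
    y = sub["deaths"].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=maxiter, tol=1e-9)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(community {community or '?'}, deviance {res.deviance:.3f})"
        )

    k = lag_basis.n_columns
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    c = lag_basis.cumulative_contrast
    lag_slice = slice(1, 1 + k)
    theta = float(c @ beta[lag_slice])
    v = float(c @ cov[lag_slice, lag_slice] @ c)
    logger.info(
        "community %s: RR=%.4f, dispersion=%.3f, %d hot-season days",
        community or "?", np.exp(theta), res.scale, len(sub),
    )
    return FirstStageFit(
        community=community,
        beta=beta,
        covariance=cov,
        dispersion=float(res.scale),
        theta=theta,
        v=v,
        residual_deviance=float(res.deviance),
        n_days=len(sub),
        colnames=names,
    )


def cross_validate_last_year(
    records: pd.DataFrame,
    hot_season: HotSeason,
    lag_basis: LagBasis | None = None,
    community: str = "",
    season_df: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out the final hot season, refit, predict its heatwave days.

    Returns (predicted, observed) death counts on the held-out year's
    heatwave days; empty arrays when that year has none.
    """
    lag_basis = lag_basis or LagBasis()
    sub_all, cross_all = _hot_season_frame(records, hot_season, lag_basis)
    syears = np.sort(sub_all["season_year"].unique())
    if len(syears) < 3:
        raise ValueError("need at least 3 hot seasons for last-year cross-validation")
    last = syears[-1]
    train = sub_all["season_year"] < last
    test = (sub_all["season_year"] == last) & (sub_all["heatwave"] == 1)
    if not test.any():
        logger.info("community %s: held-out year has no heatwave days", community or "?")
        return np.array([]), np.array([])
    if not np.any(cross_all[train.to_numpy()]):
        raise NoExposureVariationError(
            f"community {community or '?'}: training years have no heatwave days"
        )

    season_spline = NaturalCubicSpline.from_df(
        season_df, (1.0, float(sub_all["day_of_season"].max()))
    )
    total_years = (records.index[-1] - records.index[0]).days / 365.25
    trend_spline = NaturalCubicSpline.from_df(
        trend_df_for_years(total_years),
        (0.0, float((records.index[-1] - records.index[0]).days / 365.25)),
    )
    trend_origin = records.index[0]

    Xtr, _ = _design_matrix(
        sub_all[train], cross_all[train.to_numpy()], season_spline, trend_spline, trend_origin
    )
    Xte, _ = _design_matrix(
        sub_all[test], cross_all[test.to_numpy()], season_spline, trend_spline, trend_origin
    )
    ytr = sub_all.loc[train, "deaths"].to_numpy(dtype=float)
    res = sm.GLM(ytr, Xtr, family=sm.families.Poisson()).fit(scale="X2", tol=1e-9)
    predicted = np.exp(Xte @ np.asarray(res.params))
    observed = sub_all.loc[test, "deaths"].to_numpy(dtype=float)
    return predicted, observed


def pooled_r2(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Squared Pearson correlation of pooled (predicted, observed) pairs."""
    pred = np.concatenate([p for p, _ in pairs])
    obs = np.concatenate([o for _, o in pairs])
    if len(pred) < 3 or np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def first_stage_table(fits: list[FirstStageFit]) -> pd.DataFrame:
    """Summary table of stage-1 fits (one row per community)."""
    rows = []
    for f in fits:
        lo, hi = f.rr_ci()
        rows.append(
            {
                "community": f.community,
                "theta": f.theta,
                "v": f.v,
                "rr": f.rr,
                "ci_low": lo,
                "ci_high": hi,
                "dispersion": f.dispersion,
                "residual_deviance": f.residual_deviance,
                "n_days": f.n_days,
            }
        )
    return pd.DataFrame(rows)
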