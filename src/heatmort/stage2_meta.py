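"""Stage 2: random-effects meta-regression pooling community estimates.

Community cumulative log relative risks theta_i (with within-community
variances v_i) are modelled as theta_i = X_i gamma + u_i + e_i with
random effects u_i ~ N(0, tau2) and sampling errors e_i ~ N(0, v_i).
Meta-predictors: country indicators, climate-zone indicators, and the
community's hot-season mean and range of temperature.  tau2 is
estimated by REML (profile restricted likelihood, bounded scalar
optimisation) or by the DerSimonian-Laird moment estimator; community
best linear unbiased predictions (BLUPs) shrink each theta_i toward its
meta-regression prediction in proportion to the noise it carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

REML = "reml"
MOM = "mom"


@dataclass
class MetaDesign:
    """Design matrix for the meta-regression, one row per community."""

    matrix: np.ndarray
    colnames: list[str]
    communities: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError(
                "meta-regression design is rank deficient; "
                f"columns: {self.colnames}"
            )


def build_meta_design(
    metadata: pd.DataFrame,
    use_country: bool = True,
    use_climate_zone: bool = True,
    use_temperature: bool = True,
) -> MetaDesign:
    """Assemble meta-predictors from the community metadata table.

    Categorical predictors use first-level reference coding.  A country
    (or zone) with a single community would be confounded with that
    community's residual; such columns are dropped with a warning.
    """
    cols = [np.ones(len(metadata))]
    names = ["intercept"]

    def add_indicators(series: pd.Series, prefix: str) -> None:
        counts = series.value_counts()
        levels = sorted(series.unique())
        for level in levels[1:]:  # first level is the reference
            if counts[level] < 2 or counts[levels[0]] < 1:
                logger.warning(
                    "dropping %s indicator %r (single community)", prefix, level
                )
                continue
            cols.append((series == level).to_numpy(dtype=float))
            names.append(f"{prefix}[{level}]")

    if use_country and metadata["country"].nunique() > 1:
        add_indicators(metadata["country"], "country")
    if use_climate_zone and metadata["climate_zone"].nunique() > 1:
        add_indicators(metadata["climate_zone"], "zone")
    if use_temperature:
        cols.append(metadata["hot_season_mean"].to_numpy(dtype=float))
        names.append("hot_season_mean")
        cols.append(metadata["hot_season_range"].to_numpy(dtype=float))
        names.append("hot_season_range")

    # prune columns that are collinear with earlier ones (or that would
    # leave fewer than 2 residual degrees of freedom), keeping file order
    n = len(metadata)
    kept_cols, kept_names = [cols[0]], [names[0]]
    for c, name in zip(cols[1:], names[1:]):
        if len(kept_cols) >= n - 2:
            logger.warning("dropping meta-predictor %r: too few communities", name)
            continue
        candidate = np.column_stack(kept_cols + [c])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            logger.warning("dropping collinear meta-predictor %r", name)
            continue
        kept_cols.append(c)
        kept_names.append(name)
    return MetaDesign(
        matrix=np.column_stack(kept_cols),
        colnames=kept_names,
        communities=list(metadata.index),
    )


def intercept_only_design(communities: list[str]) -> MetaDesign:
    return MetaDesign(
        matrix=np.ones((len(communities), 1)),
        colnames=["intercept"],
        communities=list(communities),
    )


@dataclass
class MetaFit:
    """Fitted meta-regression: fixed effects, heterogeneity, BLUPs."""

    gamma: np.ndarray
    V_gamma: np.ndarray
    tau2: float
    method: str
    design: MetaDesign
    blup_mean: np.ndarray | None = None
    blup_var: np.ndarray | None = None

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.design.matrix if X is None else X
        return X @ self.gamma


def _wls(theta: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (gamma, (X'WX)^-1)."""
    XtW = X.T * w
    XtWX_inv = np.linalg.inv(XtW @ X)
    gamma = XtWX_inv @ (XtW @ theta)
    return gamma, XtWX_inv


def restricted_loglik(
    tau2: float, theta: np.ndarray, v: np.ndarray, X: np.ndarray
) -> float:
    """Profile restricted log-likelihood of tau2 (gamma profiled out)."""
    w = 1.0 / (v + tau2)
    gamma, XtWX_inv = _wls(theta, X, w)
    resid = theta - X @ gamma
    sign, logdet = np.linalg.slogdet(np.linalg.inv(XtWX_inv))
    return -0.5 * (
        np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2)
    )


def _tau2_mom(theta: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian-Laird style moment estimator, generalised to regression."""
    w = 1.0 / v
    gamma, XtWX_inv = _wls(theta, X, w)
    resid = theta - X @ gamma
    Q = float(np.sum(w * resid**2))
    n, p = X.shape
    denom = float(np.sum(w) - np.trace(XtWX_inv @ (X.T * (w**2)) @ X))
    tau2 = (Q - (n - p)) / max(denom, 1e-12)
    if tau2 < 0:
        logger.info("moment estimate of tau2 negative (%.4g); truncated to 0", tau2)
        tau2 = 0.0
    return tau2


def fit_meta_regression(
    theta,
    v,
    design: MetaDesign,
    method: str = REML,
) -> MetaFit:
    """Fit the random-effects meta-regression.

    tau2 >= 0 by construction: REML maximises the profile restricted
    likelihood over a bracket, the moment estimator truncates at zero.
    gamma is then the weighted least-squares solution with weights
    1/(v_i + tau2), with covariance (X'WX)^-1.
    """
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    X = design.matrix
    if not (len(theta) == len(v) == X.shape[0]):
        raise ValueError("theta, v and design must have matching lengths")
    if np.any(v <= 0):
        raise ValueError("all within-community variances must be positive")

    if method == REML:
        upper = max(10.0 * float(np.var(theta)), 10.0 * float(np.max(v)), 1e-4)
        res = optimize.minimize_scalar(
            lambda t2: -restricted_loglik(t2, theta, v, X),
            bounds=(0.0, upper),
            method="bounded",
            options={"xatol": 1e-10},
        )
        tau2 = float(res.x)
        # the bounded optimiser can sit just inside 0; snap if 0 is no worse
        if restricted_loglik(0.0, theta, v, X) >= restricted_loglik(tau2, theta, v, X):
            tau2 = 0.0
    elif method == MOM:
        tau2 = _tau2_mom(theta, v, X)
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")

    w = 1.0 / (v + tau2)
    gamma, V_gamma = _wls(theta, X, w)
    fit = MetaFit(gamma=gamma, V_gamma=V_gamma, tau2=tau2, method=method, design=design)
    blup_mean, blup_var = compute_blups(fit, theta, v, design)
    fit.blup_mean, fit.blup_var = blup_mean, blup_var
    return fit


def compute_blups(
    fit: MetaFit, theta, v, design: MetaDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Best linear unbiased predictions of community log relative risks.

    With shrinkage lambda_i = tau2 / (tau2 + v_i):
        blup_mean_i = X_i gamma + lambda_i (theta_i - X_i gamma)
        blup_var_i  = lambda_i v_i + (1 - lambda_i)^2 X_i V_gamma X_i'
    so noisy communities are pulled toward the meta-prediction while
    precisely estimated ones keep their own estimate.
    """
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    X = design.matrix
    lam = fit.tau2 / (fit.tau2 + v)
    pred = X @ fit.gamma
    pred_var = np.einsum("ij,jk,ik->i", X, fit.V_gamma, X)
    blup_mean = pred + lam * (theta - pred)
    blup_var = lam * v + (1.0 - lam) ** 2 * pred_var
    return blup_mean, blup_var


def blup_table(fit: MetaFit, theta, v) -> pd.DataFrame:
    """Per-community BLUP summary, expressed as relative risks."""
    from scipy.stats import norm

    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    lam = fit.tau2 / (fit.tau2 + v)
    se = np.sqrt(fit.blup_var)
    z = norm.ppf(0.975)
    return pd.DataFrame(
        {
            "community": fit.design.communities,
            "blup_log_rr": fit.blup_mean,
            "blup_var": fit.blup_var,
            "rr": np.exp(fit.blup_mean),
            "ci_low": np.exp(fit.blup_mean - z * se),
            "ci_high": np.exp(fit.blup_mean + z * se),
            "shrinkage": lam,
        }
    )
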