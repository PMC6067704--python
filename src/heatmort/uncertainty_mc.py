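"""Monte-Carlo uncertainty propagation and variance decomposition.

Coefficient uncertainty is propagated by drawing (by default 1,000)
normal samples of each community's pooled log relative risk and
re-evaluating the projection metric for every draw and every GCM.  The
point estimate is the GCM-ensemble mean at the central coefficients;
empirical confidence intervals (eCIs) are the 2.5th and 97.5th
percentiles of the pooled draws-by-GCM distribution, so they carry both
statistical and climate-model uncertainty.  The relative weight of the
two sources is summarised by the ratio of the average within-GCM
standard deviation to the between-GCM standard deviation of draw means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .heatwave_calendar import empirical_percentile


@dataclass
class MonteCarloEnsemble:
    """Draws of a scenario metric across coefficient samples and GCMs."""

    draws: np.ndarray  # shape (n_draws, n_gcms)
    gcms: list[str]
    point_estimate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2:
            raise ValueError("draws must be a (n_draws, n_gcms) array")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_gcms(self) -> int:
        return self.draws.shape[1]

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.ravel()

    @property
    def eci(self) -> tuple[float, float]:
        pooled = self.pooled
        return (
            empirical_percentile(pooled, 0.025),
            empirical_percentile(pooled, 0.975),
        )


@dataclass
class VarianceDecomposition:
    """Within- vs between-GCM spread of the ensemble."""

    within_gcm_sd: float
    between_gcm_sd: float

    @property
    def ratio(self) -> float:
        if self.between_gcm_sd == 0.0:
            return float("inf") if self.within_gcm_sd > 0 else float("nan")
        return self.within_gcm_sd / self.between_gcm_sd


def draw_coefficients(
    blup_mean: float,
    blup_var: float,
    n_draws: int = 1000,
    seed: int | np.random.Generator | Sequence[int] = 0,
) -> np.ndarray:
    """Normal samples of the pooled log relative risk.

    The same seed always yields the same draw vector, so scenario cells
    evaluated with common random numbers differ only through the metric.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    if blup_var < 0:
        raise ValueError("variance must be nonnegative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return blup_mean + np.sqrt(blup_var) * rng.standard_normal(n_draws)


def build_ensemble(
    metric_fn: Callable[[float, str], float],
    blup_mean: float,
    blup_var: float,
    gcm_list: list[str],
    n_draws: int = 1000,
    seed: int | Sequence[int] = 0,
) -> MonteCarloEnsemble:
    """Evaluate a projection metric for every coefficient draw x GCM.

    ``metric_fn(log_rr, gcm)`` must be deterministic.  The point
    estimate averages the metric over GCMs at the central (undrawn)
    coefficient.
    """
    if not gcm_list:
        raise ValueError("gcm_list is empty")
    samples = draw_coefficients(blup_mean, blup_var, n_draws, seed)
    draws = np.empty((n_draws, len(gcm_list)))
    for j, gcm in enumerate(gcm_list):
        for i, log_rr in enumerate(samples):
            try:
                draws[i, j] = metric_fn(float(log_rr), gcm)
            except Exception as exc:  # identify the failing cell
                raise RuntimeError(
                    f"metric evaluation failed at draw {i}, gcm {gcm!r}: {exc}"
                ) from exc
    point = float(np.mean([metric_fn(blup_mean, g) for g in gcm_list]))
    return MonteCarloEnsemble(
        draws=draws,
        gcms=list(gcm_list),
        point_estimate=point,
        seed=seed if isinstance(seed, int) else None,
    )


def decompose_variance(ensemble: MonteCarloEnsemble) -> VarianceDecomposition:
    """Average within-GCM SD over draws vs SD of per-GCM draw means."""
    if ensemble.n_gcms < 2:
        raise ValueError("variance decomposition needs at least 2 GCMs")
    if ensemble.n_draws < 2:
        raise ValueError("variance decomposition needs at least 2 draws")
    within = float(np.mean(ensemble.draws.std(axis=0, ddof=1)))
    between = float(ensemble.draws.mean(axis=0).std(ddof=1))
    return VarianceDecomposition(within_gcm_sd=within, between_gcm_sd=between)
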