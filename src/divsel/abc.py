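"""ABC-rejection and kernel-weighted local-linear regression adjustment.

The reference table holds ``n_sim`` parameter draws with their summary
statistics.  Rejection keeps the ``floor(tolerance * n_sim)`` simulations
nearest the observed statistics in MAD-standardized Euclidean distance;
the regression stage fits a kernel-weighted least-squares regression of
each accepted parameter on the centered statistics and projects the draws
to the observed point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceTable",
    "ABCResult",
    "mad_scale",
    "euclidean_distances",
    "abc_rejection",
    "kernel_weights",
    "regression_adjust",
    "posterior_summary",
]

logger = logging.getLogger(__name__)

KERNELS = ("epanechnikov", "gaussian")


@dataclass
class ReferenceTable:
    """Simulated parameter draws, their summary statistics, and the target.

    ``params`` is (n_sim, n_param), ``stats`` is (n_sim, n_stat) and ``obs``
    is the length-``n_stat`` observed summary vector.
    """

    params: np.ndarray
    stats: np.ndarray
    obs: np.ndarray
    stat_names: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.stats = np.atleast_2d(np.asarray(self.stats, dtype=float))
        self.obs = np.asarray(self.obs, dtype=float).ravel()
        if self.params.shape[0] != self.stats.shape[0]:
            raise ValueError("params and stats must have the same number of rows")
        if self.stats.shape[1] != self.obs.size:
            raise ValueError("obs length must match the number of statistics")
        if not (np.isfinite(self.params).all() and np.isfinite(self.stats).all()
                and np.isfinite(self.obs).all()):
            raise ValueError("reference table must not contain missing values")
        if not self.stat_names:
            self.stat_names = tuple(f"S{j}" for j in range(self.stats.shape[1]))
        if not self.param_names:
            self.param_names = tuple(f"theta{j}" for j in range(self.params.shape[1]))

    @property
    def n_sim(self) -> int:
        return self.stats.shape[0]


@dataclass
class ABCResult:
    """Accepted draws with distances, weights and adjusted values."""

    accepted_idx: np.ndarray
    distances: np.ndarray
    raw_draws: np.ndarray
    scaled_stats: np.ndarray
    scaled_obs: np.ndarray
    scale: np.ndarray
    param_names: tuple[str, ...]
    weights: np.ndarray | None = None
    adjusted_draws: np.ndarray | None = None
    kernel: str | None = None

    @property
    def M(self) -> int:
        return self.accepted_idx.size

    @property
    def draws(self) -> np.ndarray:
        """Adjusted draws when available, else the raw accepted draws."""
        return self.raw_draws if self.adjusted_draws is None else self.adjusted_draws

    @property
    def posterior_median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)


def mad_scale(
    stats: np.ndarray, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardize statistics by their median absolute deviation.

    The per-dimension scale is ``median(|x - median(x)|)`` over the
    simulated table; zero-MAD dimensions get scale 1 and are flagged in the
    returned boolean mask.  Returns
    ``(scaled_stats, scaled_obs, scale, degenerate)``.
    """
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    obs = np.asarray(obs, dtype=float).ravel()
    if stats.shape[0] < 2:
        raise ValueError("need at least two simulations to estimate scale")
    med = np.median(stats, axis=0)
    scale = np.median(np.abs(stats - med), axis=0)
    degenerate = scale == 0.0
    if degenerate.any():
        logger.warning(
            "%d summary dimension(s) have zero MAD; using scale 1",
            int(degenerate.sum()),
        )
    scale = np.where(degenerate, 1.0, scale)
    return stats / scale, obs / scale, scale, degenerate


def euclidean_distances(scaled_stats: np.ndarray, scaled_obs: np.ndarray) -> np.ndarray:
    """Euclidean distance of every scaled row to the scaled observation."""
    diff = np.atleast_2d(scaled_stats) - np.asarray(scaled_obs).ravel()
    return np.sqrt((diff * diff).sum(axis=1))


def abc_rejection(table: ReferenceTable, tolerance: float) -> ABCResult:
    """Accept the ``floor(tolerance * n_sim)`` nearest simulations.

    Distance ties are broken by simulation index; accepted distances are
    returned sorted ascending.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance}")
    M = math.floor(tolerance * table.n_sim)
    if M < 2:
        raise ValueError(
            f"floor(tolerance * n_sim) = {M} < 2; increase tolerance or n_sim"
        )
    scaled, scaled_obs, scale, _ = mad_scale(table.stats, table.obs)
    d = euclidean_distances(scaled, scaled_obs)
    order = np.argsort(d, kind="stable")[:M]
    return ABCResult(
        accepted_idx=order,
        distances=d[order],
        raw_draws=table.params[order],
        scaled_stats=scaled[order],
        scaled_obs=scaled_obs,
        scale=scale,
        param_names=table.param_names,
    )


def kernel_weights(distances: np.ndarray, kernel: str = "epanechnikov") -> np.ndarray:
    """Kernel weights at bandwidth ``d_M`` (the largest accepted distance).

    Epanechnikov: ``0.75 * (1 - t^2)`` for ``t = d/d_M < 1``, else 0;
    Gaussian: ``exp(-t^2 / 2)``.  If ``d_M = 0`` (all accepted rows match
    the observation exactly) all weights are 1.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    d = np.asarray(distances, dtype=float)
    d_max = d[-1] if d.size else 0.0
    if d_max == 0.0:
        return np.ones_like(d)
    t = d / d_max
    if kernel == "epanechnikov":
        return np.clip(0.75 * (1.0 - t * t), 0.0, None)
    return np.exp(-0.5 * t * t)


def regression_adjust(
    result: ABCResult,
    kernel: str = "epanechnikov",
    adjust: np.ndarray | None = None,
) -> ABCResult:
    """Local-linear regression correction of the accepted draws.

    Each parameter is regressed (weighted least squares, with intercept) on
    the centered predictors ``scaled_stats - scaled_obs``; the adjusted
    draw is ``theta - beta^T (S_scaled - S_obs_scaled)``.  Rows with zero
    kernel weight are excluded from the fit but still adjusted.  Collinear
    predictors are handled by the minimum-norm least-squares solution.

    ``adjust`` optionally masks which parameter columns are adjusted
    (categorical parameters such as m and sex should be excluded);
    unadjusted columns keep their raw draws.
    """
    w = kernel_weights(result.distances, kernel=kernel)
    Z = result.scaled_stats - result.scaled_obs
    theta = result.raw_draws
    M, n_param = theta.shape
    if adjust is None:
        adjust = np.ones(n_param, dtype=bool)
    adjust = np.asarray(adjust, dtype=bool)

    active = w > 0
    n_active = int(active.sum())
    adjusted = theta.copy()
    if Z.shape[1] > 0 and n_active >= 2:
        sw = np.sqrt(w[active])
        design = np.column_stack([np.ones(n_active), Z[active]])
        beta, _, rank, _ = np.linalg.lstsq(
            design * sw[:, None], theta[active] * sw[:, None], rcond=None
        )
        if rank < design.shape[1]:
            # common with discrete statistics (duplicate accepted rows);
            # the minimum-norm solution gives the same fitted values as
            # dropping the collinear columns
            logger.debug(
                "rank-deficient predictor matrix (rank %d < %d); "
                "minimum-norm WLS solution used",
                rank,
                design.shape[1],
            )
        correction = Z @ beta[1:]  # (M, n_param)
        adjusted[:, adjust] = theta[:, adjust] - correction[:, adjust]
    out = ABCResult(
        accepted_idx=result.accepted_idx,
        distances=result.distances,
        raw_draws=result.raw_draws,
        scaled_stats=result.scaled_stats,
        scaled_obs=result.scaled_obs,
        scale=result.scale,
        param_names=result.param_names,
        weights=w,
        adjusted_draws=adjusted,
        kernel=kernel,
    )
    return out


def posterior_summary(
    draws: np.ndarray, quantiles: tuple[float, float] = (0.025, 0.975)
) -> dict[str, np.ndarray]:
    """Median (the point estimator), central quantiles and SD per parameter."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError("need at least two draws")
    lo, hi = quantiles
    return {
        "median": np.median(draws, axis=0),
        "q_lo": np.quantile(draws, lo, axis=0),
        "q_hi": np.quantile(draws, hi, axis=0),
        "sd": draws.std(axis=0, ddof=1),
    }
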