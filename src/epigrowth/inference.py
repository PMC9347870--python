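"""Bayesian estimation of the instantaneous reproduction number.

EpiFilter-style grid inference: the unknown ``R_t`` lives on a fixed grid and
evolves as a Gaussian random walk whose daily standard deviation is
``eta * sqrt(R)``; each day's Poisson likelihood (mean ``Lambda_t * R``) is
combined with the propagated prior by exact discrete Bayes updates.  A
fixed-interval backward smoother then conditions every day on the whole
incidence curve, giving minimum-mean-squared-error estimates, equal-tailed
credible intervals, and one-step-ahead predictive distributions for
validation.

All likelihood arithmetic is done in the log domain with max-subtraction;
probabilities are floored at ``exp(-700)`` to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ImpossibleObservationError, InvalidInputError, InvalidParameterError
from .generation_time import GenerationTimeDistribution
from .simulate import total_infectiousness_series

__all__ = [
    "RtGrid",
    "EpiFilterConfig",
    "RtPosterior",
    "make_grid",
    "filter_forward",
    "smooth_backward",
    "estimate_rt",
    "write_posterior_csv",
]

_LOG_FLOOR = -700.0
_PROB_FLOOR = np.exp(_LOG_FLOOR)


@dataclass(frozen=True)
class RtGrid:
    """Uniform grid of candidate ``R`` values."""

    values: np.ndarray
    resolution: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size < 50:
            raise InvalidParameterError("grid needs at least 50 points")
        if values[0] <= 0:
            raise InvalidParameterError("grid values must be strictly positive")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise InvalidParameterError("grid values must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise InvalidParameterError("grid must be uniformly spaced")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "resolution", float(steps[0]))

    @property
    def size(self) -> int:
        return self.values.size


def make_grid(r_min: float = 0.01, r_max: float = 10.0, n: int = 2000) -> RtGrid:
    """Default estimation grid: 2000 points on [0.01, 10]."""
    if not 0 < r_min < r_max:
        raise InvalidParameterError("need 0 < r_min < r_max")
    return RtGrid(values=np.linspace(r_min, r_max, n))


@dataclass(frozen=True)
class EpiFilterConfig:
    """Estimator settings: grid range/size, state noise, interval level."""

    r_min: float = 0.01
    r_max: float = 10.0
    grid_size: int = 2000
    eta: float = 0.1
    ci_level: float = 0.95

    def grid(self) -> RtGrid:
        return make_grid(self.r_min, self.r_max, self.grid_size)


@dataclass(frozen=True)
class RtPosterior:
    """Per-day posteriors over the ``R`` grid with summaries.

    ``mean_rt`` and the credible bounds come from the smoothed posterior (the
    headline estimate); ``pred_*`` are one-step-ahead predictive summaries of
    the incidence itself, built from the filtered posterior only (so each
    day's prediction uses strictly past data).  Day 1 carries the prior and
    has no prediction (NaN).
    """

    grid: RtGrid
    filtered: np.ndarray
    smoothed: np.ndarray
    mean_rt: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pred_mean: np.ndarray
    pred_lower: np.ndarray
    pred_upper: np.ndarray
    eta: float

    @property
    def horizon(self) -> int:
        return self.mean_rt.size

    def filtered_mean(self) -> np.ndarray:
        return self.filtered @ self.grid.values

    def filtered_variance(self) -> np.ndarray:
        g = self.grid.values
        return self.filtered @ g**2 - self.filtered_mean() ** 2

    def smoothed_variance(self) -> np.ndarray:
        g = self.grid.values
        return self.smoothed @ g**2 - self.mean_rt**2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(1, self.horizon + 1),
                "mean_R": self.mean_rt,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "pred_mean": self.pred_mean,
                "pred_lower": self.pred_lower,
                "pred_upper": self.pred_upper,
            }
        )


# ---------------------------------------------------------------------------
# Forward filter / backward smoother core.  The batched versions propagate
# many epidemics at once through the shared transition kernel, which is how
# replicate studies (e.g. interval-calibration checks) stay fast on one CPU.
# ---------------------------------------------------------------------------


def _transition_kernel(grid: RtGrid, eta: float) -> np.ndarray:
    """Row-stochastic kernel K[j, i] = P(R_t = g_i | R_{t-1} = g_j).

    Gaussian random walk with standard deviation ``eta * sqrt(g_j)``,
    discretized onto the grid and row-renormalised.
    """
    g = grid.values
    sd = eta * np.sqrt(g)
    z = (g[None, :] - g[:, None]) / sd[:, None]
    logk = -0.5 * z**2
    logk -= logk.max(axis=1, keepdims=True)
    kernel = np.exp(np.maximum(logk, _LOG_FLOOR))
    kernel /= kernel.sum(axis=1, keepdims=True)
    return kernel


def _filter_batch(
    incidence: np.ndarray,
    lam: np.ndarray,
    grid: RtGrid,
    eta: float,
    kernel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the forward filter on ``n`` epidemics at once.

    Parameters are ``(n, T)`` arrays of counts and total infectiousness.
    Returns ``(filtered, predicted)`` of shape ``(n, T, G)``: the day-``t``
    posterior and the day-``t`` prior (the day-``t-1`` posterior pushed through
    the state kernel).  Day 1 holds the uniform prior in both.
    """
    incidence = np.atleast_2d(np.asarray(incidence, dtype=float))
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    n, T = incidence.shape
    if T < 3:
        raise InvalidInputError("need at least 3 days of incidence")
    if np.any((lam[:, 1:] == 0) & (incidence[:, 1:] > 0)):
        raise ImpossibleObservationError(
            "positive incidence on a day with zero total infectiousness"
        )
    g = grid.values
    G = g.size
    if kernel is None:
        kernel = _transition_kernel(grid, eta)
    filtered = np.empty((n, T, G))
    predicted = np.empty((n, T, G))
    filtered[:, 0, :] = 1.0 / G
    predicted[:, 0, :] = 1.0 / G
    log_g = np.log(g)
    for t in range(1, T):
        prior = filtered[:, t - 1, :] @ kernel
        predicted[:, t, :] = prior
        mu = lam[:, t, None] * g[None, :]  # (n, G)
        i_t = incidence[:, t, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = i_t * (np.log(lam[:, t, None]) + log_g[None, :]) - mu
        loglik[lam[:, t] == 0.0, :] = 0.0  # no infectious pressure: flat
        logpost = np.log(np.maximum(prior, _PROB_FLOOR)) + loglik
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(np.maximum(logpost, _LOG_FLOOR))
        filtered[:, t, :] = post / post.sum(axis=1, keepdims=True)
    return filtered, predicted


def _smooth_batch(
    filtered: np.ndarray,
    predicted: np.ndarray,
    grid: RtGrid,
    eta: float,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed-interval backward smoother for batched filtered distributions."""
    if kernel is None:
        kernel = _transition_kernel(grid, eta)
    n, T, G = filtered.shape
    smoothed = np.empty_like(filtered)
    smoothed[:, -1, :] = filtered[:, -1, :]
    for t in range(T - 2, -1, -1):
        ratio = smoothed[:, t + 1, :] / np.maximum(predicted[:, t + 1, :], _PROB_FLOOR)
        s = filtered[:, t, :] * (ratio @ kernel.T)
        smoothed[:, t, :] = s / s.sum(axis=1, keepdims=True)
    return smoothed


def filter_forward(
    incidence: np.ndarray,
    gt: GenerationTimeDistribution,
    grid: RtGrid,
    state_noise_eta: float = 0.1,
) -> np.ndarray:
    """Per-day filtered posteriors (``T x G``), starting from a uniform prior."""
    if not 0 < state_noise_eta <= 1:
        raise InvalidParameterError("state_noise_eta must lie in (0, 1]")
    incidence = np.asarray(incidence, dtype=float)
    lam = total_infectiousness_series(incidence, gt)
    filtered, _ = _filter_batch(incidence[None, :], lam[None, :], grid, state_noise_eta)
    return filtered[0]


def smooth_backward(
    filtered: np.ndarray,
    grid: RtGrid,
    state_noise_eta: float = 0.1,
) -> np.ndarray:
    """Smoothed posteriors from filtered ones (final day: smoothed = filtered)."""
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 2 or filtered.shape[1] != grid.size:
        raise InvalidInputError("filtered must be a (T, grid_size) array")
    if not np.allclose(filtered.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidInputError("filtered rows must be normalised")
    kernel = _transition_kernel(grid, state_noise_eta)
    predicted = np.empty_like(filtered)
    predicted[0] = filtered[0]
    predicted[1:] = filtered[:-1] @ kernel
    smoothed = _smooth_batch(
        filtered[None, ...], predicted[None, ...], grid, state_noise_eta, kernel
    )
    return smoothed[0]


def _grid_quantiles(pmf: np.ndarray, grid: RtGrid, levels: np.ndarray) -> np.ndarray:
    """Equal-tailed quantiles of per-day grid pmfs, rows = days.

    The mass at each grid point is treated as uniform over its cell, and the
    resulting piecewise-linear CDF inverted.  This keeps intervals meaningful
    even when the posterior concentrates within a single grid cell.
    """
    half = grid.resolution / 2.0
    edges_hi = grid.values + half
    cum = np.cumsum(pmf, axis=-1)
    out = np.empty(pmf.shape[:-1] + (levels.size,))
    for k, q in enumerate(levels):
        idx = np.minimum(
            (cum < q).sum(axis=-1), pmf.shape[-1] - 1
        )  # first cell with cum >= q
        take = np.take_along_axis
        cum_lo = np.where(idx > 0, take(cum, np.maximum(idx - 1, 0)[..., None], -1)[..., 0], 0.0)
        mass = take(pmf, idx[..., None], -1)[..., 0]
        frac = np.clip((q - cum_lo) / np.maximum(mass, _PROB_FLOOR), 0.0, 1.0)
        out[..., k] = edges_hi[idx] - grid.resolution + frac * grid.resolution
    return out


def _mixture_poisson_quantile(weights: np.ndarray, mu: np.ndarray, level: float) -> int:
    """Smallest integer k with mixture-Poisson CDF(k) >= level."""
    mean = weights @ mu
    var = weights @ (mu + mu**2) - mean**2
    hi = int(np.ceil(mean + 12.0 * np.sqrt(max(var, 0.0)) + 20.0))
    lo = 0
    if float(weights @ stats.poisson.cdf(lo, mu)) >= level:
        return 0
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if float(weights @ stats.poisson.cdf(mid, mu)) >= level:
            hi = mid
        else:
            lo = mid
    return hi


def estimate_rt(
    incidence: np.ndarray,
    gt: GenerationTimeDistribution,
    config: EpiFilterConfig | None = None,
) -> RtPosterior:
    """Full pipeline: filter, smooth, summarise, and predict one step ahead.

    The headline ``mean_rt`` and equal-tailed credible bounds come from the
    smoothed posterior; predictive means and 95% intervals for each day's
    count come from the filtered prior of that day (a Poisson mixture across
    the grid with means ``Lambda_t * R``).
    """
    config = config or EpiFilterConfig()
    grid = config.grid()
    g = grid.values
    incidence = np.asarray(incidence, dtype=float)
    lam = total_infectiousness_series(incidence, gt)
    kernel = _transition_kernel(grid, config.eta)
    filtered, predicted = _filter_batch(
        incidence[None, :], lam[None, :], grid, config.eta, kernel
    )
    smoothed = _smooth_batch(filtered, predicted, grid, config.eta, kernel)
    filtered, predicted, smoothed = filtered[0], predicted[0], smoothed[0]

    alpha = (1.0 - config.ci_level) / 2.0
    qs = _grid_quantiles(smoothed, grid, np.array([alpha, 1.0 - alpha]))
    mean_rt = smoothed @ g

    T = incidence.size
    pred_mean = np.full(T, np.nan)
    pred_lower = np.full(T, np.nan)
    pred_upper = np.full(T, np.nan)
    for t in range(1, T):
        w = predicted[t]
        if lam[t] == 0.0:
            pred_mean[t] = 0.0
            pred_lower[t] = 0.0
            pred_upper[t] = 0.0
            continue
        keep = w > 1e-12
        wk = w[keep] / w[keep].sum()
        mu = lam[t] * g[keep]
        pred_mean[t] = wk @ mu
        pred_lower[t] = _mixture_poisson_quantile(wk, mu, alpha)
        pred_upper[t] = _mixture_poisson_quantile(wk, mu, 1.0 - alpha)

    return RtPosterior(
        grid=grid,
        filtered=filtered,
        smoothed=smoothed,
        mean_rt=mean_rt,
        ci_lower=qs[:, 0],
        ci_upper=qs[:, 1],
        pred_mean=pred_mean,
        pred_lower=pred_lower,
        pred_upper=pred_upper,
        eta=config.eta,
    )


def write_posterior_csv(posterior: RtPosterior, path: str | Path) -> None:
    """Posterior summary as CSV (day, mean_R, CI bounds, prediction bounds)."""
    posterior.to_frame().to_csv(Path(path), index=False)
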