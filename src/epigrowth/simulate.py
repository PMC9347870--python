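"""Renewal-model epidemic simulator.

Generates synthetic incidence curves from the renewal model
``E[I_t] = Lambda_t * R_t`` with ``Lambda_t = sum_{j>=1} I_{t-j} w_j``,
under a configurable true reproduction-number profile.  The simulator is the
ground truth for every estimator in the package: the conditional mean of each
day's count is exactly the total infectiousness times the true ``R_t``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidProfileError, UndefinedConvolutionError
from .generation_time import GenerationTimeDistribution

__all__ = [
    "RtProfile",
    "EpidemicTrajectory",
    "seasonal_rt_profile",
    "constant_rt_profile",
    "total_infectiousness",
    "total_infectiousness_series",
    "simulate",
    "write_trajectory_csv",
    "read_incidence_csv",
    "DEFAULT_SEASONAL",
]

#: Default seasonal scenario: 300 days, R_t = 1 + 0.75 sin(2 pi t / 120),
#: 50 seed cases.  Two rising and two falling seasons, with incidence spanning
#: small and large counts.
DEFAULT_SEASONAL = {
    "horizon_T": 300,
    "baseline": 1.0,
    "amplitude": 0.75,
    "period": 120.0,
    "seed_cases": 50,
}


@dataclass(frozen=True)
class RtProfile:
    """True instantaneous reproduction numbers ``R_t``, ``t = 1..T``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise InvalidProfileError("profile needs at least 2 days")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise InvalidProfileError("R_t must be finite and strictly positive")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def horizon(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EpidemicTrajectory:
    """A simulated epidemic: counts, total infectiousness, and the truth.

    ``total_infectiousness[t-1]`` stores ``Lambda_t``; ``Lambda_1 = 0`` by
    convention (no past incidence exists before day 1 — early days are instead
    driven by constant seeding).  ``went_extinct`` flags a trajectory whose
    final generation-time window contains no cases, so no infectious pressure
    remains; extinction is an outcome, not an error.
    """

    incidence: np.ndarray
    total_infectiousness: np.ndarray
    true_rt_profile: RtProfile
    seed: int | None
    n_seed_days: int
    went_extinct: bool = False

    @property
    def horizon(self) -> int:
        return self.incidence.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(1, self.horizon + 1),
                "incidence": self.incidence,
                "true_R": self.true_rt_profile.values,
                "total_infectiousness": self.total_infectiousness,
            }
        )


def seasonal_rt_profile(
    horizon_T: int,
    baseline: float = DEFAULT_SEASONAL["baseline"],
    amplitude: float = DEFAULT_SEASONAL["amplitude"],
    period: float = DEFAULT_SEASONAL["period"],
) -> RtProfile:
    """Sinusoidal profile ``R_t = baseline + amplitude sin(2 pi t / period)``.

    Models seasonal transmission: the epidemic alternates between growing
    (``R_t > 1``) and declining seasons.  ``baseline - amplitude`` must be
    positive so the profile never reaches zero.
    """
    if horizon_T < 2:
        raise InvalidProfileError("horizon_T must be >= 2")
    if period <= 0:
        raise InvalidProfileError("period must be positive")
    if baseline - amplitude <= 0:
        raise InvalidProfileError(
            "baseline - amplitude must be > 0 so that R_t stays positive"
        )
    t = np.arange(1, horizon_T + 1, dtype=float)
    return RtProfile(values=baseline + amplitude * np.sin(2.0 * np.pi * t / period))


def constant_rt_profile(horizon_T: int, value: float) -> RtProfile:
    """Constant profile ``R_t = value`` (a zero-amplitude sinusoid)."""
    return seasonal_rt_profile(horizon_T, baseline=value, amplitude=0.0)


def total_infectiousness(
    incidence: np.ndarray, gt: GenerationTimeDistribution, t: int
) -> float:
    """Total infectiousness ``Lambda_t = sum_{j=1}^{min(t-1, L)} I_{t-j} w_j``.

    Valid for ``2 <= t <= T + 1``; ``t = T + 1`` gives the next-day value used
    for one-step-ahead prediction.
    """
    gt.require_daily()
    incidence = np.asarray(incidence, dtype=float)
    if t < 2:
        raise UndefinedConvolutionError(
            f"Lambda_t needs at least one past day, got t={t}"
        )
    if t > incidence.size + 1:
        raise UndefinedConvolutionError(
            f"t={t} exceeds horizon+1={incidence.size + 1}"
        )
    return _lambda_at(incidence, gt.probs, t)


def _lambda_at(incidence: np.ndarray, probs: np.ndarray, t: int) -> float:
    # shared by the simulator and the series builder so stored and recomputed
    # Lambda values agree bit-for-bit (same summation order)
    j_max = min(t - 1, probs.size)
    past = incidence[t - 1 - j_max : t - 1][::-1]  # I_{t-1}, I_{t-2}, ...
    return float(past @ probs[:j_max])


def total_infectiousness_series(
    incidence: np.ndarray, gt: GenerationTimeDistribution
) -> np.ndarray:
    """Vector of ``Lambda_t`` for ``t = 1..T`` (``Lambda_1 = 0`` by convention)."""
    gt.require_daily()
    incidence = np.asarray(incidence, dtype=float)
    T = incidence.size
    lam = np.zeros(T)
    for t in range(2, T + 1):
        lam[t - 1] = _lambda_at(incidence, gt.probs, t)
    return lam


def simulate(
    profile: RtProfile,
    gt: GenerationTimeDistribution,
    seed_cases: int = 50,
    rng_seed: int | None = None,
    *,
    deterministic: bool = False,
    dispersion: float | None = None,
    n_seed_days: int | None = None,
) -> EpidemicTrajectory:
    """Simulate an epidemic from the renewal model.

    The first ``n_seed_days`` days (default ``max(7, L // 2)``) are constant
    imports of ``seed_cases``, so the convolution is well defined early on.
    Afterwards each day's count is drawn Poisson with mean
    ``Lambda_t * R_t`` — or negative binomial with the given ``dispersion``
    (smaller = more overdispersed), or propagated as the exact mean when
    ``deterministic`` is set (useful for analytic checks).
    """
    gt.require_daily()
    if seed_cases < 1:
        raise InvalidParameterError("seed_cases must be >= 1")
    if dispersion is not None and dispersion <= 0:
        raise InvalidParameterError("dispersion must be positive")
    T = profile.horizon
    L = gt.support_days
    if n_seed_days is None:
        n_seed_days = max(7, L // 2)
    n_seed_days = min(n_seed_days, T)

    rng = np.random.default_rng(rng_seed)
    w = gt.probs
    incidence = np.zeros(T, dtype=float)
    lam = np.zeros(T, dtype=float)
    incidence[:n_seed_days] = float(seed_cases)
    for t in range(2, T + 1):  # 1-based day
        lam[t - 1] = _lambda_at(incidence, w, t)
        if t <= n_seed_days:
            continue
        mean = lam[t - 1] * profile.values[t - 1]
        if deterministic:
            incidence[t - 1] = mean
        elif mean == 0.0:
            incidence[t - 1] = 0.0
        elif dispersion is None:
            incidence[t - 1] = rng.poisson(mean)
        else:
            p = dispersion / (dispersion + mean)
            incidence[t - 1] = rng.negative_binomial(dispersion, p)

    if not deterministic:
        incidence = incidence.astype(np.int64)
    # extinct when no case fell within the final generation-time window, so
    # no infectious pressure remains
    tail = min(L, T - n_seed_days)
    went_extinct = bool(tail > 0 and np.all(incidence[T - tail :] == 0))
    return EpidemicTrajectory(
        incidence=incidence,
        total_infectiousness=lam,
        true_rt_profile=profile,
        seed=rng_seed,
        n_seed_days=n_seed_days,
        went_extinct=went_extinct,
    )


def write_trajectory_csv(
    trajectory: EpidemicTrajectory, path: str | Path, config: dict | None = None
) -> None:
    """Write a trajectory as CSV plus a side-car JSON with seed and config hash."""
    path = Path(path)
    trajectory.to_frame().to_csv(path, index=False)
    config = config or {}
    blob = json.dumps(config, sort_keys=True).encode()
    meta = {
        "seed": trajectory.seed,
        "n_seed_days": trajectory.n_seed_days,
        "went_extinct": trajectory.went_extinct,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_incidence_csv(path: str | Path) -> np.ndarray:
    """Read an incidence curve from a CSV with columns ``day, incidence``."""
    table = pd.read_csv(path)
    if not {"day", "incidence"} <= set(table.columns):
        raise InvalidParameterError(
            f"{path} must have columns 'day' and 'incidence'"
        )
    table = table.sort_values("day")
    return table["incidence"].to_numpy()
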