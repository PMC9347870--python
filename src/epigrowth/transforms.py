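"""Conversions between reproduction numbers and growth rates.

Under the renewal model with generation-time distribution ``w``, a constant
(or slowly varying) reproduction number ``R`` corresponds to exponential
growth at the rate ``r`` solving ``R * M_w(-r) = 1``, where ``M_w`` is the
moment generating function of ``w``.  For a gamma(``a``, ``b``) generation
time this has the closed form ``r = b (R^{1/a} - 1)`` with exact inverse
``R = (1 + r/b)^a``; a linearised SIR model gives the first-order version
``r = (R - 1) / E[w]``.  All three maps are strictly increasing and send
``R = 1`` to ``r = 0``, so epidemic-threshold crossings coincide exactly.

Credible intervals are propagated by mapping the posterior quantile bounds
through the (monotone) transform day by day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, InvalidParameterError, UnsupportedOperationError
from .generation_time import GenerationTimeDistribution, mgf
from .growth import GrowthRateSeries
from .inference import RtPosterior

__all__ = [
    "TransformSpec",
    "growth_from_R_gamma",
    "R_from_growth_gamma",
    "growth_from_R_numeric",
    "growth_from_R_sir",
    "growth_from_R",
    "transform_posterior",
    "critical_prevention_fraction",
]

_KINDS = ("gamma_closed_form", "numeric_mgf", "sir_linear")


@dataclass(frozen=True)
class TransformSpec:
    """Which R <-> r map to use, with its generation-time information."""

    kind: str
    gt: GenerationTimeDistribution

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}")
        if self.kind == "gamma_closed_form" and (
            self.gt.shape_a is None or self.gt.rate_b is None
        ):
            raise UnsupportedOperationError(
                "gamma_closed_form needs a gamma-parametrised generation time"
            )


def growth_from_R_gamma(R: float, shape_a: float, rate_b: float) -> float:
    """Closed-form growth rate ``r = b (R^{1/a} - 1)`` for a gamma generation time."""
    if R <= 0:
        raise InvalidParameterError("R must be positive")
    if shape_a <= 0 or rate_b <= 0:
        raise InvalidParameterError("gamma parameters must be positive")
    return rate_b * (R ** (1.0 / shape_a) - 1.0)


def R_from_growth_gamma(r: float, shape_a: float, rate_b: float) -> float:
    """Exact inverse ``R = (1 + r/b)^a``; requires ``r > -b`` (MGF domain)."""
    if shape_a <= 0 or rate_b <= 0:
        raise InvalidParameterError("gamma parameters must be positive")
    if r <= -rate_b:
        raise InvalidParameterError(f"r must exceed -rate_b = {-rate_b}")
    return (1.0 + r / rate_b) ** shape_a


def growth_from_R_numeric(R: float, gt: GenerationTimeDistribution) -> float:
    """Solve ``R * M_w(-r) = 1`` on the discretized distribution by root finding.

    ``M_w(-r)`` is strictly decreasing in ``r`` (support at positive days), so
    the root is unique.  Bracketed with geometric expansion then solved by
    Brent's method to 1e-12.  Strong decay rates below ``-min(5, b)`` per day
    are outside the numerically stable range of the discretized MGF.
    """
    if R <= 0:
        raise InvalidParameterError("R must be positive")
    r_floor = -min(5.0, gt.rate_b - 1e-9) if gt.rate_b is not None else -5.0

    def f(r: float) -> float:
        return R * mgf(gt, -r) - 1.0

    lo, hi = -0.25, 0.25
    for _ in range(60):
        if lo <= r_floor:
            lo = r_floor
        if np.sign(f(lo)) != np.sign(f(hi)):
            break
        if f(hi) > 0:
            hi *= 2.0
        else:
            lo *= 2.0
        if hi > 50.0:
            raise ConvergenceError(
                f"failed to bracket the growth rate for R={R} (hi={hi})"
            )
    else:
        raise ConvergenceError(f"failed to bracket the growth rate for R={R}")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def growth_from_R_sir(R: float, mean_gt: float) -> float:
    """Linearised-SIR transform ``r = (R - 1) / E[w]``."""
    if R <= 0:
        raise InvalidParameterError("R must be positive")
    if mean_gt <= 0:
        raise InvalidParameterError("mean generation time must be positive")
    return (R - 1.0) / mean_gt


def growth_from_R(R: float, spec: TransformSpec) -> float:
    """Dispatch a single R -> r conversion through the chosen transform."""
    if spec.kind == "gamma_closed_form":
        return growth_from_R_gamma(R, spec.gt.shape_a, spec.gt.rate_b)
    if spec.kind == "numeric_mgf":
        return growth_from_R_numeric(R, spec.gt)
    return growth_from_R_sir(R, spec.gt.mean_days)


def transform_posterior(posterior: RtPosterior, spec: TransformSpec) -> GrowthRateSeries:
    """Map an R posterior summary into growth rates with credible intervals.

    The posterior mean and equal-tailed quantile bounds are pushed through the
    strictly increasing transform day by day, so the bounds remain ordered
    and remain equal-tailed quantiles of the induced distribution.  Days where
    the transform is undefined come out as NaN.
    """

    def convert(values: np.ndarray) -> np.ndarray:
        out = np.full(values.shape, np.nan)
        for i, v in enumerate(values):
            if not np.isfinite(v):
                continue
            try:
                out[i] = growth_from_R(float(v), spec)
            except (InvalidParameterError, ConvergenceError):
                pass
        return out

    return GrowthRateSeries(
        values=convert(posterior.mean_rt),
        method="model_transform",
        ci_lower=convert(posterior.ci_lower),
        ci_upper=convert(posterior.ci_upper),
    )


def critical_prevention_fraction(R: float) -> float:
    """Smallest fraction ``f`` of transmissions to block so ``(1-f) R <= 1``.

    The herd-immunity / control threshold: 0 for ``R <= 1``, else ``1 - 1/R``
    (located by bracketed root finding on ``(1-f) R - 1``).
    """
    if R <= 0:
        raise InvalidParameterError("R must be positive")
    if R <= 1.0:
        return 0.0
    return float(brentq(lambda f: (1.0 - f) * R - 1.0, 0.0, 1.0, xtol=1e-15))
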