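"""Model-agnostic growth rates via Savitzky-Golay filtering.

The instantaneous growth rate is the derivative of log-smoothed incidence.
Savitzky-Golay (SG) filters unify the common smoothing choices: a window of
``m`` days is fitted with a least-squares polynomial, and the smoothed value
(derivative order 0) or local slope (order 1) at the window centre is a fixed
convolution of the data.  Setting the polynomial order to 0 or 1 with
derivative 0 recovers the plain moving average ``a_j = 1/m``.

Two estimators are provided: one smooths the raw incidence and differentiates
its log, the other differentiates the log of the total infectiousness — which
is itself a smoothing of incidence with the generation-time distribution as an
epidemiologically informed kernel, and therefore lags by roughly the mean
generation time ``E[w]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs
from scipy.stats import pearsonr

from .errors import InvalidFilterError, InvalidInputError
from .generation_time import GenerationTimeDistribution
from .simulate import total_infectiousness_series

__all__ = [
    "SGFilterSpec",
    "GrowthRateSeries",
    "sg_coefficients",
    "smooth_series",
    "growth_from_log_incidence",
    "growth_from_total_infectiousness",
    "align_lag",
    "DEFAULT_WINDOW",
    "DEFAULT_POLY_ORDER",
    "LOG_FLOOR_CASES",
]

#: Default SG window (days) and polynomial order: a 15-day quadratic window
#: spans roughly two mean generation times of the default serial interval.
DEFAULT_WINDOW = 15
DEFAULT_POLY_ORDER = 2

#: Incidence floor applied before taking logs, in cases.
LOG_FLOOR_CASES = 0.5


@dataclass(frozen=True)
class SGFilterSpec:
    """An SG convolution kernel: ``m`` weights ``a_j``, ``j = -(m-1)/2 .. (m-1)/2``.

    Derivative order 0 preserves constants (``sum a_j = 1``); order 1 is exact
    on linear ramps (``sum a_j = 0`` and ``sum j a_j = 1``).
    """

    window_m: int
    poly_order: int
    deriv_order: int
    weights_aj: np.ndarray

    @property
    def half_width(self) -> int:
        return (self.window_m - 1) // 2


@dataclass(frozen=True)
class GrowthRateSeries:
    """Per-day growth-rate estimates (1/day) with provenance.

    ``lag_shift_days`` records any alignment shift already applied to the
    values: negative means the series was advanced (moved toward earlier
    days), positive delayed.  Boundary days without estimates are NaN;
    ``undefined_edges`` counts them at the worst-affected end (before any
    shift).  Credible bounds exist only for transform-derived series.
    """

    values: np.ndarray
    method: str
    lag_shift_days: int = 0
    undefined_edges: int = 0
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def sg_coefficients(window_m: int, poly_order: int, deriv_order: int) -> SGFilterSpec:
    """Least-squares SG weights for the window centre.

    ``window_m`` must be odd and at least 3; ``poly_order < window_m`` and
    ``deriv_order <= poly_order`` with ``deriv_order`` in {0, 1}.
    """
    if window_m < 3 or window_m % 2 == 0:
        raise InvalidFilterError(f"window_m must be odd and >= 3, got {window_m}")
    if not 0 <= poly_order < window_m:
        raise InvalidFilterError(
            f"need 0 <= poly_order < window_m, got {poly_order}"
        )
    if deriv_order not in (0, 1) or deriv_order > poly_order:
        raise InvalidFilterError(
            f"deriv_order must be 0 or 1 and <= poly_order, got {deriv_order}"
        )
    # 'dot' ordering gives weights indexed j = -(m-1)/2 .. (m-1)/2 such that
    # sum_j a_j y[t+j] estimates the value (deriv 0) or slope (deriv 1) at t.
    weights = savgol_coeffs(window_m, poly_order, deriv=deriv_order, use="dot")
    weights = np.ascontiguousarray(weights)
    weights.setflags(write=False)
    return SGFilterSpec(
        window_m=window_m,
        poly_order=poly_order,
        deriv_order=deriv_order,
        weights_aj=weights,
    )


def smooth_series(series: np.ndarray, spec: SGFilterSpec) -> np.ndarray:
    """Apply the SG convolution; the ``(m-1)/2`` edge days are NaN."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < spec.window_m:
        raise InvalidInputError(
            f"series of length {series.size} shorter than window {spec.window_m}"
        )
    h = spec.half_width
    core = np.correlate(series, spec.weights_aj, mode="valid")
    out = np.full(series.size, np.nan)
    out[h : series.size - h] = core
    return out


def _log_floored(series: np.ndarray, floor: float) -> np.ndarray:
    out = np.full(series.shape, np.nan)
    ok = np.isfinite(series)
    out[ok] = np.log(np.maximum(series[ok], floor))
    return out


def growth_from_log_incidence(
    incidence: np.ndarray,
    smooth_spec: SGFilterSpec | None = None,
    deriv_spec: SGFilterSpec | None = None,
    floor: float = LOG_FLOOR_CASES,
) -> GrowthRateSeries:
    """Growth rate from the log-derivative of SG-smoothed incidence.

    Two stages: smooth the raw counts (derivative order 0), floor at a small
    positive constant, log, then apply a first-derivative SG filter.  Staging
    avoids taking logs of raw (possibly zero) counts; days whose whole window
    is at the floor simply come out as zero growth, never as an exception.
    """
    smooth_spec = smooth_spec or sg_coefficients(DEFAULT_WINDOW, DEFAULT_POLY_ORDER, 0)
    deriv_spec = deriv_spec or sg_coefficients(DEFAULT_WINDOW, DEFAULT_POLY_ORDER, 1)
    if smooth_spec.deriv_order != 0 or deriv_spec.deriv_order != 1:
        raise InvalidFilterError(
            "smooth_spec must have deriv_order 0 and deriv_spec deriv_order 1"
        )
    incidence = np.asarray(incidence, dtype=float)
    smoothed = smooth_series(incidence, smooth_spec)
    log_s = _log_floored(smoothed, floor)
    h1 = smooth_spec.half_width
    h2 = deriv_spec.half_width
    core = np.correlate(log_s[h1 : log_s.size - h1], deriv_spec.weights_aj, "valid")
    values = np.full(incidence.size, np.nan)
    values[h1 + h2 : incidence.size - h1 - h2] = core
    return GrowthRateSeries(
        values=values,
        method="sg_log_incidence",
        undefined_edges=h1 + h2,
    )


def growth_from_total_infectiousness(
    incidence: np.ndarray,
    gt: GenerationTimeDistribution,
    deriv_spec: SGFilterSpec | None = None,
    floor: float = LOG_FLOOR_CASES,
    apply_shift: bool = True,
) -> GrowthRateSeries:
    """Growth rate from the log-derivative of the total infectiousness.

    The convolution with the generation-time distribution already smooths the
    counts, so only the first-derivative SG filter is applied to
    ``log Lambda_t``.  Because that kernel's centroid sits ``E[w]`` days in
    the past, the series is advanced by ``round(E[w] / 2)`` days by default
    (half of the total lag; the directly smoothed incidence is conventionally
    delayed by the other half when the two are compared against a model-based
    estimate).  Set ``apply_shift=False`` for the raw, unshifted series.

    The first ``L`` days (the generation-time support) see only a truncated
    kernel — the convolution there is not yet the full implicit filter — and
    are reported as undefined.
    """
    deriv_spec = deriv_spec or sg_coefficients(DEFAULT_WINDOW, DEFAULT_POLY_ORDER, 1)
    if deriv_spec.deriv_order != 1:
        raise InvalidFilterError("deriv_spec must have deriv_order 1")
    incidence = np.asarray(incidence, dtype=float)
    lam = total_infectiousness_series(incidence, gt)
    lam[: gt.support_days] = np.nan  # truncated-kernel burn-in
    log_lam = _log_floored(lam, floor)
    h = deriv_spec.half_width
    start = gt.support_days
    core = np.correlate(log_lam[start:], deriv_spec.weights_aj, "valid")
    values = np.full(incidence.size, np.nan)
    values[start + h : incidence.size - h] = core

    shift = int(round(gt.mean_days / 2.0)) if apply_shift else 0
    if shift:
        advanced = np.full(incidence.size, np.nan)
        advanced[: incidence.size - shift] = values[shift:]
        values = advanced
    return GrowthRateSeries(
        values=values,
        method="sg_total_infectiousness",
        lag_shift_days=-shift,
        undefined_edges=h + gt.support_days,
    )


def align_lag(
    series_a: GrowthRateSeries | np.ndarray,
    series_b: GrowthRateSeries | np.ndarray,
    max_lag: int,
) -> int:
    """Integer lag of ``series_a`` behind ``series_b``.

    Returns the ``k`` in ``[-max_lag, max_lag]`` maximising the Pearson
    correlation between ``a[t]`` and ``b[t - k]`` over their defined overlap
    (positive ``k``: ``a`` trails ``b`` by ``k`` days).  Ties break toward
    smaller ``|k|``.  The overlap must span at least ``3 * max_lag`` days.
    """
    a = series_a.values if isinstance(series_a, GrowthRateSeries) else np.asarray(series_a, float)
    b = series_b.values if isinstance(series_b, GrowthRateSeries) else np.asarray(series_b, float)
    if max_lag < 1:
        raise InvalidInputError("max_lag must be >= 1")
    n = min(a.size, b.size)
    overlap = np.isfinite(a[:n]) & np.isfinite(b[:n])
    if overlap.sum() < 3 * max_lag:
        raise InvalidInputError(
            f"need >= {3 * max_lag} overlapping defined days, got {overlap.sum()}"
        )
    best_lag, best_corr = 0, -np.inf
    for k in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if k >= 0:
            aa, bb = a[k:n], b[: n - k]
        else:
            aa, bb = a[: n + k], b[-k:n]
        ok = np.isfinite(aa) & np.isfinite(bb)
        if ok.sum() < 3:
            continue
        if np.std(aa[ok]) == 0 or np.std(bb[ok]) == 0:
            continue
        corr = pearsonr(aa[ok], bb[ok]).statistic
        if corr > best_corr + 1e-12:
            best_lag, best_corr = k, corr
    if not np.isfinite(best_corr):
        raise InvalidInputError("no lag produced a computable correlation")
    return best_lag
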