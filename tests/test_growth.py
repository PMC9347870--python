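import numpy as np
import pytest

import epigrowth as eg
from epigrowth.errors import InvalidFilterError, InvalidInputError


def brute_force_sg_weights(window_m, poly_order, deriv_order):
    """Independent oracle: explicit least-squares polynomial fit per window.

    Fit y ~ sum_k beta_k j^k over j = -(m-1)/2..(m-1)/2; the centre value is
    beta_0 and the centre slope beta_1, so the weights are the corresponding
    rows of the pseudo-inverse times deriv_order!.
    """
    h = (window_m - 1) // 2
    j = np.arange(-h, h + 1, dtype=float)
    X = np.vander(j, poly_order + 1, increasing=True)
    pinv = np.linalg.inv(X.T @ X) @ X.T
    return pinv[deriv_order]


class TestCoefficients:
    @pytest.mark.parametrize("poly_order", [0, 1])
    def test_moving_average_reduction(self, poly_order):
        """Polynomial order <= 1 with derivative 0 is the plain moving
        average a_j = 1/m."""
        spec = eg.sg_coefficients(5, poly_order, 0)
        np.testing.assert_allclose(spec.weights_aj, np.full(5, 0.2), atol=1e-12)

    @pytest.mark.parametrize(
        "window_m,poly_order,deriv_order",
        [(5, 2, 0), (5, 2, 1), (7, 3, 1), (15, 2, 0), (15, 2, 1), (9, 4, 0)],
    )
    def test_matches_normal_equations_oracle(self, window_m, poly_order, deriv_order):
        spec = eg.sg_coefficients(window_m, poly_order, deriv_order)
        expected = brute_force_sg_weights(window_m, poly_order, deriv_order)
        np.testing.assert_allclose(spec.weights_aj, expected, atol=1e-10)

    @pytest.mark.parametrize("window_m,poly_order,deriv_order", [(5, 2, 0), (9, 3, 0)])
    def test_smoothing_weights_sum_to_one(self, window_m, poly_order, deriv_order):
        spec = eg.sg_coefficients(window_m, poly_order, deriv_order)
        assert spec.weights_aj.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("window_m,poly_order", [(5, 2), (7, 3), (15, 2)])
    def test_derivative_weights_exact_on_ramps(self, window_m, poly_order):
        spec = eg.sg_coefficients(window_m, poly_order, 1)
        h = spec.half_width
        j = np.arange(-h, h + 1)
        assert spec.weights_aj.sum() == pytest.approx(0.0, abs=1e-12)
        assert spec.weights_aj @ j == pytest.approx(1.0, abs=1e-12)

    def test_ramp_derivative_is_slope(self):
        spec = eg.sg_coefficients(7, 2, 1)
        ramp = 3.7 * np.arange(30.0)
        smoothed = eg.smooth_series(ramp, spec)
        np.testing.assert_allclose(smoothed[3:-3], 3.7, atol=1e-10)

    @pytest.mark.parametrize(
        "window_m,poly_order,deriv_order",
        [(4, 2, 0), (1, 0, 0), (5, 5, 0), (5, 2, 2), (5, 0, 1)],
    )
    def test_invalid_parameters(self, window_m, poly_order, deriv_order):
        with pytest.raises(InvalidFilterError):
            eg.sg_coefficients(window_m, poly_order, deriv_order)


class TestSmoothSeries:
    def test_constant_preserved(self):
        spec = eg.sg_coefficients(5, 2, 0)
        out = eg.smooth_series(np.full(20, 6.5), spec)
        np.testing.assert_allclose(out[2:-2], 6.5, atol=1e-12)
        assert np.isnan(out[:2]).all() and np.isnan(out[-2:]).all()

    def test_moving_average_oracle(self):
        """Moving average of 1..10 with m=5 equals the centred 5-term means."""
        spec = eg.sg_coefficients(5, 1, 0)
        series = np.arange(1.0, 11.0)
        out = eg.smooth_series(series, spec)
        expected = np.array([np.mean(series[i - 2 : i + 3]) for i in range(2, 8)])
        np.testing.assert_allclose(out[2:8], expected, atol=1e-12)

    def test_derivative_of_constant_is_zero(self):
        spec = eg.sg_coefficients(5, 2, 1)
        out = eg.smooth_series(np.full(15, 42.0), spec)
        np.testing.assert_allclose(out[2:-2], 0.0, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            eg.smooth_series(np.ones(4), eg.sg_coefficients(5, 2, 0))


class TestGrowthEstimators:
    @pytest.mark.parametrize("r", [0.05, -0.05])
    def test_exact_on_noiseless_exponentials(self, gt_default, r):
        """Both estimators recover the exponent to 1e-6 on interior days:
        an LTI smoother scales an exponential by a constant, which the log
        derivative removes."""
        t_axis = np.arange(1, 151)
        inc = 1e5 * np.exp(r * t_axis)
        sg = eg.growth_from_log_incidence(inc)
        interior = np.isfinite(sg.values)
        assert np.max(np.abs(sg.values[interior] - r)) < 1e-6
        lam = eg.growth_from_total_infectiousness(inc, gt_default)
        interior = np.isfinite(lam.values)
        assert interior.sum() > 50
        assert np.max(np.abs(lam.values[interior] - r)) < 1e-6

    def test_constant_incidence_zero_growth(self, gt_default):
        inc = np.full(100, 200.0)
        for series in (
            eg.growth_from_log_incidence(inc),
            eg.growth_from_total_infectiousness(inc, gt_default),
        ):
            ok = np.isfinite(series.values)
            np.testing.assert_allclose(series.values[ok], 0.0, atol=1e-10)

    def test_all_zero_incidence_flagged_not_raised(self, gt_default):
        series = eg.growth_from_log_incidence(np.zeros(60))
        ok = np.isfinite(series.values)
        assert ok.any()
        np.testing.assert_allclose(series.values[ok], 0.0, atol=1e-12)

    def test_lambda_estimator_records_shift(self, gt_default, seasonal_growth):
        shifted = seasonal_growth["lambda"]
        assert shifted.lag_shift_days == -round(gt_default.mean_days / 2)
        assert seasonal_growth["lambda_raw"].lag_shift_days == 0

    def test_shift_improves_agreement(self, seasonal_growth):
        """Advancing the total-infectiousness estimate by E[w]/2 brings it
        closer to the smoothed-incidence estimate."""
        sg = seasonal_growth["sg"].values

        def mad(series):
            ok = np.isfinite(series.values) & np.isfinite(sg)
            return np.mean(np.abs(series.values[ok] - sg[ok]))

        assert mad(seasonal_growth["lambda"]) < mad(seasonal_growth["lambda_raw"])

    def test_total_infectiousness_is_implicit_smoother(
        self, seasonal_trajectory, gt_default
    ):
        """Advancing the total infectiousness by E[w] days reproduces the
        SG-smoothed incidence curve (relative RMS < 15% where counts > 10):
        the generation-time convolution is itself a smoothing filter."""
        inc = seasonal_trajectory.incidence.astype(float)
        lam = eg.total_infectiousness_series(inc, gt_default)
        lam[: gt_default.support_days] = np.nan
        tau = int(round(gt_default.mean_days))
        advanced = np.full(inc.size, np.nan)
        advanced[: inc.size - tau] = lam[tau:]
        smoothed = eg.smooth_series(inc, eg.sg_coefficients(15, 2, 0))
        ok = np.isfinite(advanced) & np.isfinite(smoothed) & (inc > 10)
        rel_rms = np.sqrt(np.mean((advanced[ok] - smoothed[ok]) ** 2)) / np.sqrt(
            np.mean(smoothed[ok] ** 2)
        )
        assert ok.sum() > 80
        assert rel_rms < 0.15

    def test_lambda_estimator_overshoots_less_at_troughs(
        self, seasonal_trajectory, seasonal_growth
    ):
        """At incidence troughs the epidemiological kernel damps the spurious
        swings that the generic SG estimate shows."""
        trough = seasonal_trajectory.incidence <= 10
        sg, lam = seasonal_growth["sg"], seasonal_growth["lambda"]
        max_sg = np.nanmax(np.abs(np.where(trough, sg.values, np.nan)))
        max_lam = np.nanmax(np.abs(np.where(trough, lam.values, np.nan)))
        assert max_lam < max_sg


class TestAlignLag:
    def test_self_alignment_is_zero(self, seasonal_growth):
        assert eg.align_lag(seasonal_growth["sg"], seasonal_growth["sg"], 10) == 0

    @pytest.mark.parametrize("k", [3, -4])
    def test_recovers_constructed_shift(self, k):
        rng = np.random.default_rng(0)
        base = np.cumsum(rng.normal(size=200))
        n = 200 - abs(k)
        if k >= 0:
            a, b = base[: n], np.roll(base, -k)[: n]  # a[t] == b[t - k]
        else:
            a, b = np.roll(base, k)[: n], base[: n]
        assert eg.align_lag(a, b, 10) == k

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(InvalidInputError):
            eg.align_lag(np.ones(10), np.ones(10), 10)
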