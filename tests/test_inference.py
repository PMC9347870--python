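import numpy as np
import pytest

import epigrowth as eg
from epigrowth.errors import ImpossibleObservationError, InvalidParameterError
from epigrowth.inference import (
    _filter_batch,
    _grid_quantiles,
    _smooth_batch,
    _transition_kernel,
    make_grid,
)


class TestGrid:
    def test_needs_enough_points(self):
        with pytest.raises(InvalidParameterError):
            eg.RtGrid(values=np.linspace(0.1, 5, 10))

    def test_rejects_nonpositive_start(self):
        with pytest.raises(InvalidParameterError):
            make_grid(r_min=0.0)

    def test_resolution(self):
        grid = make_grid(1.0, 2.0, 101)
        assert grid.resolution == pytest.approx(0.01)


class TestForwardFilter:
    def test_rows_sum_to_one(self, seasonal_posterior):
        np.testing.assert_allclose(seasonal_posterior.filtered.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(seasonal_posterior.smoothed.sum(axis=1), 1.0, atol=1e-9)

    def test_no_information_propagates_prior(self, gt_default):
        """All-zero incidence gives zero infectious pressure and a flat
        likelihood, so each filtered posterior is exactly the previous one
        pushed through the state kernel."""
        grid = make_grid(n=100)
        filtered = eg.filter_forward(np.zeros(10), gt_default, grid)
        kernel = _transition_kernel(grid, 0.1)
        expected = np.full(100, 1.0 / 100)
        np.testing.assert_allclose(filtered[0], expected, atol=1e-12)
        for t in range(1, 10):
            expected = expected @ kernel
            np.testing.assert_allclose(filtered[t], expected, atol=1e-9)

    def test_cases_without_infectiousness_rejected(self, gt_default):
        inc = np.zeros(10)
        inc[1] = 5  # day 2 has cases but no past incidence
        with pytest.raises(ImpossibleObservationError):
            eg.filter_forward(inc, gt_default, make_grid(n=100))

    def test_constant_r_recovered(self, gt_default):
        traj = eg.simulate(eg.constant_rt_profile(200, 2.0), gt_default, 5, rng_seed=3)
        posterior = eg.estimate_rt(traj.incidence, gt_default)
        assert abs(posterior.mean_rt[-1] - 2.0) / 2.0 < 0.10

    def test_invalid_eta(self, gt_default):
        with pytest.raises(InvalidParameterError):
            eg.filter_forward(np.ones(10), gt_default, make_grid(n=100), state_noise_eta=0.0)


class TestSmoother:
    def test_final_day_equals_filtered(self, seasonal_posterior):
        np.testing.assert_allclose(
            seasonal_posterior.smoothed[-1], seasonal_posterior.filtered[-1], atol=1e-12
        )

    def test_smoothing_reduces_variance_on_average(self, seasonal_posterior):
        assert (
            seasonal_posterior.smoothed_variance().mean()
            <= seasonal_posterior.filtered_variance().mean()
        )

    def test_smoother_beats_filter_mse(self, gt_default):
        """Paired replicates: conditioning on the whole series lowers the
        mean-squared error against the constant truth."""
        R, n_rep = 1.3, 100
        grid = make_grid(n=500)
        kernel = _transition_kernel(grid, 0.1)
        profile = eg.constant_rt_profile(120, R)
        incs, lams = [], []
        for seed in range(n_rep):
            traj = eg.simulate(profile, gt_default, 10, rng_seed=5000 + seed)
            incs.append(traj.incidence)
            lams.append(traj.total_infectiousness)
        f, p = _filter_batch(np.array(incs, float), np.array(lams, float), grid, 0.1, kernel)
        s = _smooth_batch(f, p, grid, 0.1, kernel)
        g = grid.values
        burn = 8
        mse_f = np.mean((f @ g - R)[:, burn:] ** 2)
        mse_s = np.mean((s @ g - R)[:, burn:] ** 2)
        assert mse_s < mse_f


class TestPosteriorSummaries:
    def test_interval_brackets_mean(self, seasonal_posterior):
        assert np.all(seasonal_posterior.ci_lower <= seasonal_posterior.mean_rt + 1e-9)
        assert np.all(seasonal_posterior.mean_rt <= seasonal_posterior.ci_upper + 1e-9)

    def test_grid_quantiles_of_known_pmf(self):
        """Mass split evenly over two adjacent cells: the median sits at their
        shared edge and the quartiles at the cell midpoints."""
        grid = make_grid(1.0, 2.0, 101)
        pmf = np.zeros(101)
        pmf[40] = pmf[41] = 0.5
        qs = _grid_quantiles(pmf[None, :], grid, np.array([0.25, 0.5, 0.75]))[0]
        assert qs[1] == pytest.approx(grid.values[40] + grid.resolution / 2, abs=1e-9)
        assert qs[0] == pytest.approx(grid.values[40], abs=1e-9)
        assert qs[2] == pytest.approx(grid.values[41], abs=1e-9)

    def test_more_incidence_tightens_posterior(self, gt_default):
        """Scaling the epidemic up 10x shrinks the posterior variance."""
        profile = eg.seasonal_rt_profile(150)
        config = eg.EpiFilterConfig(grid_size=500)
        variances = {}
        for seed_cases in (5, 50):
            traj = eg.simulate(profile, gt_default, seed_cases, rng_seed=42)
            posterior = eg.estimate_rt(traj.incidence, gt_default, config)
            variances[seed_cases] = posterior.smoothed_variance()[traj.n_seed_days :].mean()
        assert variances[50] < variances[5]

    def test_grid_refinement_stability(self, gt_default):
        """Doubling the grid resolution moves the posterior mean < 1%."""
        traj = eg.simulate(eg.seasonal_rt_profile(150), gt_default, 50, rng_seed=2)
        coarse = eg.estimate_rt(traj.incidence, gt_default, eg.EpiFilterConfig(grid_size=1000))
        fine = eg.estimate_rt(traj.incidence, gt_default, eg.EpiFilterConfig(grid_size=2000))
        rel = np.abs(fine.mean_rt - coarse.mean_rt) / coarse.mean_rt
        assert rel.max() < 0.01

    def test_summary_csv(self, seasonal_posterior, tmp_path):
        import pandas as pd

        path = tmp_path / "posterior.csv"
        eg.write_posterior_csv(seasonal_posterior, path)
        table = pd.read_csv(path)
        assert list(table.columns) == [
            "day", "mean_R", "ci_lower", "ci_upper", "pred_mean", "pred_lower", "pred_upper",
        ]
        assert len(table) == seasonal_posterior.horizon
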