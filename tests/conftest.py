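import numpy as np
import pytest

import epigrowth as eg


@pytest.fixture(scope="session")
def gt_default():
    """Gamma(3, 0.375) generation time: mean 8 days on the continuous scale."""
    return eg.discretize_gamma(3.0, 0.375)


@pytest.fixture(scope="session")
def seasonal_trajectory(gt_default):
    """Default seasonal epidemic (300 days, R_t = 1 + 0.75 sin(2 pi t/120))."""
    profile = eg.seasonal_rt_profile(300)
    return eg.simulate(profile, gt_default, seed_cases=50, rng_seed=1)


@pytest.fixture(scope="session")
def seasonal_posterior(seasonal_trajectory, gt_default):
    """Smoothed R_t posterior for the default seasonal epidemic."""
    return eg.estimate_rt(seasonal_trajectory.incidence, gt_default)


@pytest.fixture(scope="session")
def seasonal_growth(seasonal_trajectory, gt_default):
    """The three growth-rate estimates on the default seasonal epidemic."""
    inc = seasonal_trajectory.incidence
    return {
        "sg": eg.growth_from_log_incidence(inc),
        "lambda": eg.growth_from_total_infectiousness(inc, gt_default),
        "lambda_raw": eg.growth_from_total_infectiousness(
            inc, gt_default, apply_shift=False
        ),
    }


@pytest.fixture(scope="session")
def true_seasonal_r(seasonal_trajectory):
    """Exact growth rates implied by the true R_t profile (gamma transform)."""
    return np.array(
        [
            eg.growth_from_R_gamma(R, 3.0, 0.375)
            for R in seasonal_trajectory.true_rt_profile.values
        ]
    )
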