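import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from elevrange import response_curves as rc
from elevrange import synthetic_data as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rugged_grid() -> syn.ElevationGrid:
    """Default rugged terrain covering 600-2,700 m."""
    return syn.generate_landscape(1)


@pytest.fixture(scope="session")
def gaussian_truth() -> syn.SpeciesTruth:
    """Symmetric curve with optimum 1,500 m, scale 200 m, peak 0.6."""
    return syn.SpeciesTruth.from_linear_drift(
        "gauss", [2000], p_max=0.6, mu0=1500.0, sigma_l0=200.0, sigma_u0=200.0
    )


@pytest.fixture(scope="session")
def gaussian_survey(rugged_grid, gaussian_truth):
    """5,000 point counts from the symmetric Gaussian truth."""
    return syn.simulate_surveys(rugged_grid, [gaussian_truth], {2000: 5000}, seed=2)


def analytic_curve(
    mu: float,
    sigma_l: float,
    sigma_u: float,
    p_max: float = 0.6,
    settings_: rc.CurveSettings | None = None,
) -> rc.FittedCurve:
    """Tabulate an asymmetric Gaussian as a FittedCurve (no fitting)."""
    s = settings_ or rc.CurveSettings()
    grid = s.grid()
    sigma = np.where(grid < mu, sigma_l, sigma_u)
    p = p_max * np.exp(-((grid - mu) ** 2) / (2 * sigma**2))
    return rc.FittedCurve("analytic", 2000, grid, p, converged=True, n_obs=0)
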