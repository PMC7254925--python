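import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dietval as dv

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# A fixed, well-conditioned parameter set used across estimation tests:
# moderate slopes, correlated person biases, noticeable within-person error.
P0 = dv.ModelParameters(
    mu_T=4.25,
    sigma2_T=0.09,
    mu_Q=(0.0, 0.02, -0.02),
    mu_F=(0.0, 0.02, -0.02),
    mu_M=(0.0, 0.0, 0.0),
    beta_Q0=1.92,
    beta_F0=1.68,
    beta_Q1=0.59,
    beta_F1=0.64,
    sigma2_r=0.059,
    sigma2_s=0.043,
    rho_rs=0.3,
    sigma2_eps=0.107,
    sigma2_u=0.095,
    sigma2_v=0.0875,
)


@pytest.fixture(scope="session")
def p0():
    return P0


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition cohort (n=160, J=3) shared by read-only tests."""
    return dv.generate_cohort(dv.SimulationScenario(seed=42))


@pytest.fixture(scope="session")
def protein_fit(small_sim):
    return dv.fit_model(small_sim.cohorts["protein"])


def make_scenario(seed, **kwargs):
    return dv.SimulationScenario(seed=seed, **kwargs)
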