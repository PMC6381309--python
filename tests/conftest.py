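import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

import critspeed as cs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: group-level linear-condition parameter means used as the canonical
#: simulation truth throughout the tests (growth terms are defaults:
#: tau_g = 1.5 s, Ag from the start-from-rest constraint)
LINEAR_MEANS = dict(s0=3.52, a_d=5.37, t_c=6.42, tau_d=43.96)


def biexp_params_strategy():
    """Valid parameter sets spanning the optimiser bounds."""
    return st.builds(
        cs.BiExpParams,
        s0=st.floats(0.5, 8.0),
        a_d=st.floats(0.5, 10.0),
        a_g=st.floats(0.1, 50.0),
        t_c=st.floats(1.0, 20.0),
        tau_g=st.floats(0.2, 10.0),
        tau_d=st.floats(5.0, 200.0),
    )


@pytest.fixture(scope="session")
def linear_params() -> cs.BiExpParams:
    return cs.BiExpParams.from_rest(tau_g=1.5, **LINEAR_MEANS)


@pytest.fixture(scope="session")
def noiseless_trace(linear_params) -> cs.SpeedTimeSeries:
    return cs.generate_trace(
        cs.SimulationSpec(truth=linear_params, noise_sd=0.0, rate=1.0, seed=0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190219)
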