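import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from floralpattern import KineticParams, ModelOptions, RunConfig, simulate
from floralpattern.wus_prepattern import WusParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def wildtype_traj(default_config):
    """The full default (wide-boundary, eps=5) 16.6 h run, shared."""
    return simulate(default_config)


@pytest.fixture(scope="session")
def wildtype_final(wildtype_traj):
    return wildtype_traj.final_state


@pytest.fixture
def short_config() -> RunConfig:
    """A cheap configuration for structural tests: 100 s of simulated time
    with a 10 s gate and a fast WUS clock so every field moves."""
    return RunConfig(
        n_steps=2000,
        sample_every=200,
        kinetics=KineticParams(gate_time=10.0),
        wus=WusParams(time_scale=20.0),
    )


@pytest.fixture
def uniform_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def default_options() -> ModelOptions:
    return ModelOptions()


def rand_profile(rng: np.random.Generator, n: int = 15) -> np.ndarray:
    return rng.uniform(0.0, 3.0, size=n)
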