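import numpy as np
import pytest
from hypothesis import settings

from purgesim import SimulationConfig, burn_in

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small but structurally complete configuration for unit tests."""
    return SimulationConfig(
        s=0.1, h=0.5, free_recombination=True,
        n_s=20000, n_n=1000, N_b=50,
        U_del=0.1, U_neu=0.02, T_burnin=100, seed=42,
    )


@pytest.fixture(scope="session")
def small_base(tiny_config):
    """A quick burned-in base population shared by line-level unit tests."""
    config = tiny_config.replace(N_b=100, T_burnin=300)
    pop = burn_in(config, np.random.default_rng(config.seed))
    return pop, config
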