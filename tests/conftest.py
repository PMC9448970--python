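import numpy as np
import pytest

from msmr.model import ModelSpec
from msmr.synthetic import SimConfig, simulate_histories


@pytest.fixture(scope="session")
def constant_config() -> SimConfig:
    return SimConfig.constant(
        phi=0.8,
        p={"B": 0.9, "N": 0.55, "P": 0.5},
        psi_move={"B": 0.2, "N": 0.65, "P": 0.5},
        n_per_colony=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def sim_histories(constant_config):
    return simulate_histories(constant_config)


@pytest.fixture(scope="session")
def constant_spec() -> ModelSpec:
    return ModelSpec(phi="1", p="state", psi="state")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
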