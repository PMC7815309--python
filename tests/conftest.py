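import numpy as np
import pytest

from banditexplore import (
    ParameterSet,
    TaskConfig,
    build_taskset,
    parse_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig(seed=11)


@pytest.fixture(scope="session")
def default_taskset(default_config):
    return build_taskset(default_config)


@pytest.fixture(scope="session")
def small_taskset():
    """160-trial task set (10 trials per combination)."""
    return build_taskset(TaskConfig(seed=23, trials_per_combination=10))


@pytest.fixture(scope="session")
def winning_model():
    return parse_model("thompson+vf+nov")


@pytest.fixture(scope="session")
def mean_fit_params():
    """Mean fitted parameters used throughout validation simulations."""
    return ParameterSet(Q0=3.2, sigma0=1.312, epsilon=0.1, eta=2.625)


@pytest.fixture(scope="session")
def simulated_dataset(winning_model, default_taskset):
    params = ParameterSet(
        Q0=3.2, sigma0=1.312, epsilon={1: 0.3, 6: 0.1}, eta={1: 1.0, 6: 2.5}
    )
    return simulate_dataset(winning_model, params, default_taskset, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
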