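import numpy as np
import pytest

import depictive as dp


@pytest.fixture(scope="session")
def benchmark_pop():
    """Five-component benchmark population, moderate size, fixed seed."""
    return dp.simulate_population(dp.benchmark_config(n_cells=2000, seed=123))


@pytest.fixture(scope="session")
def censored_q(benchmark_pop):
    return dp.censor_to_live_only(benchmark_pop, "q")


@pytest.fixture(scope="session")
def jurkat_params():
    return dp.load_params("jurkat-like")


@pytest.fixture(scope="session")
def mda_params():
    return dp.load_params("mda-like")


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
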