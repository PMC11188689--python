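import numpy as np
import pytest

from barfit import simulate


@pytest.fixture(scope="session")
def small_genome():
    """20 kb circular genome with 40 genes (deterministic)."""
    return simulate.simulate_genome(20_000, 40, seed=11)


@pytest.fixture(scope="session")
def small_library(small_genome):
    annotation, _seq = small_genome
    pool, abundances = simulate.simulate_library(
        annotation, 200, coding_fraction=0.9, seed=12
    )
    return pool, abundances


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
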