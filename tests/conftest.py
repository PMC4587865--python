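import numpy as np
import pytest

from methylmark import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_screen():
    """One screen simulation at default settings, shared across tests."""
    spec = sim.ScreenSimSpec(seed=7)
    matrix, truth = sim.gen_expression_matrices(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort simulation at default settings, shared across tests."""
    spec = sim.CohortSimSpec(seed=7)
    table, truth = sim.gen_cohort(spec)
    return spec, table, truth
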