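import numpy as np
import pytest

from opmomentum import design, metrics, synthetic


@pytest.fixture(scope="session")
def problem_table():
    return design.build_problem_table()


@pytest.fixture(scope="session")
def default_cohort():
    """One default 32+32 cohort, shared across tests that only read it."""
    return synthetic.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def default_bias(default_cohort):
    trials, _, _ = default_cohort
    return metrics.om_bias(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
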