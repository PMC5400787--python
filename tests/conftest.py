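import numpy as np
import pytest

from mircohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = SimulationConfig(n_subjects=150, n_mirna=80, n_mrna=40,
                           site="mixed", seed=42)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
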