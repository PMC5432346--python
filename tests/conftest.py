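import numpy as np
import pytest
from hypothesis import settings

import cvasd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_cohort():
    """One strong-signal synthetic cohort at the default configuration."""
    return cvasd.simulate(cvasd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for CV plumbing tests."""
    cfg = cvasd.SimulationConfig(
        n_patients=80, n_genes=15, n_sensitive_genes=4, seed=7,
        censoring_rate=0.4, treatment_prob=0.5,
    )
    return cvasd.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
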