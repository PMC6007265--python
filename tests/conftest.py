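import dataclasses

import numpy as np
import pytest

from socialpref.cohort import CohortConfig, simulate_cohort
from socialpref.fitting import FitOptions
from socialpref.task import TaskConfig


@pytest.fixture(scope="session")
def task_cfg() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def fit_opts() -> FitOptions:
    return FitOptions(seed=0)


@pytest.fixture(scope="session")
def behavioral_cohort():
    """Six default agents, behavior only (fast, shared across tests)."""
    cc = dataclasses.replace(CohortConfig(), n_participants=6,
                             with_optics=False)
    return simulate_cohort(cc, seed=7)


@pytest.fixture(scope="session")
def optical_cohort():
    """Four default agents including forward-modelled optics."""
    cc = dataclasses.replace(CohortConfig(), n_participants=4)
    return simulate_cohort(cc, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
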