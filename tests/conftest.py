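import numpy as np
import pytest

from mbooi.grading import grade_cohort
from mbooi.indices import add_indices
from mbooi.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort with derived index columns."""
    return add_indices(generate_cohort(SimulationConfig(), seed=42))


@pytest.fixture(scope="session")
def graded_cohort(default_cohort):
    return grade_cohort(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
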