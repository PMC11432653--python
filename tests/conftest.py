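import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ldlprs.score import ScoreDefinition
from ldlprs.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def definition() -> ScoreDefinition:
    return ScoreDefinition.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest labelled synthetic cohort shared across tests."""
    return simulate_cohort(CohortSpec(), n=800, seed=11)


@pytest.fixture(scope="session")
def big_cohort():
    """The default-condition cohort at the size used for recovery checks."""
    return simulate_cohort(CohortSpec(), n=10_000, seed=20240918)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
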