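import pytest

from hnf1b_score import CohortConfig, generate_cohort, uk_fixture


@pytest.fixture(scope="session")
def fixture_table():
    return uk_fixture()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default UK-like synthetic cohort (n=686), fixed seed for the suite."""
    return generate_cohort(CohortConfig(seed=20150522))
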