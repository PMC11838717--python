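import pytest

import urised as u


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 463-sample reference cohort."""
    return u.study_fixture()


@pytest.fixture(scope="session")
def schemes():
    return u.default_schemes()


@pytest.fixture(scope="session")
def merge_maps(schemes):
    return u.default_merge_maps(schemes)
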