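import numpy as np
import pytest

from nonfh_collapse import reconstructed_fixture
from nonfh_collapse.report import _score_event_counts


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 202-hip cohort rebuilt from the published tables."""
    return reconstructed_fixture()


@pytest.fixture(scope="session")
def score_counts(fixture_cohort):
    """(positives, negatives) per score level on the fixture cohort."""
    return _score_event_counts(fixture_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20161001)
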