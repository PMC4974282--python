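import pytest

from petct_screen import build_paper_fixture
from petct_screen.adjudicate import evaluable_set, locoregional_set


@pytest.fixture(scope="session")
def paper_cohort():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def evaluable(paper_cohort):
    return evaluable_set(paper_cohort)


@pytest.fixture(scope="session")
def lrc(evaluable):
    return locoregional_set(evaluable)
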