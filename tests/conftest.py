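import logging

import pytest

from vttrial.cohort import reference_cohort
from vttrial.design import DesignSpec, TwoStageDesign, search_designs

logging.getLogger("vttrial").setLevel(logging.ERROR)

# the trial's design: 5% unacceptable vs 25% target response, one-sided
# alpha 0.10, power 0.90
TRIAL_SPEC = DesignSpec(p0=0.05, p1=0.25, alpha=0.10, beta=0.10, n_max=60)
TRIAL_DESIGN = TwoStageDesign(r1=0, n1=13, r=2, n=20)


@pytest.fixture(scope="session")
def trial_design() -> TwoStageDesign:
    return TRIAL_DESIGN


@pytest.fixture(scope="session")
def trial_spec() -> DesignSpec:
    return TRIAL_SPEC


@pytest.fixture(scope="session")
def trial_search():
    return search_designs(TRIAL_SPEC)


@pytest.fixture(scope="session")
def fixture_cohort():
    return reference_cohort()
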