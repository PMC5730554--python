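import copy

import pytest

from riskrecal import builtin_specs, fit_cox, generate_cohort


@pytest.fixture(scope="session")
def specs():
    """The built-in (NE, SE) population specs."""
    return builtin_specs()


@pytest.fixture()
def ne_spec(specs):
    return copy.deepcopy(specs[0])


@pytest.fixture()
def se_spec(specs):
    return copy.deepcopy(specs[1])


@pytest.fixture(scope="session")
def ne_cohort(specs):
    return generate_cohort(specs[0], seed=11)


@pytest.fixture(scope="session")
def se_cohort(specs):
    return generate_cohort(specs[1], seed=12)


@pytest.fixture(scope="session")
def ne_fit(ne_cohort):
    return fit_cox(ne_cohort, horizon=25.0)


@pytest.fixture(scope="session")
def se_fit(se_cohort):
    return fit_cox(se_cohort, horizon=25.0)
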