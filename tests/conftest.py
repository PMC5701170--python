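import pytest
from hypothesis import settings

import remipk as rp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def final_model():
    return rp.final_2017()


@pytest.fixture(scope="session")
def female_ref():
    """Reference female subject at the centring pump speed."""
    return rp.CovariateRecord(sex=0, pump_speed=2350.0)


@pytest.fixture(scope="session")
def male_ref():
    return rp.CovariateRecord(sex=1, pump_speed=2350.0)


@pytest.fixture(scope="session")
def small_study(final_model):
    """15-subject sparse study emulating the original design."""
    return rp.paper_like_study(seed=4)


@pytest.fixture(scope="session")
def small_fit(small_study, final_model):
    """A converged fit of the final-model structure on the small study."""
    fit = rp.PopPKModel(small_study, final_model).fit(compute_se=False)
    assert fit.converged
    return fit
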