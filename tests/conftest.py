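import pytest

from p53ddr.model import ModelState, StimulusSchedule, steady_state
from p53ddr.params import DEFAULT_OBSERVABLE_MAP, DEFAULT_PARAMS


@pytest.fixture(scope="session")
def base_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def base_omap():
    return DEFAULT_OBSERVABLE_MAP


@pytest.fixture(scope="session")
def base_steady(base_params):
    return steady_state(base_params)


@pytest.fixture(scope="session")
def unit_params():
    """All rate parameters equal to one (hand-evaluation oracle point)."""
    from p53ddr.model import RATE_PARAM_NAMES, KineticParameters

    return KineticParameters(**{n: 1.0 for n in RATE_PARAM_NAMES})


@pytest.fixture(scope="session")
def unit_state():
    return ModelState(*([1.0] * 10))


@pytest.fixture
def no_stimulus():
    return StimulusSchedule(EC=0.0, tau=0.0)
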