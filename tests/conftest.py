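import numpy as np
import pytest

from mycotherm import (
    FIG5_VIRULENCE,
    TABLE6_EXPERIMENT1,
    TABLE6_EXPERIMENT2,
    TABLE6_EXPERIMENT3,
)

#: Every bundled published parameter set, for property suites.
ALL_FIXTURE_PARAMS = {
    "virulence": FIG5_VIRULENCE,
    "growth_exp1": TABLE6_EXPERIMENT1,
    "growth_exp2": TABLE6_EXPERIMENT2,
    "growth_exp3": TABLE6_EXPERIMENT3,
}


@pytest.fixture(params=list(ALL_FIXTURE_PARAMS), ids=list(ALL_FIXTURE_PARAMS))
def fixture_params(request):
    return ALL_FIXTURE_PARAMS[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
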