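from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from makit import enzymatic_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA = Path(__file__).parent / "data"

# Paper-fixed constants of the enzymatic model, used across test modules.
K1, K2, K3 = 0.184, 0.016, 0.211
# closed form for one enzyme: r1 count to the 6th conversion is negative
# binomial with success probability k3/(k2+k3), mean 6*(k2+k3)/k3
CLOSED_FORM_E1 = 6 * (K2 + K3) / K3


@pytest.fixture
def enzymatic():
    return enzymatic_fixture()


@pytest.fixture
def data_dir():
    return DATA
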