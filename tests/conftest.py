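import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soyflood.soil import SoilLayer, SoilProfile, SoilWaterState

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def simple_profile() -> SoilProfile:
    """Four equal 300 mm layers, free-draining."""
    return SoilProfile(
        tuple(
            SoilLayer(300.0, 0.20, 0.30, 0.40, 1.40, ks=50.0, kl=0.08)
            for _ in range(4)
        )
    )


@pytest.fixture
def simple_state(simple_profile) -> SoilWaterState:
    return SoilWaterState(
        sw=simple_profile.arr("dul").copy(),
        mineral_n=np.full(simple_profile.n_layers, 10.0),
    )
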