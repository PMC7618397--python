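import numpy as np
import pytest

from astrokir.kir_kinetics import KirParams
from astrokir.territory_model import DynamicsConfig


@pytest.fixture
def params() -> KirParams:
    return KirParams()


@pytest.fixture
def small_config() -> DynamicsConfig:
    """A cubic 9x9x9 arena small enough for repeated runs in tests."""
    return DynamicsConfig(
        arena=(45.0, 45.0, 45.0),
        center=(0.0, 0.0, 0.0),
        grid=(9, 9, 9),
        territory_radius=15.0,
        duration=3.0,
        snapshot_every=250.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
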