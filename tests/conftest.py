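import numpy as np
import pytest

from emkit.containers import SensorLayout
from emkit.inverse import InterpolationOperator
from emkit.synth import make_layout


@pytest.fixture(scope="session")
def eeg_layout_64() -> SensorLayout:
    return make_layout("sphere_eeg", 64)


@pytest.fixture(scope="session")
def eeg_layout_32() -> SensorLayout:
    return make_layout("sphere_eeg", 32)


@pytest.fixture(scope="session")
def meg_layout_32() -> SensorLayout:
    return make_layout("sphere_meg", 32)


@pytest.fixture(scope="session")
def interp_64(eeg_layout_64) -> InterpolationOperator:
    """Shared inverse-forward interpolator (moderate source grid)."""
    return InterpolationOperator(eeg_layout_64, lam=0.05, n_sources=300)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
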