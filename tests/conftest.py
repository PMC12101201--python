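import numpy as np
import pytest

from hearthru import (
    HeadModelParams,
    TransparencyParams,
    apply_transparency,
    make_hrir_set,
)

FS = 44100


@pytest.fixture(scope="session")
def head_params():
    return HeadModelParams()


@pytest.fixture(scope="session")
def nh_hrirs(head_params):
    """Default-calibrated normal-hearing set, 0° elevation row only (fast)."""
    return make_hrir_set(head_params, elevations=[0.0], seed=0)


@pytest.fixture(scope="session")
def nh_hrirs_full(head_params):
    """Full azimuth × elevation grid."""
    return make_hrir_set(head_params, seed=0)


@pytest.fixture(scope="session")
def device_hrirs(nh_hrirs):
    """Transparency-transformed counterpart of the 0°-elevation set."""
    return apply_transparency(nh_hrirs, TransparencyParams(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
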