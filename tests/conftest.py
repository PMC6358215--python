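import numpy as np
import pytest

from drivesim import DriveParams, design_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def catalog():
    return design_catalog()


@pytest.fixture
def null_params():
    """All stochastic modification switched off: pure Mendelian transmission."""
    return DriveParams(
        c_f=0.0, c_m=0.0, r_f=0.0, r_m=0.0, r1_fraction=0.0,
        e_cut=0.0, e_mosaic=0.0, p_active=0.0, c_carry=0.0, r_carry=0.0,
    )
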