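import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from herbe import (
    LQPair,
    TissueParams,
    kernel_library,
    load_tissue,
    optimize_sobp,
)

# Measured LQ parameters (photon baseline + helium rows with their LET_d)
# for the SOBP cell experiment; mirrors the packaged fixture table.
EXP_B_PHOTON = dict(alpha_x=0.050, beta_x=0.023)
EXP_B_ROWS = {
    4.78: LQPair(0.076, 0.024),
    10.18: LQPair(0.150, 0.018),
    15.37: LQPair(0.201, 0.017),
    26.52: LQPair(0.305, 0.022),
}


@pytest.fixture(scope="session")
def water2() -> TissueParams:
    return load_tissue("water2")


@pytest.fixture(scope="session")
def water10() -> TissueParams:
    return load_tissue("water10")


@pytest.fixture(scope="session")
def photon_b() -> TissueParams:
    return TissueParams(**EXP_B_PHOTON, label="Renca photon, SOBP experiment")


@pytest.fixture(scope="session")
def sobp_kernels():
    """Pristine kernels spanning a 4-cm target centered at 8 cm depth."""
    return kernel_library(60.0, 100.0, spacing=2.0)


@pytest.fixture(scope="session")
def bio_sobp(sobp_kernels, water2):
    """Biologically optimized 2 Gy (RBE) SOBP (DDM, (alpha/beta)_x = 2 Gy)."""
    return optimize_sobp(
        sobp_kernels, 2.0, (60.0, 100.0), model="ddm", tissue=water2,
        mode="biological",
    )
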