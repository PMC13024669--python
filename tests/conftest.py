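import numpy as np
import pytest

import mbovs as M
from mbovs.sequences import cine_protocol, residual_vs_t1

T1_GRID = (0.2, 0.25, 0.275, 0.3, 0.325, 0.35)


@pytest.fixture(scope="session")
def pulse_catalog():
    return M.standard_pulse_set()


@pytest.fixture(scope="session")
def am8(pulse_catalog):
    return pulse_catalog["am_sinc_8"]


@pytest.fixture(scope="session")
def geometry():
    return M.default_geometry()


@pytest.fixture(scope="session")
def wide_positions():
    """1 mm grid covering both slabs plus margin for transition metrics."""
    return -0.225 + 1e-3 * np.arange(451)


@pytest.fixture(scope="session")
def cine_seq():
    return cine_protocol()


@pytest.fixture(scope="session")
def residual_curve(cine_seq):
    """Residual stop-band signal (%) on the characterization T1 grid."""
    return residual_vs_t1(list(T1_GRID), cine_seq)


@pytest.fixture(scope="session")
def catalog_profiles(pulse_catalog, geometry, wide_positions):
    """Saturation profiles of the full pulse catalog on the wide grid."""
    return {
        name: M.simulate_profile(shape, geometry, positions=wide_positions)
        for name, shape in pulse_catalog.items()
    }
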