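import numpy as np
import pytest

import srnfshape as ss
from srnfshape.sphere_grid import grid_nodes_xyz


@pytest.fixture(scope="session")
def grid32():
    return ss.make_grid(32, 32)


@pytest.fixture(scope="session")
def grid64():
    return ss.make_grid(64, 64)


@pytest.fixture(scope="session")
def unit_sphere64(grid64):
    return ss.GridSurface(grid64, grid_nodes_xyz(grid64), "unit-sphere")


@pytest.fixture(scope="session")
def ellipsoid64(grid64):
    return ss.GridSurface(
        grid64, grid_nodes_xyz(grid64) * np.array([1.0, 0.7, 0.5]), "ellipsoid"
    )


@pytest.fixture(scope="session")
def bumpy_pair32(grid32):
    """Two distinct smooth synthetic shapes on the 32x32 grid, normalized."""
    spec = ss.SurfaceFamilySpec(
        n=2, seed=3, grid=grid32, mode_sds=(0.05, 0.03, 0.02)
    )
    surfaces, _, _ = ss.generate_family(spec)
    return surfaces
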