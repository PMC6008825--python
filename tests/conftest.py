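"""Shared fixtures: small phantoms and toy planning instances."""

import numpy as np
import pytest

from imrtbao.phantoms import Phantom, Structure, VoxelGrid, make_box_phantom


@pytest.fixture(scope="session")
def box_phantom():
    """Full-size box preset (40x40x20 grid, 32k body voxels)."""
    return make_box_phantom()


@pytest.fixture(scope="session")
def small_box_phantom():
    """Coarse box phantom for search tests: 1 cm voxels, 4000 body voxels."""
    return make_box_phantom(voxel_size_cm=1.0, ptv_half_length_cm=1.0)


def make_line_phantom(n_target: int, n_oar: int = 0, n_extra_body: int = 0) -> Phantom:
    """1-D phantom with n_target target voxels, then OAR, then plain body.

    Lets FMO tests specify a dose-influence matrix by hand: body voxel k is
    row k of the matrix.
    """
    n = n_target + n_oar + n_extra_body
    grid = VoxelGrid(shape=(n, 1, 1), voxel_size=(1.0, 1.0, 1.0))
    structures = [Structure("PTV", "target", np.arange(n_target))]
    if n_oar:
        structures.append(Structure("OAR", "oar", n_target + np.arange(n_oar)))
    structures.append(Structure("Body", "body", np.arange(n)))
    return Phantom(grid=grid, structures=tuple(structures))


@pytest.fixture
def line_phantom_factory():
    return make_line_phantom
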