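import numpy as np
import pytest

from icsfilter.geometry import ImageVolume, ScannerGeometry
from icsfilter.mc import AttenuationTable
from icsfilter.projector import SystemMatrixView


@pytest.fixture(scope="session")
def tiny_geometry():
    """8 transaxial crystals x 2 rings: smallest ring the package allows."""
    return ScannerGeometry(ring_radius=15.0, n_crystals_transaxial=8,
                           n_rings=2, crystal_pitch_transaxial=11.0,
                           crystal_pitch_axial=6.0, crystal_depth=5.0,
                           axial_fov=12.0)


@pytest.fixture(scope="session")
def toy_geometry():
    """16-crystal x 2-ring toy used for the EM and projector checks."""
    return ScannerGeometry(ring_radius=15.0, n_crystals_transaxial=16,
                           n_rings=2, crystal_pitch_transaxial=5.8,
                           crystal_pitch_axial=6.0, crystal_depth=5.0,
                           axial_fov=12.0)


@pytest.fixture(scope="session")
def tiny_volume():
    return ImageVolume((9, 9, 9), 2.0)


@pytest.fixture(scope="session")
def tiny_view(tiny_geometry, tiny_volume):
    return SystemMatrixView(tiny_geometry, tiny_volume)


@pytest.fixture(scope="session")
def toy_view(toy_geometry, tiny_volume):
    return SystemMatrixView(toy_geometry, tiny_volume)


@pytest.fixture(scope="session")
def lyso_table():
    return AttenuationTable.from_material("lyso_like")


@pytest.fixture(scope="session")
def pe_only_table():
    return AttenuationTable.photoelectric_only()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
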