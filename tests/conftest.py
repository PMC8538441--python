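import numpy as np
import pytest

from pttsim.geometry import Material, homogeneous_slab
from pttsim.optics import OpticalProperties


@pytest.fixture(scope="session")
def water_like() -> Material:
    """Soft-tissue-like single material for solver verification."""
    return Material(
        "waterish", OpticalProperties(mu_a=1.0, mu_s=0.0, g=0.0), rho=1000.0, cp=4000.0, k=0.6
    )


@pytest.fixture(scope="session")
def absorber_slab():
    """Pure-absorber slab (mu_a = 1 mm^-1), 10 mm deep, 0.5 mm voxels."""
    mat = Material(
        "absorber", OpticalProperties(mu_a=1.0, mu_s=0.0, g=0.0), rho=1000.0, cp=4000.0, k=0.6
    )
    return homogeneous_slab(mat, extents_mm=(10.0, 10.0, 10.0), voxel_size=0.5)


@pytest.fixture(scope="session")
def skin_coarse():
    """Default skin stack at desk resolution, shared across tests."""
    from pttsim.geometry import build_skin_stack

    return build_skin_stack(voxel_size=0.5, fv=1.0e-6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210)
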