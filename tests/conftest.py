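import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rtcohort import phantom
from rtcohort.geometry import BinaryMask
from rtcohort.rt_model import Grid3D

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    """BinaryMask from a (nz, ny, nx) boolean array on a simple grid."""
    voxels = np.asarray(voxels, bool)
    nz, ny, nx = voxels.shape
    grid = Grid3D(origin=origin, spacing=spacing, shape=(nx, ny, nz))
    return BinaryMask(grid=grid, voxels=voxels)


def random_mask(rng, shape=(10, 10, 10), p=0.2, **kw) -> BinaryMask:
    return make_mask(rng.random(shape) < p, **kw)


@pytest.fixture(scope="session")
def default_case():
    """One phantom case with population-mean organ volumes."""
    spec = phantom.PhantomSpec(heart_volume=800.0, eso_volume=40.0, pbt_volume=45.0)
    return phantom.make_case(spec)


@pytest.fixture(scope="session")
def gradient_case():
    """Phantom with a pure linear dose gradient along x (0.1 Gy/mm)."""
    spec = phantom.PhantomSpec(
        patient_id="PTGRAD",
        heart_volume=800.0,
        dose_model={"kind": "gradient", "gradient": 0.1, "axis": "x"},
    )
    return phantom.make_case(spec)
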