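import numpy as np
import pytest

from tractatlas.core_tensor import ScalarVolume, TensorVolume
from tractatlas.synthetic_data import PhantomSpec, build_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd_tensors(rng, n, scale=3e-4):
    """Random symmetric positive-definite 3x3 tensors with physiological
    eigenvalue magnitudes (~1e-4 to ~3e-3 mm^2/s), shape (n, 3, 3)."""
    A = rng.normal(size=(n, 3, 3))
    return scale * (A @ np.swapaxes(A, -1, -2) + 0.1 * np.eye(3))


def tensor_volume_from(tensors, voxel=2.0):
    """Wrap an (n, 3, 3) stack as an (n, 1, 1) TensorVolume."""
    t = np.asarray(tensors).reshape(-1, 1, 1, 3, 3)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return TensorVolume(t, aff)


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """Quarter-size phantom for expensive registration tests."""
    return build_phantom(PhantomSpec(shape=(32, 32, 32), voxel_size=3.0))


@pytest.fixture
def gaussian_blob():
    """A smooth blob image useful for registration tests."""
    shape = (24, 24, 24)
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    x, y, z = np.indices(shape, dtype=float)
    vals = np.exp(-((x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2) / 30.0)
    vals += 0.5 * np.exp(-((x - 7) ** 2 + (y - 15) ** 2 + (z - 10) ** 2) / 12.0)
    vals += 0.7 * np.exp(-((x - 16) ** 2 + (y - 8) ** 2 + (z - 15) ** 2) / 8.0)
    return ScalarVolume(vals, aff)
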