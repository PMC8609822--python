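import numpy as np
import pytest

from hipclear import HipPhantomSpec, fit_sphere, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def phantom_nocam():
    return generate_phantom(HipPhantomSpec(seed=10))


@pytest.fixture(scope="session")
def phantom_cam():
    return generate_phantom(HipPhantomSpec(seed=12, cam_amplitude=3.0))


@pytest.fixture(scope="session")
def head_fit_nocam(phantom_nocam):
    return fit_sphere(phantom_nocam.head)


@pytest.fixture(scope="session")
def head_fit_cam(phantom_cam):
    return fit_sphere(phantom_cam.head)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
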