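import numpy as np
import pytest

from myomech import Activation, fiber_frame_e3, fitted_params, get_model

MODELS = ("ASE", "GASA", "ASA", "GASAM")
FAMILY = ("GASA", "ASA", "GASAM")


@pytest.fixture(scope="session")
def frame():
    return fiber_frame_e3()


@pytest.fixture(scope="session")
def tetanic():
    return Activation.tetanic()


@pytest.fixture(scope="session")
def passive():
    return Activation.passive()


@pytest.fixture(scope="session", params=MODELS)
def any_model(request):
    return get_model(request.param)


@pytest.fixture(scope="session", params=FAMILY)
def family_model(request):
    return get_model(request.param)


def random_isochoric_F(rng, scale=0.15):
    """A random deformation gradient with unit determinant."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    d = np.linalg.det(F)
    if d <= 0.2:
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        d = np.linalg.det(F)
    return F / np.cbrt(d)


def sqrtm_spd(C):
    w, V = np.linalg.eigh(C)
    return (V * np.sqrt(w)) @ V.T
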