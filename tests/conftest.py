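import numpy as np
import pytest

import foursphere as fs

#: dipole radius used throughout: 1 mm below the brain-CSF interface
RZ = 0.078
P = 1e-7


@pytest.fixture(scope="session")
def model():
    """Standard four-sphere model, skull divisor 20."""
    return fs.default_head_model(20.0)


@pytest.fixture(scope="session")
def homogeneous_model(model):
    """Same radii, all conductivities equal to the brain value."""
    return fs.HeadModel(radii=model.radii, conductivities=(0.33,) * 4)


@pytest.fixture
def radial_dipole():
    return fs.Dipole(position=(0.0, 0.0, RZ), moment=(0.0, 0.0, P))


@pytest.fixture
def tangential_dipole():
    return fs.Dipole(position=(0.0, 0.0, RZ), moment=(0.0, P, 0.0))


@pytest.fixture
def oblique_dipole():
    m = P / np.sqrt(2.0)
    return fs.Dipole(position=(0.0, 0.0, RZ), moment=(0.0, m, m))


@pytest.fixture(scope="session")
def ctrl():
    return fs.SeriesControl()


def rel_diff(a, b, floor=1e-280):
    scale = max(abs(a), abs(b))
    return 0.0 if scale < floor else abs(a - b) / scale
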