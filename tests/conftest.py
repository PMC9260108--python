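import numpy as np
import pytest

from renal_mpmri.geometry import AcquisitionGeometry
from renal_mpmri.kinetics import AIFModel
from renal_mpmri.phantom import PhantomSpec, make_phantom

PAPER_B_VALUES = (25.0, 180.0, 323.0, 508.0)
PAPER_FLIP_ANGLES = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
PAPER_TR_S = 0.039


@pytest.fixture
def small_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry((8.0, 8.0), (8, 8), 1.0, 4)


@pytest.fixture
def aif() -> AIFModel:
    return AIFModel()


@pytest.fixture
def uniform_phantom(small_geometry):
    """A structureless phantom whose maps can be overwritten per test."""

    def build(**overrides):
        spec = PhantomSpec(kidneys=(), vessel=None, lesions=())
        ph = make_phantom(spec, small_geometry)
        ph.maps["pd"][:] = 1.0
        for name, value in overrides.items():
            ph.maps[name][:] = value
        return ph

    return build


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
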