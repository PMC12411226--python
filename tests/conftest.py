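import numpy as np
import pytest

from lietsim.device_config import default_device, default_materials


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def char_device():
    return default_device("characterization")


@pytest.fixture(scope="session")
def sensing_device():
    return default_device("sensing")


@pytest.fixture(scope="session")
def junction_eps():
    """Fixed single-wavelength permittivities (650 nm ballpark) for solver
    unit tests that do not need the material tables."""
    return {
        "glass": 1.52**2 + 0j,
        "air": 1.0 + 0j,
        "Al": -53.7 + 21.2j,
        "Al2O3": 1.76**2 + 0j,
        "Cr": -6.4 + 30.7j,
        "Au": -10.8 + 1.9j,
    }


@pytest.fixture(scope="session")
def planar_junction_layers(junction_eps):
    """Planar junction stack listed from the glass side: Al / Al2O3 / Cr / Au."""
    e = junction_eps
    return [(e["Al"], 25.0), (e["Al2O3"], 5.0), (e["Cr"], 5.0), (e["Au"], 50.0)]


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
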