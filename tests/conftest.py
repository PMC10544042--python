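import numpy as np
import pytest
from hypothesis import settings

from dectspr import physics_core as pc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def basis():
    return pc.build_jh_basis()


@pytest.fixture(scope="session")
def tissues():
    return pc.load_tissues()


@pytest.fixture(scope="session")
def inserts():
    return pc.load_inserts()


@pytest.fixture(scope="session")
def calibration_materials(inserts):
    """Insert set spanning soft tissue and bone, as used for calibration."""
    names = ("adipose", "breast", "water", "muscle", "liver", "bone_200", "bone_800")
    return [pc.water() if n == "water" else inserts[n] for n in names]


@pytest.fixture()
def rng():
    return np.random.default_rng(20230920)
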