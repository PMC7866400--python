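import numpy as np
import pytest
from hypothesis import settings

from thermostruct import synthetic_data as synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def helix12():
    return synth.build_ideal_peptide("A" * 12, phi=-57, psi=-47)


@pytest.fixture(scope="session")
def hairpin():
    return synth.build_antiparallel_hairpin()


@pytest.fixture(scope="session")
def homolog_pair():
    return synth.mini_homolog_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
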