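import numpy as np
import pytest

from rnalandscape import datasets, native_contacts


@pytest.fixture(scope="session")
def hairpin():
    cg, ann = datasets.toy_hairpin()
    return cg, ann


@pytest.fixture(scope="session")
def hairpin_contacts(hairpin):
    cg, _ = hairpin
    return native_contacts(cg)


@pytest.fixture(scope="session")
def riboswitch():
    cg, ann = datasets.synthetic_riboswitch()
    return cg, ann


@pytest.fixture(scope="session")
def riboswitch_contacts(riboswitch):
    cg, _ = riboswitch
    return native_contacts(cg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
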