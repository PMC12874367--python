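import numpy as np
import pytest

from cageconform import (
    detect_topology,
    gen_ideal_cage,
    perceive_bonds,
)


@pytest.fixture(scope="session")
def closed_cage():
    cage = gen_ideal_cage("endo-C", (90.0, 90.0, 90.0, 90.0))
    perceive_bonds(cage)
    return cage


@pytest.fixture(scope="session")
def closed_cage_topology(closed_cage):
    return detect_topology(closed_cage)


@pytest.fixture(scope="session")
def endo_n_cage():
    cage = gen_ideal_cage("endo-N", (90.0, 90.0, 90.0, 90.0))
    perceive_bonds(cage)
    return cage


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
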