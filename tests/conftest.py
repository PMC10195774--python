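import numpy as np
import pytest

from terpued.geometry import MolecularGeometry
from terpued.surrogate import SurrogateParams, build_terpinene, generate_ensemble


@pytest.fixture(scope="session")
def reactant():
    return build_terpinene(1)


@pytest.fixture(scope="session")
def reactant_rotamers():
    return [build_terpinene(rot) for rot in (1, 2, 3)]


@pytest.fixture(scope="session")
def small_ensemble():
    """30-trajectory surrogate ensemble shared by the fast tests."""
    return generate_ensemble(SurrogateParams(n_traj=30, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return q, t


def toy_geometry(elements, positions):
    return MolecularGeometry(tuple(elements), np.asarray(positions, float))
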