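import numpy as np
import pytest

from gafrag import fixtures, molgraph
from gafrag.forcefield import AdditiveBackend, BondedToyBackend


@pytest.fixture(scope="session")
def graphs():
    """Annotated molecular graphs of the named fixtures, built once."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = molgraph.from_structure(
                fixtures.build_named_molecule(name))
        return cache[name]

    return get


@pytest.fixture()
def toy_backend():
    return BondedToyBackend()


@pytest.fixture()
def additive_backend():
    return AdditiveBackend()


@pytest.fixture()
def random_rotation():
    """A fixed, seeded proper rotation matrix + translation."""
    rng = np.random.default_rng(42)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=5.0, size=3)
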