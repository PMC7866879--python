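import numpy as np
import pytest

from varimpact.structure_io import Atom, ResidueKey, Structure
from varimpact.synthetic_data import make_structure


@pytest.fixture
def helix():
    return make_structure(12, "helix", seed=0)


@pytest.fixture
def linear_ca_chain():
    """Five CA-only residues on a line with 3.8 Å spacing."""
    atoms, keys = [], []
    for i in range(5):
        atoms.append(Atom(serial=i + 1, name="CA", element="C", coords=[3.8 * i, 0, 0]))
        keys.append(ResidueKey("A", i + 1, "", "GLY"))
    return Structure(atoms, keys)


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
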