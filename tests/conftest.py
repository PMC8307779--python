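import numpy as np
import pytest

from confens.ensembles import ConformationEnsemble, Topology


@pytest.fixture
def ca_topology():
    """Five-residue Cα-only topology (numbering 689–693)."""
    return Topology(
        residue_numbers=np.arange(689, 694),
        residue_names=["ALA"] * 5,
        atom_names=["CA"] * 5,
        elements=["C"] * 5,
        atom_residue_index=np.arange(5),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ca_ensemble(coords, topology=None, label="test"):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if topology is None:
        topology = Topology(
            residue_numbers=np.arange(689, 689 + n_atoms),
            residue_names=["ALA"] * n_atoms,
            atom_names=["CA"] * n_atoms,
            elements=["C"] * n_atoms,
            atom_residue_index=np.arange(n_atoms),
        )
    return ConformationEnsemble(topology, coords, label=label)


@pytest.fixture
def random_ensemble(rng):
    """Ten Cα atoms, twenty random frames."""
    return make_ca_ensemble(rng.normal(scale=5.0, size=(20, 10, 3)))


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
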