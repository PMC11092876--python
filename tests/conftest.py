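import numpy as np
import pytest

from molflow.fixtures import FixtureGrammar, generate_molecules
from molflow.mol_types import CategoryCodebook, MoleculeGraph, to_onehot


@pytest.fixture(scope="session")
def codebook():
    return CategoryCodebook()


@pytest.fixture(scope="session")
def water(codebook):
    """Water: O at origin, two H, two single bonds. Pair rows: (0,1), (0,2), (1,2)."""
    positions = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    atom_types = to_onehot(
        np.array([codebook.element_index("O"), codebook.element_index("H"),
                  codebook.element_index("H")]), codebook.n_a)
    charges = to_onehot(np.full(3, codebook.charge_index(0)), codebook.n_c)
    single, none = codebook.bond_index("single"), codebook.bond_index("none")
    bonds = to_onehot(np.array([single, single, none]), codebook.n_e)
    return MoleculeGraph(positions, atom_types, charges, bonds, codebook=codebook)


@pytest.fixture(scope="session")
def fixture_set():
    return generate_molecules(FixtureGrammar(max_heavy=4), 30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_graph(n, codebook, rng, simplex=True):
    """Random molecule graph; categorical rows on the simplex (or one-hot)."""
    from molflow.mol_types import n_pairs

    pos = rng.normal(size=(n, 3))
    pos -= pos.mean(axis=0)
    if simplex:
        a = rng.dirichlet(np.ones(codebook.n_a), size=n)
        c = rng.dirichlet(np.ones(codebook.n_c), size=n)
        e = rng.dirichlet(np.ones(codebook.n_e), size=n_pairs(n))
    else:
        a = to_onehot(rng.integers(0, codebook.n_a, size=n), codebook.n_a)
        c = to_onehot(rng.integers(0, codebook.n_c, size=n), codebook.n_c)
        e = to_onehot(rng.integers(0, codebook.n_e, size=n_pairs(n)), codebook.n_e)
    return MoleculeGraph(pos, a, c, e, codebook=codebook)
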