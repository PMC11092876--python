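"""Download-free synthetic fixtures: small valence-respecting molecules and
toy categorical tasks.

Molecules are grown as random trees over heavy atoms (bond orders chosen
within both endpoints' remaining valence), optionally closed into rings, then
capped with hydrogens so every declared valence is met exactly. Coordinates
come from minimizing a harmonic bond-length plus soft-repulsion objective
from a random start — deliberately minimal geometry, sufficient for
sanitization and force-field evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mol_types import CategoryCodebook, MoleculeGraph, n_pairs, pair_indices, to_onehot

#: target bond lengths (Angstrom) per order used by the harmonic embedder
_BOND_LENGTH = {1: 1.5, 2: 1.33, 3: 1.2}
_REPULSION_RADIUS = 2.2


@dataclass(frozen=True)
class FixtureGrammar:
    """Element palette with exact valences; hydrogens cap open valences."""

    valences: dict[str, int] = field(
        default_factory=lambda: {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1}
    )
    max_heavy: int = 5
    max_bond_order: int = 3
    ring_closure_prob: float = 0.0
    charges: tuple[int, ...] = (-1, 0, 1)

    def __post_init__(self):
        if not any(v == 1 for v in self.valences.values()):
            raise ValueError("grammar needs a valence-1 capping element")
        if "H" not in self.valences:
            raise ValueError("grammar must include H as the capper")

    def codebook(self) -> CategoryCodebook:
        return CategoryCodebook(elements=tuple(self.valences), charges=self.charges)


def _grow_topology(grammar: FixtureGrammar, rng: np.random.Generator):
    """Random tree over heavy atoms plus H caps; returns (symbols, bonds).

    bonds is a list of (i, j, order) with i < j. Every atom ends with its
    declared valence exactly saturated.
    """
    heavy = [s for s, v in grammar.valences.items() if s != "H" and v >= 1]
    n_heavy = int(rng.integers(1, grammar.max_heavy + 1))
    symbols = [str(rng.choice(heavy)) for _ in range(n_heavy)]
    remaining = [grammar.valences[s] for s in symbols]
    bonds: list[tuple[int, int, int]] = []

    for j in range(1, n_heavy):
        parents = [i for i in range(j) if remaining[i] >= 1]
        if not parents:
            symbols = symbols[:j]
            remaining = remaining[:j]
            break
        i = int(rng.choice(parents))
        max_order = min(remaining[i], remaining[j], grammar.max_bond_order)
        # bias strongly toward single bonds
        orders = list(range(1, max_order + 1))
        weights = np.array([4.0 ** (-(o - 1)) for o in orders])
        order = int(rng.choice(orders, p=weights / weights.sum()))
        bonds.append((i, j, order))
        remaining[i] -= order
        remaining[j] -= order

    if grammar.ring_closure_prob > 0 and len(symbols) >= 3:
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        open_atoms = [i for i in range(len(symbols)) if remaining[i] >= 1]
        rng.shuffle(open_atoms)
        for a in range(len(open_atoms)):
            for b in range(a + 1, len(open_atoms)):
                i, j = sorted((open_atoms[a], open_atoms[b]))
                if (i, j) not in bonded and rng.random() < grammar.ring_closure_prob:
                    if remaining[i] >= 1 and remaining[j] >= 1:
                        bonds.append((i, j, 1))
                        bonded.add((i, j))
                        remaining[i] -= 1
                        remaining[j] -= 1

    n_heavy = len(symbols)
    for i in range(n_heavy):
        for _ in range(remaining[i]):
            symbols.append("H")
            bonds.append((i, len(symbols) - 1, 1))
    return symbols, bonds


def _embed(symbols: list[str], bonds, rng: np.random.Generator) -> np.ndarray:
    """Coordinates from a harmonic bond / soft repulsion objective."""
    n = len(symbols)
    x0 = rng.normal(scale=1.5, size=(n, 3))
    if n == 1:
        return np.zeros((1, 3))
    bond_idx = np.array([(i, j) for i, j, _ in bonds], dtype=np.int64)
    bond_len = np.array([_BOND_LENGTH[o] for _, _, o in bonds])
    bonded = {(i, j) for i, j, _ in bonds}
    iu, ju = pair_indices(n)
    nb_mask = np.array([(i, j) not in bonded for i, j in zip(iu, ju)])
    nb_i, nb_j = iu[nb_mask], ju[nb_mask]

    def objective(flat):
        x = flat.reshape(n, 3)
        grad = np.zeros_like(x)
        d = x[bond_idx[:, 0]] - x[bond_idx[:, 1]]
        r = np.linalg.norm(d, axis=1) + 1e-12
        diff = r - bond_len
        f = 10.0 * (diff**2).sum()
        g = 20.0 * (diff / r)[:, None] * d
        np.add.at(grad, bond_idx[:, 0], g)
        np.add.at(grad, bond_idx[:, 1], -g)
        if nb_i.size:
            d2 = x[nb_i] - x[nb_j]
            r2 = np.linalg.norm(d2, axis=1) + 1e-12
            pen = np.maximum(_REPULSION_RADIUS - r2, 0.0)
            f += (pen**2).sum()
            g2 = (-2.0 * pen / r2)[:, None] * d2
            np.add.at(grad, nb_i, g2)
            np.add.at(grad, nb_j, -g2)
        return f, grad.ravel()

    res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    x = res.x.reshape(n, 3)
    return x - x.mean(axis=0)


def topology_to_graph(
    symbols: list[str], bonds, positions: np.ndarray, codebook: CategoryCodebook
) -> MoleculeGraph:
    n = len(symbols)
    elem = np.array([codebook.element_index(s) for s in symbols])
    charge = np.full(n, codebook.charge_index(0))
    order_to_kind = {1: "single", 2: "double", 3: "triple"}
    bond_labels = np.full(n_pairs(n), codebook.bond_index("none"), dtype=np.int64)
    from .mol_types import pair_row_lookup

    lookup = pair_row_lookup(n) if n > 1 else None
    for i, j, o in bonds:
        bond_labels[lookup[i, j]] = codebook.bond_index(order_to_kind[o])
    return MoleculeGraph(
        positions=positions,
        atom_types=to_onehot(elem, codebook.n_a),
        charges=to_onehot(charge, codebook.n_c),
        bonds=to_onehot(bond_labels, codebook.n_e),
        codebook=codebook,
    )


def generate_molecules(
    grammar: FixtureGrammar, count: int, seed: int = 0
) -> list[MoleculeGraph]:
    """Generate ``count`` valence-exact fixture molecules (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    codebook = grammar.codebook()
    out = []
    for _ in range(count):
        symbols, bonds = _grow_topology(grammar, rng)
        positions = _embed(symbols, bonds, rng)
        out.append(topology_to_graph(symbols, bonds, positions, codebook))
    return out


def make_toy_task(
    d: int, q, n: int, seed: int = 0
) -> np.ndarray:
    """n one-hot rows on the d-simplex with class probabilities q."""
    q = np.asarray(q, dtype=np.float64)
    if q.size != d or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("q must be a probability vector of length d")
    rng = np.random.default_rng(seed)
    labels = rng.choice(d, size=n, p=q)
    return to_onehot(labels, d)


__all__ = ["FixtureGrammar", "generate_molecules", "make_toy_task", "topology_to_graph"]
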