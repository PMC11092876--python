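"""Full molecule priors: centered Gaussian positions plus categorical priors.

The prior over a molecule factorizes over atoms and atom pairs: positions are
i.i.d. standard normal, then centered so prior (like data) lives in the
center-of-mass-free subspace; atom type, charge and bond-order rows are drawn
independently from their per-modality categorical priors; the atom count is
drawn from an empirical histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mol_types import CategoryCodebook, MoleculeGraph, n_pairs, to_onehot
from .simplex import CategoricalPriorSpec, blur_rows, sample_prior


@dataclass(frozen=True)
class MoleculePriorSpec:
    atom_type: CategoricalPriorSpec = field(default_factory=CategoricalPriorSpec)
    charge: CategoricalPriorSpec = field(default_factory=CategoricalPriorSpec)
    bond: CategoricalPriorSpec = field(default_factory=CategoricalPriorSpec)
    atom_count_hist: dict[int, float] | None = None
    #: joint (element, charge) marginal for the marginal-simplex family,
    #: shape (n_a, n_c); sampled jointly then split into the two one-hot rows.
    joint_ac: np.ndarray | None = None

    def __post_init__(self):
        if self.atom_count_hist is not None:
            probs = np.array(list(self.atom_count_hist.values()), dtype=np.float64)
            if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-8 or np.any(probs < 0):
                raise ValueError("atom-count histogram must be a nonempty distribution")
            if any(int(n) < 1 for n in self.atom_count_hist):
                raise ValueError("atom-count histogram must support N >= 1")


def atom_count_histogram(mols: list[MoleculeGraph]) -> dict[int, float]:
    """Empirical distribution of atom counts in a reference set."""
    if not mols:
        raise ValueError("empty reference set")
    counts: dict[int, float] = {}
    for g in mols:
        counts[g.n_atoms] = counts.get(g.n_atoms, 0.0) + 1.0
    total = sum(counts.values())
    return {n: c / total for n, c in sorted(counts.items())}


def categorical_marginals(mols: list[MoleculeGraph], codebook: CategoryCodebook):
    """Empirical marginals over (element, charge) jointly and bond orders."""
    if not mols:
        raise ValueError("empty reference set")
    joint_ac = np.zeros((codebook.n_a, codebook.n_c))
    bond_q = np.zeros(codebook.n_e)
    for g in mols:
        for ei, ci in zip(g.element_labels(), g.charge_labels()):
            joint_ac[ei, ci] += 1.0
        for bi in g.bond_labels():
            bond_q[bi] += 1.0
    return joint_ac / joint_ac.sum(), bond_q / bond_q.sum()


def marginal_prior_spec(
    mols: list[MoleculeGraph],
    codebook: CategoryCodebook,
    blur_sigma: float = 0.15,
) -> MoleculePriorSpec:
    """Marginal-simplex prior whose q vectors come from a reference set."""
    joint_ac, bond_q = categorical_marginals(mols, codebook)
    return MoleculePriorSpec(
        atom_type=CategoricalPriorSpec(
            "marginal-simplex", blur_sigma, tuple(joint_ac.sum(axis=1))
        ),
        charge=CategoricalPriorSpec("marginal-simplex", blur_sigma, tuple(joint_ac.sum(axis=0))),
        bond=CategoricalPriorSpec("marginal-simplex", blur_sigma, tuple(bond_q)),
        atom_count_hist=atom_count_histogram(mols),
        joint_ac=joint_ac,
    )


def sample_atom_count(hist: dict[int, float], rng: np.random.Generator) -> int:
    """Draw an atom count from the empirical histogram."""
    if not hist:
        raise ValueError("empty atom-count histogram")
    ns = np.array(list(hist.keys()), dtype=np.int64)
    ps = np.array(list(hist.values()), dtype=np.float64)
    return int(rng.choice(ns, p=ps / ps.sum()))


def sample_molecule_prior(
    spec: MoleculePriorSpec,
    n_atoms: int,
    codebook: CategoryCodebook,
    rng: np.random.Generator,
) -> MoleculeGraph:
    """Draw one prior molecule graph with the given atom count.

    Positions are standard normal then centered to zero centroid. When the
    atom-type family is marginal-simplex and a joint (element, charge) table
    is present, atom type and charge are drawn jointly from it and split into
    the two one-hot rows (each then blurred independently).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    pos = rng.normal(size=(n_atoms, 3))
    pos -= pos.mean(axis=0, keepdims=True)

    if spec.atom_type.family == "marginal-simplex" and spec.joint_ac is not None:
        flat = spec.joint_ac.ravel()
        idx = rng.choice(flat.size, size=n_atoms, p=flat / flat.sum())
        ei, ci = np.unravel_index(idx, spec.joint_ac.shape)
        atom_types = blur_rows(to_onehot(ei, codebook.n_a), spec.atom_type.blur_sigma, rng)
        charges = blur_rows(to_onehot(ci, codebook.n_c), spec.charge.blur_sigma, rng)
    else:
        atom_types = sample_prior(spec.atom_type, n_atoms, codebook.n_a, rng)
        charges = sample_prior(spec.charge, n_atoms, codebook.n_c, rng)
    bonds = sample_prior(spec.bond, n_pairs(n_atoms), codebook.n_e, rng)
    return MoleculeGraph(pos, atom_types, charges, bonds, codebook=codebook)


__all__ = [
    "MoleculePriorSpec",
    "atom_count_histogram",
    "categorical_marginals",
    "marginal_prior_spec",
    "sample_atom_count",
    "sample_molecule_prior",
]
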