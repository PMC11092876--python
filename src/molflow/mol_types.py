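"""Molecular data model: fully connected attributed graphs and SDF/XYZ I/O.

A molecule is a tuple (positions, atom types, formal charges, bond orders).
Categorical attributes live on probability simplices; at data endpoints every
categorical row is one-hot. Bond orders are stored once per unordered atom
pair, in the row order produced by ``numpy.triu_indices(N, k=1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

#: Fixed bond-kind axis order. "none" means the pair is not bonded.
BOND_KINDS = ("none", "single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_BOND_FROM_RDKIT = {v: k for k, v in _RDKIT_BOND.items()}

#: Numeric valence contribution per bond kind (aromatic counts 1.5).
BOND_ORDER_VALUE = {"none": 0.0, "single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


@dataclass(frozen=True)
class CategoryCodebook:
    """Fixed, ordered category axes for atom types, charges and bond kinds."""

    elements: tuple[str, ...] = ("H", "C", "N", "O", "F")
    charges: tuple[int, ...] = (-1, 0, 1)
    bond_orders: tuple[str, ...] = BOND_KINDS

    def __post_init__(self):
        for name in ("elements", "charges", "bond_orders"):
            vals = getattr(self, name)
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate entries in codebook field {name!r}")

    @property
    def n_a(self) -> int:
        return len(self.elements)

    @property
    def n_c(self) -> int:
        return len(self.charges)

    @property
    def n_e(self) -> int:
        return len(self.bond_orders)

    def element_index(self, symbol: str) -> int:
        return self.elements.index(symbol)

    def charge_index(self, charge: int) -> int:
        return self.charges.index(charge)

    def bond_index(self, kind: str) -> int:
        return self.bond_orders.index(kind)

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "charges": list(self.charges),
            "bond_orders": list(self.bond_orders),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryCodebook":
        return cls(tuple(d["elements"]), tuple(d["charges"]), tuple(d["bond_orders"]))


def pair_indices(n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    """Row order of the unordered-pair axis: (i, j) with i < j, lexicographic."""
    return np.triu_indices(n_atoms, k=1)


def n_pairs(n_atoms: int) -> int:
    return (n_atoms * n_atoms - n_atoms) // 2


def pair_row_lookup(n_atoms: int) -> np.ndarray:
    """(N, N) symmetric table mapping an atom pair to its bond-row index."""
    table = np.full((n_atoms, n_atoms), -1, dtype=np.int64)
    iu, ju = pair_indices(n_atoms)
    table[iu, ju] = np.arange(iu.size)
    table[ju, iu] = table[iu, ju]
    return table


@dataclass
class MoleculeGraph:
    """Fully connected molecular graph with per-modality feature matrices.

    positions : (N, 3) Cartesian coordinates in Angstrom
    atom_types : (N, n_a) rows on the simplex (one-hot at data endpoints)
    charges : (N, n_c) rows on the simplex
    bonds : ((N^2-N)/2, n_e) one row per unordered atom pair
    """

    positions: np.ndarray
    atom_types: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    codebook: CategoryCodebook = field(default_factory=CategoryCodebook)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.atom_types = np.asarray(self.atom_types, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.float64)
        n = self.n_atoms
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        if self.charges.shape[0] != n:
            raise ValueError("charges row count must equal atom count")
        if self.bonds.shape[0] != n_pairs(n):
            raise ValueError(
                f"bonds must have (N^2-N)/2 = {n_pairs(n)} rows, got {self.bonds.shape[0]}"
            )

    @property
    def n_atoms(self) -> int:
        return self.atom_types.shape[0]

    def copy(self) -> "MoleculeGraph":
        return replace(
            self,
            positions=self.positions.copy(),
            atom_types=self.atom_types.copy(),
            charges=self.charges.copy(),
            bonds=self.bonds.copy(),
        )

    def centered(self) -> "MoleculeGraph":
        out = self.copy()
        out.positions = out.positions - out.positions.mean(axis=0, keepdims=True)
        return out

    # convenient decoded views -------------------------------------------------
    def element_labels(self) -> np.ndarray:
        return self.atom_types.argmax(axis=1)

    def charge_labels(self) -> np.ndarray:
        return self.charges.argmax(axis=1)

    def bond_labels(self) -> np.ndarray:
        return self.bonds.argmax(axis=1)


def to_onehot(labels: np.ndarray, d: int) -> np.ndarray:
    """One-hot encode integer labels as rows on the d-simplex."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1:
        labels = labels.ravel()
    if labels.size and (labels.min() < 0 or labels.max() >= d):
        raise ValueError(f"labels must lie in [0, {d}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    out = np.zeros((labels.size, d), dtype=np.float64)
    out[np.arange(labels.size), labels] = 1.0
    return out


def from_rdkit(mol: Chem.Mol, codebook: CategoryCodebook) -> MoleculeGraph:
    """Convert an RDKit molecule (3D conformer, explicit Hs) to a graph."""
    n = mol.GetNumAtoms()
    conf = mol.GetConformer()
    positions = np.array(conf.GetPositions(), dtype=np.float64)

    elem_labels = np.empty(n, dtype=np.int64)
    charge_labels = np.empty(n, dtype=np.int64)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in codebook.elements:
            raise KeyError(f"element {sym!r} not in codebook")
        chg = atom.GetFormalCharge()
        if chg not in codebook.charges:
            raise KeyError(f"formal charge {chg} not in codebook")
        elem_labels[atom.GetIdx()] = codebook.element_index(sym)
        charge_labels[atom.GetIdx()] = codebook.charge_index(chg)

    lookup = pair_row_lookup(n)
    bond_labels = np.full(n_pairs(n), codebook.bond_index("none"), dtype=np.int64)
    for bond in mol.GetBonds():
        kind = _BOND_FROM_RDKIT.get(bond.GetBondType())
        if kind is None or kind not in codebook.bond_orders:
            raise KeyError(f"bond type {bond.GetBondType()} not in codebook")
        bond_labels[lookup[bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()]] = codebook.bond_index(kind)

    return MoleculeGraph(
        positions=positions,
        atom_types=to_onehot(elem_labels, codebook.n_a),
        charges=to_onehot(charge_labels, codebook.n_c),
        bonds=to_onehot(bond_labels, codebook.n_e),
        codebook=codebook,
    )


def decode_molecule(g: MoleculeGraph, codebook: CategoryCodebook | None = None) -> Chem.Mol:
    """Resolve categorical rows by argmax and build an RDKit molecule.

    Argmax ties break toward the lowest category index (numpy argmax).
    Pairs whose argmax bond kind is "none" are omitted. The result is NOT
    sanitized; downstream sanitization decides validity.
    """
    codebook = codebook or g.codebook
    rw = Chem.RWMol()
    for elem_idx, chg_idx in zip(g.element_labels(), g.charge_labels()):
        atom = Chem.Atom(codebook.elements[elem_idx])
        atom.SetFormalCharge(int(codebook.charges[chg_idx]))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    iu, ju = pair_indices(g.n_atoms)
    for i, j, lbl in zip(iu, ju, g.bond_labels()):
        kind = codebook.bond_orders[lbl]
        if kind != "none":
            rw.AddBond(int(i), int(j), _RDKIT_BOND[kind])
    mol = rw.GetMol()
    conf = Chem.Conformer(g.n_atoms)
    for idx, (x, y, z) in enumerate(g.positions):
        conf.SetAtomPosition(idx, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    return mol


def read_sdf(path, codebook: CategoryCodebook | None = None) -> list[MoleculeGraph]:
    """Read a V2000/V3000 SDF into graphs; skip records outside the codebook.

    Records containing an element, charge, or bond kind absent from the
    codebook are skipped with a logged reason. An unparsable file raises.
    """
    codebook = codebook or CategoryCodebook()
    import os

    if os.path.getsize(path) == 0 or not open(path).read().strip():
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[MoleculeGraph] = []
    n_skipped = 0
    for idx, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.warning("record %d: unparsable, skipped", idx)
            continue
        try:
            out.append(from_rdkit(mol, codebook))
        except KeyError as exc:
            n_skipped += 1
            logger.warning("record %d rejected: %s", idx, exc)
    if n_skipped:
        logger.info("read_sdf: skipped %d of %d records", n_skipped, n_skipped + len(out))
    return out


def write_sdf(mols: list[MoleculeGraph], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for g in mols:
        writer.write(decode_molecule(g))
    writer.close()


def write_xyz(g: MoleculeGraph, path) -> None:
    """Positions-only XYZ dump for debugging."""
    codebook = g.codebook
    lines = [str(g.n_atoms), "molflow"]
    for elem_idx, (x, y, z) in zip(g.element_labels(), g.positions):
        lines.append(f"{codebook.elements[elem_idx]} {x:.6f} {y:.6f} {z:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def sanitized_copy(g: MoleculeGraph) -> Chem.Mol | None:
    """Decode and sanitize with default settings; None if sanitization fails."""
    mol = decode_molecule(g)
    try:
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


__all__ = [
    "BOND_KINDS",
    "BOND_ORDER_VALUE",
    "CategoryCodebook",
    "MoleculeGraph",
    "decode_molecule",
    "from_rdkit",
    "n_pairs",
    "pair_indices",
    "pair_row_lookup",
    "read_sdf",
    "sanitized_copy",
    "to_onehot",
    "write_sdf",
    "write_xyz",
]
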