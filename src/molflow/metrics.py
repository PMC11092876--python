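"""Molecule-quality metrics: valency stability, validity, JS energy divergence.

An atom is stable when the sum of its incident bond orders (aromatic = 1.5)
is a valence observed in the reference set for its (element, formal charge);
a molecule is stable when all its atoms are. Validity is RDKit default
sanitization. Geometry quality is measured as the Jensen-Shannon divergence
between MMFF94 potential-energy histograms of generated vs reference valid
molecules, on shared bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import AllChem
from scipy.special import rel_entr

from .mol_types import BOND_ORDER_VALUE, MoleculeGraph, pair_indices, sanitized_copy

logger = logging.getLogger(__name__)


@dataclass
class ValencyTable:
    """(element symbol, formal charge) -> set of allowed total valences."""

    allowed: dict[tuple[str, int], set[float]] = field(default_factory=dict)

    def add(self, element: str, charge: int, valence: float) -> None:
        self.allowed.setdefault((element, charge), set()).add(round(float(valence), 6))

    def is_stable(self, element: str, charge: int, valence: float) -> bool:
        vals = self.allowed.get((element, charge))
        if vals is None:
            logger.debug("no reference valences for (%s, %+d)", element, charge)
            return False
        return round(float(valence), 6) in vals

    def __len__(self) -> int:
        return len(self.allowed)


def atom_valences(g: MoleculeGraph) -> np.ndarray:
    """Per-atom sum of incident bond-order values (aromatic counts 1.5)."""
    order_values = np.array([BOND_ORDER_VALUE[k] for k in g.codebook.bond_orders])
    vals = np.zeros(g.n_atoms)
    if g.bonds.shape[0]:
        iu, ju = pair_indices(g.n_atoms)
        per_pair = order_values[g.bond_labels()]
        np.add.at(vals, iu, per_pair)
        np.add.at(vals, ju, per_pair)
    return vals


def build_valency_table(reference: list[MoleculeGraph]) -> ValencyTable:
    """Record every (element, charge, valence) triple seen in the reference."""
    if not reference:
        raise ValueError("empty reference set")
    table = ValencyTable()
    for g in reference:
        vals = atom_valences(g)
        for ei, ci, v in zip(g.element_labels(), g.charge_labels(), vals):
            table.add(g.codebook.elements[ei], g.codebook.charges[ci], v)
    return table


def stability(mols: list[MoleculeGraph], table: ValencyTable) -> tuple[float, float]:
    """(percent atoms stable, percent molecules stable) over the set."""
    n_atoms = 0
    n_atoms_stable = 0
    n_mols_stable = 0
    for g in mols:
        vals = atom_valences(g)
        flags = [
            table.is_stable(g.codebook.elements[ei], g.codebook.charges[ci], v)
            for ei, ci, v in zip(g.element_labels(), g.charge_labels(), vals)
        ]
        n_atoms += len(flags)
        n_atoms_stable += sum(flags)
        n_mols_stable += all(flags)
    if not mols:
        return 0.0, 0.0
    return 100.0 * n_atoms_stable / n_atoms, 100.0 * n_mols_stable / len(mols)


def validity(mols: list[MoleculeGraph]) -> float:
    """Percent of molecules passing RDKit default sanitization (0.0 if empty)."""
    if not mols:
        logger.warning("validity called on an empty set (n=0)")
        return 0.0
    n_valid = sum(sanitized_copy(g) is not None for g in mols)
    return 100.0 * n_valid / len(mols)


def mmff_energies(mols: list[MoleculeGraph]) -> np.ndarray:
    """MMFF94 potential energies of the valid (sanitizable) molecules only."""
    energies = []
    for g in mols:
        mol = sanitized_copy(g)
        if mol is None:
            continue
        try:
            props = AllChem.MMFFGetMoleculeProperties(mol)
            if props is None:
                continue
            ff = AllChem.MMFFGetMoleculeForceField(mol, props)
            if ff is None:
                continue
            energies.append(ff.CalcEnergy())
        except Exception:  # missing parameters etc.
            continue
    return np.asarray(energies, dtype=np.float64)


def js_divergence(p: np.ndarray, q: np.ndarray, base: str = "nats") -> float:
    """Jensen-Shannon divergence of two histograms (normalized internally)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    js = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(js / np.log(2.0)) if base == "bits" else float(js)


def shared_bins(pooled: np.ndarray, min_bins: int = 20) -> np.ndarray:
    """Freedman-Diaconis binning on the pooled sample, at least ``min_bins``."""
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        return np.linspace(lo - 0.5, hi + 0.5, min_bins + 1)
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
    n_bins = min_bins if width <= 0 else max(min_bins, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def js_energy_divergence(
    sample_mols: list[MoleculeGraph],
    reference_mols: list[MoleculeGraph],
    base: str = "nats",
    min_bins: int = 20,
) -> float:
    """JS divergence of MMFF energy histograms, valid molecules only."""
    e_s = mmff_energies(sample_mols)
    e_r = mmff_energies(reference_mols)
    if e_s.size == 0 or e_r.size == 0:
        raise ValueError("no valid molecules with MMFF energies in one of the sets")
    bins = shared_bins(np.concatenate([e_s, e_r]), min_bins=min_bins)
    h_s, _ = np.histogram(e_s, bins=bins)
    h_r, _ = np.histogram(e_r, bins=bins)
    return js_divergence(h_s, h_r, base=base)


@dataclass
class EvalReport:
    atoms_stable_pct: float
    mols_stable_pct: float
    mols_valid_pct: float
    js_energy: float | None
    n_molecules: int
    ci95: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "atoms_stable_pct": self.atoms_stable_pct,
            "mols_stable_pct": self.mols_stable_pct,
            "mols_valid_pct": self.mols_valid_pct,
            "js_energy": self.js_energy,
            "n_molecules": self.n_molecules,
            "ci95": self.ci95,
        }


def evaluate(
    mols: list[MoleculeGraph],
    reference: list[MoleculeGraph],
    table: ValencyTable | None = None,
) -> EvalReport:
    """Full metric battery for a generated set against a reference set."""
    table = table or build_valency_table(reference)
    atoms_pct, mols_pct = stability(mols, table)
    valid_pct = validity(mols)
    try:
        js = js_energy_divergence(mols, reference)
    except ValueError:
        js = None
    return EvalReport(atoms_pct, mols_pct, valid_pct, js, len(mols))


def evaluate_repeated(sampler_fn, reference, n_repeats: int = 5) -> dict:
    """Repeat sampling+evaluation; mean with normal-approximation 95% CIs.

    ``sampler_fn(repeat_index)`` must return a list of molecules.
    """
    table = build_valency_table(reference)
    rows = [evaluate(sampler_fn(i), reference, table) for i in range(n_repeats)]
    out = {}
    for key in ("atoms_stable_pct", "mols_stable_pct", "mols_valid_pct", "js_energy"):
        vals = np.array([getattr(r, key) for r in rows if getattr(r, key) is not None])
        if vals.size == 0:
            out[key] = {"mean": None, "ci95": None}
            continue
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        out[key] = {"mean": float(vals.mean()), "ci95": float(1.96 * sem)}
    out["n_repeats"] = n_repeats
    return out


__all__ = [
    "EvalReport",
    "ValencyTable",
    "atom_valences",
    "build_valency_table",
    "evaluate",
    "evaluate_repeated",
    "js_divergence",
    "js_energy_divergence",
    "mmff_energies",
    "shared_bins",
    "stability",
    "validity",
]
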