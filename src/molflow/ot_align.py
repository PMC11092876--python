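"""Training-time alignment of prior and data point clouds.

Finds the atom permutation (linear assignment on squared distances) and the
proper rigid rotation (Kabsch) that minimize the squared distance between a
prior cloud and its paired data cloud, by alternating the two sub-solvers
from several random rotation restarts. The permutation and rotation are
applied to the PRIOR sample only; categorical rows ride along via reindexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .flows import ConditionalPair
from .mol_types import MoleculeGraph, pair_indices, pair_row_lookup


@dataclass(frozen=True)
class AlignmentResult:
    """permutation, proper rotation (det +1) and final sum of squared residuals.

    The aligned prior is ``(x0[permutation]) @ rotation.T``.
    """

    permutation: np.ndarray
    rotation: np.ndarray
    cost: float

    def __post_init__(self):
        n = self.permutation.size
        if sorted(self.permutation.tolist()) != list(range(n)):
            raise ValueError("permutation must be a bijection on [N]")
        r = self.rotation
        if not (np.allclose(r.T @ r, np.eye(3), atol=1e-8) and np.linalg.det(r) > 0):
            raise ValueError("rotation must be proper orthogonal")


def kabsch(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x1 - x0 @ R.T||^2 for centered clouds."""
    with warnings.catch_warnings():
        # collinear / planar clouds trigger a uniqueness warning; any optimal
        # rotation is acceptable here
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(x1, x0)
    return rot.as_matrix()


def _assign(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Permutation perm with x0[perm[i]] matched to x1[i]."""
    d2 = ((x1[:, None, :] - x0[None, :, :]) ** 2).sum(axis=-1)
    _, cols = linear_sum_assignment(d2)
    return cols


def _cost(x0p: np.ndarray, r: np.ndarray, x1: np.ndarray) -> float:
    return float(((x0p @ r.T - x1) ** 2).sum())


def align_pair(
    x0: np.ndarray,
    x1: np.ndarray,
    max_rounds: int = 10,
    n_restarts: int = 100,
    assignment_first: bool = True,
    rng: np.random.Generator | None = None,
) -> AlignmentResult:
    """Jointly optimize permutation and rotation of x0 onto x1.

    Alternates linear assignment and Kabsch superposition until the cost stops
    decreasing (change < 1e-10) or ``max_rounds`` is hit, restarting from
    ``n_restarts`` random proper rotations (plus the identity) and keeping the
    best. ``assignment_first=False`` solves the rotation before the first
    assignment in each restart. Non-centered inputs are centered with a
    warning.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    x1 = np.asarray(x1, dtype=np.float64)
    if x0.shape != x1.shape or x0.ndim != 2 or x0.shape[1] != 3:
        raise ValueError(f"expected matching (N, 3) clouds, got {x0.shape} and {x1.shape}")
    for name, x in (("x0", x0), ("x1", x1)):
        if np.abs(x.mean(axis=0)).max() > 1e-6:
            warnings.warn(f"{name} is not centered; centering internally", stacklevel=2)
    x0 = x0 - x0.mean(axis=0)
    x1 = x1 - x1.mean(axis=0)
    rng = rng if rng is not None else np.random.default_rng(0)
    n = x0.shape[0]

    starts = [np.eye(3)] + [Rotation.random(random_state=rng).as_matrix() for _ in range(n_restarts)]
    best = None
    for r0 in starts:
        r = r0
        perm = np.arange(n)
        if not assignment_first:
            r = kabsch(x0, x1) @ r0  # rotation refined before first assignment
        prev = np.inf
        for _ in range(max_rounds):
            perm = _assign(x0 @ r.T, x1)
            r = kabsch(x0[perm], x1)
            c = _cost(x0[perm], r, x1)
            if prev - c < 1e-10:
                break
            prev = c
        c = _cost(x0[perm], r, x1)
        if best is None or c < best[2]:
            best = (perm, r, c)
    perm, r, c = best
    return AlignmentResult(permutation=perm, rotation=r, cost=c)


def permute_graph(g: MoleculeGraph, perm: np.ndarray) -> MoleculeGraph:
    """Reorder atoms by ``perm`` (new atom k = old atom perm[k]), reindexing
    atom rows and bond pair-rows consistently."""
    n = g.n_atoms
    out = g.copy()
    out.positions = g.positions[perm]
    out.atom_types = g.atom_types[perm]
    out.charges = g.charges[perm]
    lookup = pair_row_lookup(n)
    iu, ju = pair_indices(n)
    old_rows = lookup[perm[iu], perm[ju]]
    out.bonds = g.bonds[old_rows]
    return out


def apply_alignment(pair: ConditionalPair, result: AlignmentResult) -> ConditionalPair:
    """Permute and rotate the prior sample g0; the data sample g1 is untouched."""
    if result.permutation.size != pair.n_atoms:
        raise ValueError("alignment size does not match pair")
    g0 = permute_graph(pair.g0, result.permutation)
    g0.positions = g0.positions @ result.rotation.T
    return ConditionalPair(g0=g0, g1=pair.g1)


__all__ = [
    "AlignmentResult",
    "align_pair",
    "apply_alignment",
    "kabsch",
    "permute_graph",
]
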