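"""Conditional interpolants, conditional vector fields, and training losses.

The conditioning variable is the trajectory endpoint pair z = (g0, g1). The
conditional path is the deterministic per-modality interpolant

    g_t = (1 - alpha_t) * g0 + alpha_t * g1

whose velocity is u = alpha'_t (g1 - g0), equivalently
(alpha'_t / (1 - alpha_t)) (g1 - g_t) wherever alpha_t < 1. The endpoint
parameterization predicts g1_hat instead of the velocity and reconstructs the
field from the second form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_types import MoleculeGraph
from .schedules import ScheduleSet

#: Default per-modality loss combination weights (X, A, C, E).
DEFAULT_ETA = (3.0, 0.4, 1.0, 2.0)

_EPS = 1e-12


@dataclass
class ConditionalPair:
    """A coupled (prior sample, data sample) pair with matching shapes."""

    g0: MoleculeGraph
    g1: MoleculeGraph

    def __post_init__(self):
        for name in ("positions", "atom_types", "charges", "bonds"):
            s0, s1 = getattr(self.g0, name).shape, getattr(self.g1, name).shape
            if s0 != s1:
                raise ValueError(f"shape mismatch on {name}: {s0} vs {s1}")

    @property
    def n_atoms(self) -> int:
        return self.g0.n_atoms


def _modality_arrays(g: MoleculeGraph):
    return {"x": g.positions, "a": g.atom_types, "c": g.charges, "e": g.bonds}


def interpolate(pair: ConditionalPair, schedules: ScheduleSet, t: float) -> MoleculeGraph:
    """Convex combination per modality with that modality's alpha(t)."""
    a0, a1 = _modality_arrays(pair.g0), _modality_arrays(pair.g1)
    out = {}
    for m in ("x", "a", "c", "e"):
        alpha = schedules.by_modality(m).alpha(t)
        out[m] = (1.0 - alpha) * a0[m] + alpha * a1[m]
    return MoleculeGraph(out["x"], out["a"], out["c"], out["e"], codebook=pair.g1.codebook)


def conditional_vf(pair: ConditionalPair, schedules: ScheduleSet, t: float) -> dict:
    """Per-modality conditional velocity alpha'_t * (g1 - g0)."""
    a0, a1 = _modality_arrays(pair.g0), _modality_arrays(pair.g1)
    return {
        m: schedules.by_modality(m).alpha_prime(t) * (a1[m] - a0[m]) for m in ("x", "a", "c", "e")
    }


def endpoint_vf(
    g_t: MoleculeGraph, g1_hat: MoleculeGraph, schedules: ScheduleSet, t: float
) -> dict:
    """Velocity (alpha'_t / (1 - alpha_t)) * (g1_hat - g_t) per modality.

    Raises if any modality's alpha(t) is numerically 1 (the sampler's
    integration grid must stop short of that point).
    """
    at, ahat = _modality_arrays(g_t), _modality_arrays(g1_hat)
    out = {}
    for m in ("x", "a", "c", "e"):
        s = schedules.by_modality(m)
        alpha = float(s.alpha(t))
        if 1.0 - alpha < 1e-12:
            raise ValueError(f"alpha_{m}(t={t}) is numerically 1; endpoint field undefined")
        out[m] = (s.alpha_prime(t) / (1.0 - alpha)) * (ahat[m] - at[m])
    return out


def cross_entropy_rows(pred_rows: np.ndarray, target_rows: np.ndarray) -> float:
    """Mean -log p(target class) with simplex-valued predictions."""
    p = np.clip(pred_rows, _EPS, None)
    return float(-(target_rows * np.log(p)).sum(axis=-1).mean())


def training_loss(
    pairs: list[ConditionalPair],
    predictions: list[dict],
    schedules: ScheduleSet,
    t_values: np.ndarray,
    objective: str = "endpoint",
    eta: tuple = DEFAULT_ETA,
    use_raw_weight: bool = False,
) -> float:
    """Weighted combination of per-modality flow-matching losses.

    endpoint objective: per-pair weight w(t) (or the raw alpha'/(1-alpha)
    behind ``use_raw_weight``) times squared error on positions plus
    cross-entropy on each categorical modality, where predictions[k] maps
    modality -> predicted-g1 array with simplex-valued categorical rows.

    vector-field objective: squared error against the conditional velocity
    for every modality; predictions[k] maps modality -> tangent array.
    """
    if objective not in ("endpoint", "vector_field"):
        raise ValueError(f"unknown objective {objective!r}")
    if len(pairs) != len(predictions) or len(pairs) != len(t_values):
        raise ValueError("pairs, predictions and t_values must have equal length")
    eta = {m: w for m, w in zip(("x", "a", "c", "e"), eta)}

    total = 0.0
    for pair, pred, t in zip(pairs, predictions, t_values):
        a1 = _modality_arrays(pair.g1)
        if objective == "endpoint":
            for m in ("x", "a", "c", "e"):
                if pred[m].shape != a1[m].shape:
                    raise ValueError(f"prediction shape mismatch on modality {m}")
            for m, sched in zip(("x", "a", "c", "e"), schedules):
                if a1[m].shape[0] == 0:  # e.g. single-atom molecule has no pairs
                    continue
                if use_raw_weight:
                    alpha = float(sched.alpha(t))
                    w = float(sched.alpha_prime(t)) / max(1.0 - alpha, _EPS)
                else:
                    w = float(sched.loss_weight(t))
                if m == "x":
                    term = float(((pred[m] - a1[m]) ** 2).sum(axis=-1).mean())
                else:
                    term = cross_entropy_rows(pred[m], a1[m])
                total += eta[m] * w * term
        else:
            target = conditional_vf(pair, schedules, float(t))
            for m in ("x", "a", "c", "e"):
                if pred[m].shape != target[m].shape:
                    raise ValueError(f"prediction shape mismatch on modality {m}")
                if target[m].shape[0] == 0:
                    continue
                total += eta[m] * float(((pred[m] - target[m]) ** 2).sum(axis=-1).mean())
    return total / len(pairs)


__all__ = [
    "DEFAULT_ETA",
    "ConditionalPair",
    "conditional_vf",
    "cross_entropy_rows",
    "endpoint_vf",
    "interpolate",
    "training_loss",
]
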