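"""Molecule generation by Euler integration of the learned ODE.

The integration grid is evenly spaced on [0, t_max] with t_max slightly below
1 so the endpoint field's alpha/(1-alpha) factor stays finite. For the
endpoint parameterization each Euler update is a convex combination of the
current state and the predicted endpoint whenever dt * alpha'/(1-alpha) <= 1;
that coefficient is clamped to 1, which keeps simplex-valued categorical
states on the simplex at every step. A terminal jump replaces categorical
states with the last endpoint prediction before argmax decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mol_types import MoleculeGraph, to_onehot
from .priors import MoleculePriorSpec, sample_atom_count, sample_molecule_prior
from .schedules import ScheduleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    n_steps: int = 100
    t_max: float = 1.0 - 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 < self.t_max <= 1.0:
            raise ValueError("t_max must lie in (0, 1]")


def euler_step(g: MoleculeGraph, t: float, dt: float, field) -> MoleculeGraph:
    """One explicit Euler update g' = g + dt * field(g, t) per modality."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = field(g, t)
    out = g.copy()
    out.positions = g.positions + dt * u["x"]
    out.atom_types = g.atom_types + dt * u["a"]
    out.charges = g.charges + dt * u["c"]
    out.bonds = g.bonds + dt * u["e"]
    return out


def _finite(g: MoleculeGraph) -> bool:
    return all(
        np.all(np.isfinite(arr)) for arr in (g.positions, g.atom_types, g.charges, g.bonds)
    )


def integrate(
    model,
    g0: MoleculeGraph,
    schedules: ScheduleSet,
    cfg: SamplingConfig,
    record: list | None = None,
) -> MoleculeGraph:
    """Advance g0 along the learned field; returns the pre-decoding state.

    Endpoint mode applies per-modality convex updates
    g <- (1 - c) g + c g1_hat with c = min(dt * alpha'/(1 - alpha), 1), then a
    terminal jump to the last categorical endpoint prediction. Vector-field
    mode applies plain Euler steps on the predicted tangents.
    """
    ts = np.linspace(0.0, cfg.t_max, cfg.n_steps + 1)
    g = g0.copy()
    g1_hat = None
    for t, t_next in zip(ts[:-1], ts[1:]):
        dt = float(t_next - t)
        if model.cfg.mode == "endpoint":
            g1_hat = model.predict_endpoint(g, float(t))
            out = g.copy()
            for m, attr in (("x", "positions"), ("a", "atom_types"),
                            ("c", "charges"), ("e", "bonds")):
                s = schedules.by_modality(m)
                alpha = float(s.alpha(t))
                c = min(dt * float(s.alpha_prime(t)) / max(1.0 - alpha, 1e-12), 1.0)
                cur, hat = getattr(g, attr), getattr(g1_hat, attr)
                setattr(out, attr, (1.0 - c) * cur + c * hat)
            g = out
        else:
            g = euler_step(g, float(t), dt, lambda gg, tt: model.predict_vf(gg, tt))
        if not _finite(g):
            raise FloatingPointError("non-finite state during integration")
        if record is not None:
            record.append(g.copy())
    if model.cfg.mode == "endpoint" and g1_hat is not None:
        # terminal jump: categorical states snap to the last endpoint prediction
        g1_hat = model.predict_endpoint(g, float(ts[-1]))
        g.atom_types = g1_hat.atom_types
        g.charges = g1_hat.charges
        g.bonds = g1_hat.bonds
        g.positions = g1_hat.positions
    return g


def decode_onehot(g: MoleculeGraph) -> MoleculeGraph:
    """Resolve categorical rows to one-hot by argmax (ties -> lowest index)."""
    out = g.copy()
    out.atom_types = to_onehot(g.element_labels(), g.atom_types.shape[1])
    out.charges = to_onehot(g.charge_labels(), g.charges.shape[1])
    if g.bonds.shape[0]:
        out.bonds = to_onehot(g.bond_labels(), g.bonds.shape[1])
    return out


def sample_molecules(
    model,
    priors: MoleculePriorSpec,
    count: int,
    schedules: ScheduleSet,
    cfg: SamplingConfig,
) -> list[MoleculeGraph]:
    """Generate ``count`` molecules; atom counts come from the prior histogram.

    Molecules whose integration goes non-finite are aborted and reported; the
    generator retries with fresh prior draws so exactly ``count`` molecules
    are returned (up to 10x oversampling attempts).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[MoleculeGraph] = []
    attempts = 0
    while len(out) < count and attempts < 10 * count:
        attempts += 1
        n = sample_atom_count(priors.atom_count_hist, rng)
        g0 = sample_molecule_prior(priors, n, model.codebook, rng)
        try:
            g = integrate(model, g0, schedules, cfg)
        except FloatingPointError:
            logger.warning("aborted molecule: non-finite state during integration")
            continue
        out.append(decode_onehot(g))
    if len(out) < count:
        raise RuntimeError(f"only generated {len(out)} of {count} molecules")
    return out


__all__ = ["SamplingConfig", "decode_onehot", "euler_step", "integrate", "sample_molecules"]
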