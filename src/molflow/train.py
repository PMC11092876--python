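"""Training loops: the molecule flow model and a desk-scale toy categorical flow.

Per step, each molecule in the batch is coupled with a fresh prior draw of the
same atom count (optionally OT-aligned), a shared t ~ U(0,1) is sampled per
molecule, and the endpoint (cross-entropy + weighted squared error) or
vector-field (squared error against the conditional velocity) objective is
minimized with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .flows import DEFAULT_ETA, ConditionalPair, conditional_vf, interpolate
from .mol_types import MoleculeGraph
from .network import FlowNet
from .nn import MLP, Adam, Module
from .ot_align import align_pair, apply_alignment
from .priors import MoleculePriorSpec, sample_molecule_prior
from .schedules import ScheduleSet
from .simplex import CategoricalPriorSpec, sample_prior


@dataclass(frozen=True)
class TrainConfig:
    n_steps: int = 300
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0
    objective: str = "endpoint"
    eta: tuple = DEFAULT_ETA
    ot_align: bool = True
    use_raw_weight: bool = False
    #: use Dirichlet conditional paths for categorical modalities (requires a
    #: uniform-simplex categorical prior and the endpoint objective)
    dirichlet_paths: bool = False
    omega_max: float = 100.0


def dirichlet_interpolate(
    pair: ConditionalPair,
    schedules: ScheduleSet,
    t: float,
    omega_max: float,
    rng: np.random.Generator,
) -> MoleculeGraph:
    """Positions follow the linear interpolant; each categorical row is drawn
    from the Dirichlet conditional path toward its one-hot target class."""
    from .simplex import dirichlet_path_sample

    g_t = interpolate(pair, schedules, t)
    g1 = pair.g1
    for attr, m in (("atom_types", "a"), ("charges", "c"), ("bonds", "e")):
        sched = schedules.by_modality(m)
        labels = getattr(g1, attr).argmax(axis=1)
        d = getattr(g1, attr).shape[1]
        rows = np.vstack(
            [dirichlet_path_sample(int(lbl), d, t, sched, omega_max, rng) for lbl in labels]
        ) if labels.size else getattr(g1, attr).copy()
        setattr(g_t, attr, rows)
    return g_t


def _endpoint_loss(model: FlowNet, pair: ConditionalPair, t: float,
                   schedules: ScheduleSet, eta, use_raw_weight: bool,
                   g_t: MoleculeGraph | None = None) -> Tensor:
    if g_t is None:
        g_t = interpolate(pair, schedules, t)
    out = model.forward(g_t, t)
    g1 = pair.g1
    total = None
    targets = {"a": g1.atom_types, "c": g1.charges, "e": g1.bonds}
    for m, w_eta in zip(("x", "a", "c", "e"), eta):
        sched = schedules.by_modality(m)
        if use_raw_weight:
            alpha = float(sched.alpha(t))
            w = float(sched.alpha_prime(t)) / max(1.0 - alpha, 1e-12)
        else:
            w = float(sched.loss_weight(t))
        if m == "x":
            diff = out["x"] - Tensor(g1.positions)
            term = (diff * diff).sum(axis=-1).mean()
        else:
            logits = out[f"{m}_logits"]
            if logits.shape[0] == 0:
                continue
            term = -(Tensor(targets[m]) * logits.log_softmax()).sum(axis=-1).mean()
        term = term * (w_eta * w)
        total = term if total is None else total + term
    return total


def _vf_loss(model: FlowNet, pair: ConditionalPair, t: float,
             schedules: ScheduleSet, eta) -> Tensor:
    g_t = interpolate(pair, schedules, t)
    out = model.forward(g_t, t)
    target = conditional_vf(pair, schedules, t)
    preds = {"x": out["vx"], "a": out["a_logits"], "c": out["c_logits"], "e": out["e_logits"]}
    total = None
    for m, w_eta in zip(("x", "a", "c", "e"), eta):
        if preds[m].shape[0] == 0:
            continue
        diff = preds[m] - Tensor(target[m])
        term = (diff * diff).sum(axis=-1).mean() * w_eta
        total = term if total is None else total + term
    return total


def make_pair(
    g1: MoleculeGraph,
    priors: MoleculePriorSpec,
    rng: np.random.Generator,
    ot: bool = True,
) -> ConditionalPair:
    """Couple a data molecule with a prior draw; optionally OT-align the prior."""
    g1 = g1.centered()
    g0 = sample_molecule_prior(priors, g1.n_atoms, g1.codebook, rng)
    pair = ConditionalPair(g0=g0, g1=g1)
    if ot and g1.n_atoms > 1:
        result = align_pair(g0.positions, g1.positions, n_restarts=4, rng=rng)
        pair = apply_alignment(pair, result)
    return pair


def train(
    model: FlowNet,
    dataset: list[MoleculeGraph],
    priors: MoleculePriorSpec,
    schedules: ScheduleSet,
    cfg: TrainConfig,
    callback=None,
) -> list[float]:
    """Run the training loop; returns the per-step loss history."""
    if model.cfg.mode != ("endpoint" if cfg.objective == "endpoint" else "vector_field"):
        raise ValueError("model mode does not match training objective")
    if cfg.dirichlet_paths and cfg.objective != "endpoint":
        raise ValueError("Dirichlet conditional paths require the endpoint objective")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: list[float] = []
    for step in range(cfg.n_steps):
        idx = rng.choice(len(dataset), size=min(cfg.batch_size, len(dataset)), replace=False)
        opt.zero_grad()
        total = None
        for i in idx:
            pair = make_pair(dataset[i], priors, rng, ot=cfg.ot_align)
            t = float(rng.uniform(0.0, 1.0))
            if cfg.objective == "endpoint":
                g_t = None
                if cfg.dirichlet_paths:
                    g_t = dirichlet_interpolate(pair, schedules, t, cfg.omega_max, rng)
                loss = _endpoint_loss(model, pair, t, schedules, cfg.eta,
                                      cfg.use_raw_weight, g_t=g_t)
            else:
                loss = _vf_loss(model, pair, t, schedules, cfg.eta)
            total = loss if total is None else total + loss
        total = total * (1.0 / len(idx))
        total.backward()
        opt.step()
        history.append(float(total.data))
        if callback is not None:
            callback(step, history[-1])
    return history


# --------------------------------------------------------------------- toy task
class ToyCategoricalFlow(Module):
    """Simplex-constrained flow for a single d-categorical variable.

    A small MLP maps (x_t, t) to endpoint logits; softmax keeps predicted
    endpoints on the simplex, so Euler trajectories driven by the endpoint
    field stay on the simplex whenever they start there.
    """

    def __init__(self, d: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d = d
        self.lin1 = MLP(d + 1, hidden, hidden, rng)
        self.head = MLP(hidden, hidden, d, rng)

    def logits(self, x_t: Tensor, t_col: Tensor) -> Tensor:
        h = self.lin1(concatenate([x_t, t_col], axis=-1)).silu()
        return self.head(h).log_softmax()

    def fit(
        self,
        targets: np.ndarray,
        prior_spec: CategoricalPriorSpec,
        schedule,
        n_steps: int = 2000,
        batch_size: int = 256,
        lr: float = 2e-3,
        seed: int = 0,
    ) -> list[float]:
        """Endpoint-objective training on one-hot target rows."""
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr)
        history = []
        for step in range(n_steps):
            # cosine decay to 5% of the base rate stabilizes the endpoint head
            opt.lr = lr * (0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * step / n_steps)))
            idx = rng.integers(0, targets.shape[0], size=batch_size)
            x1 = targets[idx]
            x0 = sample_prior(prior_spec, batch_size, self.d, rng)
            t = rng.uniform(0.0, 1.0, size=(batch_size, 1))
            alpha = schedule.alpha(t)
            x_t = (1.0 - alpha) * x0 + alpha * x1
            w = schedule.loss_weight(t)
            logp = self.logits(Tensor(x_t), Tensor(t))
            loss = -(Tensor(x1 * w) * logp).sum(axis=-1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
        return history

    def sample(
        self,
        prior_spec: CategoricalPriorSpec,
        schedule,
        n: int,
        n_steps: int = 100,
        t_max: float = 1.0 - 1e-4,
        seed: int = 0,
    ) -> np.ndarray:
        """Euler-integrate the endpoint field; returns argmax class labels."""
        rng = np.random.default_rng(seed)
        x = sample_prior(prior_spec, n, self.d, rng)
        ts = np.linspace(0.0, t_max, n_steps + 1)
        x1_hat = None
        for t, t_next in zip(ts[:-1], ts[1:]):
            t_col = Tensor(np.full((n, 1), t))
            x1_hat = self.logits(Tensor(x), t_col).exp().data
            alpha = float(schedule.alpha(t))
            c = min((t_next - t) * float(schedule.alpha_prime(t)) / max(1.0 - alpha, 1e-12), 1.0)
            x = (1.0 - c) * x + c * x1_hat
        x1_hat = self.logits(Tensor(x), Tensor(np.full((n, 1), ts[-1]))).exp().data
        return np.argmax(x1_hat, axis=1)


__all__ = ["ToyCategoricalFlow", "TrainConfig", "dirichlet_interpolate", "make_pair", "train"]
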