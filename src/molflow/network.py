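"""Equivariant graph network predicting the flow endpoint (or velocity).

Molecules are fully connected directed graphs. Node scalar features start as
atom type + charge (+ time); node vector features start at zero; directed
edge features start from the unordered bond row plus a radial-basis encoding
of the interatomic distance. Several molecule update blocks — node feature
update (message passing), node position update (node-wise), edge feature
update (edge-wise) — refine the state, after which shallow node-wise and
edge-wise MLP heads emit predictions. Bond predictions are made once per
unordered pair from the SUM of the two directed edge features, so they are
invariant to the atom-index order within the pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate
from .mol_types import CategoryCodebook, MoleculeGraph, pair_indices, pair_row_lookup
from .nn import GVP, MLP, Linear, Module


@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 2
    scalar_dim: int = 32
    vector_dim: int = 4
    edge_dim: int = 16
    n_rbf: int = 8
    rbf_max: float = 5.0
    cross_products: bool = True
    mode: str = "endpoint"  # or "vector_field"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("endpoint", "vector_field"):
            raise ValueError(f"unknown mode {self.mode!r}")


class MoleculeUpdateBlock(Module):
    """One NFU + NPU + EFU round over the fully connected graph."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ds, dv, de = cfg.scalar_dim, cfg.vector_dim, cfg.edge_dim
        xp = cfg.cross_products
        self.msg = GVP(2 * ds + de + cfg.n_rbf, dv + 1, ds, dv, rng, use_cross=xp)
        self.upd = GVP(2 * ds, 2 * dv, ds, dv, rng, use_cross=xp)
        self.npu = GVP(ds, dv, ds, 1, rng, use_cross=xp, activate_scalars=False)
        self.efu = MLP(2 * ds + de + cfg.n_rbf, de, de, rng)

    def __call__(self, x, s, v, e, rbf, mask):
        n = x.shape[0]
        ds = s.shape[-1]
        si = s.reshape(n, 1, ds).expand((n, n, ds))
        sj = s.reshape(1, n, ds).expand((n, n, ds))
        vj = v.reshape(1, n, *v.shape[1:]).expand((n, n, *v.shape[1:]))
        rel = x.reshape(1, n, 3).expand((n, n, 3)) - x.reshape(n, 1, 3).expand((n, n, 3))

        # NFU: message passing over all neighbors
        m_s, m_v = self.msg(
            concatenate([si, sj, e, rbf], axis=-1),
            concatenate([vj, rel.reshape(n, n, 1, 3)], axis=-2),
        )
        denom = float(max(n - 1, 1))
        agg_s = (m_s * mask).sum(axis=1) / denom
        agg_v = (m_v * mask.reshape(n, n, 1, 1)).sum(axis=1) / denom
        u_s, u_v = self.upd(concatenate([s, agg_s], axis=-1), concatenate([v, agg_v], axis=-2))
        s = s + u_s
        v = v + u_v

        # NPU: node-wise position update from the node's own features
        _, dx = self.npu(s, v)
        x = x + dx.reshape(n, 3)

        # EFU: edge-wise feature update
        si = s.reshape(n, 1, ds).expand((n, n, ds))
        sj = s.reshape(1, n, ds).expand((n, n, ds))
        e = e + self.efu(concatenate([si, sj, e, rbf], axis=-1))
        return x, s, v, e


class FlowNet(Module):
    """g1-endpoint (or velocity) predictor for molecular graphs."""

    def __init__(self, cfg: ModelConfig, codebook: CategoryCodebook | None = None):
        self.cfg = cfg
        self.codebook = codebook or CategoryCodebook()
        cb = self.codebook
        rng = np.random.default_rng(cfg.seed)
        ds, de = cfg.scalar_dim, cfg.edge_dim
        self.embed_s = MLP(cb.n_a + cb.n_c + 1, ds, ds, rng)
        self.embed_e = MLP(cb.n_e + cfg.n_rbf, de, de, rng)
        self.blocks = [MoleculeUpdateBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.head_a = MLP(ds, ds, cb.n_a, rng)
        self.head_c = MLP(ds, ds, cb.n_c, rng)
        self.head_e = MLP(de, de, cb.n_e, rng)
        # velocity head for vector-field mode (equivariant vector output)
        self.head_vx = GVP(ds, cfg.vector_dim, ds, 1, rng,
                           use_cross=cfg.cross_products, activate_scalars=False)
        self._rbf_centers = np.linspace(0.0, cfg.rbf_max, cfg.n_rbf)
        self._rbf_width = cfg.rbf_max / max(cfg.n_rbf - 1, 1)

    # ------------------------------------------------------------------ trunk
    def forward(self, g_t: MoleculeGraph, t: float) -> dict:
        """Run the trunk and heads; returns Tensors keyed by modality.

        'x' is the predicted endpoint position (endpoint mode) and
        '{a,c,e}_logits' are pre-softmax categorical head outputs over nodes /
        unordered pairs. 'vx' is the velocity-head vector for vector-field
        mode.
        """
        if not 0.0 <= t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        cfg, cb = self.cfg, self.codebook
        n = g_t.n_atoms
        x_in = Tensor(g_t.positions)
        t_col = np.full((n, 1), float(t))
        s = self.embed_s(Tensor(np.concatenate([g_t.atom_types, g_t.charges, t_col], axis=1)))
        v = Tensor(np.zeros((n, cfg.vector_dim, 3)))

        lookup = pair_row_lookup(n)
        if g_t.bonds.shape[0] == 0:  # single atom: no pairs
            e_in = np.zeros((n, n, cb.n_e))
        else:
            safe = np.where(lookup >= 0, lookup, 0)
            e_in = g_t.bonds[safe]  # (N, N, n_e), both directions from the unordered row
        mask = Tensor((1.0 - np.eye(n))[:, :, None])

        x = x_in
        rbf = self._rbf(x)
        e = self.embed_e(concatenate([Tensor(e_in), rbf], axis=-1))
        for block in self.blocks:
            rbf = self._rbf(x)
            x, s, v, e = block(x, s, v, e, rbf, mask)

        iu, ju = pair_indices(n)
        e_pair = e[iu, ju] + e[ju, iu]  # symmetric: one prediction per pair
        out = {
            "x": x,
            "a_logits": self.head_a(s),
            "c_logits": self.head_c(s),
            "e_logits": self.head_e(e_pair),
        }
        if cfg.mode == "vector_field":
            _, vx = self.head_vx(s, v)
            out["vx"] = vx.reshape(n, 3)
        return out

    def _rbf(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        rel = x.reshape(1, n, 3).expand((n, n, 3)) - x.reshape(n, 1, 3).expand((n, n, 3))
        dist = ((rel * rel).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        z = (dist - self._rbf_centers) / self._rbf_width
        return (-(z * z)).exp()

    # ------------------------------------------------------------------ heads
    def predict_endpoint(self, g_t: MoleculeGraph, t: float) -> MoleculeGraph:
        """Predicted g1 with softmax-constrained categorical rows."""
        if self.cfg.mode != "endpoint":
            raise ValueError("model is not in endpoint mode")
        out = self.forward(g_t, t)
        return MoleculeGraph(
            positions=out["x"].data,
            atom_types=out["a_logits"].softmax().data,
            charges=out["c_logits"].softmax().data,
            bonds=out["e_logits"].softmax().data,
            codebook=self.codebook,
        )

    def predict_vf(self, g_t: MoleculeGraph, t: float) -> dict:
        """Unconstrained per-modality tangent predictions (ablation head)."""
        if self.cfg.mode != "vector_field":
            raise ValueError("model is not in vector_field mode")
        out = self.forward(g_t, t)
        return {
            "x": out["vx"].data,
            "a": out["a_logits"].data,
            "c": out["c_logits"].data,
            "e": out["e_logits"].data,
        }

    # -------------------------------------------------------------- persistence
    def save(self, path, extra: dict | None = None) -> None:
        payload = {
            "config": asdict(self.cfg),
            "codebook": self.codebook.to_dict(),
            "weights": [w.tolist() for w in self.state_dict()],
            "extra": extra or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> tuple["FlowNet", dict]:
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(ModelConfig(**payload["config"]),
                    CategoryCodebook.from_dict(payload["codebook"]))
        model.load_state_dict([np.asarray(w) for w in payload["weights"]])
        return model, payload.get("extra", {})


__all__ = ["FlowNet", "ModelConfig", "MoleculeUpdateBlock"]
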