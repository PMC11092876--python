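"""Probability-simplex geometry, categorical priors, and Dirichlet paths.

The d-simplex is the set of nonnegative d-vectors summing to one; one-hot
vectors are its vertices and (1/d, ..., 1/d) its barycenter. Categorical
priors are sampled row-wise and, for degenerate families, widened by adding
Gaussian "blur" before Euclidean re-projection onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SIMPLEX_ATOL = 1e-9

PRIOR_FAMILIES = ("gaussian", "uniform-simplex", "marginal-simplex", "barycenter")


@dataclass(frozen=True)
class CategoricalPriorSpec:
    """Per-modality categorical prior configuration.

    family : one of PRIOR_FAMILIES. "gaussian" is the unconstrained baseline
        (i.i.d. standard normal rows, NOT on the simplex).
    blur_sigma : std of Gaussian noise added to simplex samples before
        re-projection; only meaningful for simplex families.
    marginals : category probabilities (marginal-simplex family only).
    """

    family: str = "gaussian"
    blur_sigma: float = 0.0
    marginals: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.family not in PRIOR_FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.family == "marginal-simplex":
            if self.marginals is None:
                raise ValueError("marginal-simplex prior requires marginals")
            q = np.asarray(self.marginals, dtype=np.float64)
            if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-8:
                raise ValueError("marginals must be a probability vector")

    @property
    def on_simplex(self) -> bool:
        return self.family != "gaussian"


def assert_on_simplex(rows: np.ndarray, atol: float = SIMPLEX_ATOL) -> bool:
    """True iff every row is nonnegative (within atol) and sums to 1."""
    rows = np.asarray(rows, dtype=np.float64)
    if rows.size == 0:
        return True
    return bool(np.all(rows >= -atol) and np.allclose(rows.sum(axis=-1), 1.0, atol=atol))


def project_to_simplex(rows: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex.

    Sort-based algorithm (Held et al. / Duchi et al.): for each row y, the
    projection is max(y - tau, 0) where tau is chosen so the result sums to 1.
    Idempotent and non-expansive.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite input to simplex projection")
    squeeze = rows.ndim == 1
    y = np.atleast_2d(rows)
    d = y.shape[1]
    u = np.sort(y, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ks = np.arange(1, d + 1)
    cond = u - css / ks > 0
    rho = d - 1 - np.argmax(cond[:, ::-1], axis=1)  # last index where cond holds
    tau = css[np.arange(y.shape[0]), rho] / (rho + 1)
    out = np.maximum(y - tau[:, None], 0.0)
    return out[0] if squeeze else out


def blur_rows(rows: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add N(0, sigma^2) noise per coordinate, then re-project onto the simplex."""
    if sigma == 0.0:
        return np.asarray(rows, dtype=np.float64)
    return project_to_simplex(rows + rng.normal(0.0, sigma, size=np.shape(rows)))


def sample_prior(
    spec: CategoricalPriorSpec, m: int, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw M rows from the categorical prior for a d-way variable.

    uniform-simplex -> flat Dirichlet; marginal-simplex -> one-hot vertices
    with probabilities q; barycenter -> all rows at (1/d, ..., 1/d); the two
    degenerate families are then blurred and re-projected. gaussian -> i.i.d.
    standard normal rows (unconstrained).
    """
    if m < 0:
        raise ValueError("sample count must be >= 0")
    if spec.family == "gaussian":
        return rng.normal(size=(m, d))
    if spec.family == "uniform-simplex":
        rows = rng.dirichlet(np.ones(d), size=m)
    elif spec.family == "barycenter":
        rows = np.full((m, d), 1.0 / d)
    else:  # marginal-simplex
        q = np.asarray(spec.marginals, dtype=np.float64)
        if q.size != d:
            raise ValueError(f"marginals have {q.size} entries, expected {d}")
        labels = rng.choice(d, size=m, p=q / q.sum())
        rows = np.zeros((m, d))
        rows[np.arange(m), labels] = 1.0
    return blur_rows(rows, spec.blur_sigma, rng)


def dirichlet_path_sample(
    target_class: int,
    d: int,
    t: float,
    schedule,
    omega_max: float,
    rng: np.random.Generator,
    m: int = 1,
) -> np.ndarray:
    """Sample the Dirichlet conditional path for a one-hot target e_i.

    Draws M rows from Dir(gamma) with gamma_j = 1 + [j == i] * omega_t and
    omega_t = omega_max * alpha(t) + 1: the target class starts at
    concentration 2 (omega_t = 1 at alpha = 0) and sharpens toward the vertex
    as t -> 1; the path reaches the vertex only in the omega -> inf limit,
    hence the explicit finite cap omega_max.
    """
    if not 0 <= target_class < d:
        raise ValueError(f"class index {target_class} out of range for d={d}")
    if omega_max <= 0:
        raise ValueError("omega_max must be positive")
    omega_t = omega_max * float(schedule.alpha(t)) + 1.0
    gamma = np.ones(d)
    gamma[target_class] += omega_t
    return rng.dirichlet(gamma, size=m)


__all__ = [
    "PRIOR_FAMILIES",
    "SIMPLEX_ATOL",
    "CategoricalPriorSpec",
    "assert_on_simplex",
    "blur_rows",
    "dirichlet_path_sample",
    "project_to_simplex",
    "sample_prior",
]
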