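"""Interpolant schedules: per-modality cosine time warps and the loss weight.

alpha(t) = 1 - cos^2((pi/2) * t^nu) runs monotonically from 0 to 1; each data
modality (positions X, atom types A, charges C, bond orders E) carries its own
exponent nu. The training loss weight is alpha/(1-alpha) clamped to
[0.005, 1.5], which stays bounded as alpha -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("x", "a", "c", "e")

W_MIN = 0.005
W_MAX = 1.5


@dataclass(frozen=True)
class InterpolantSchedule:
    nu: float = 1.0
    kind: str = "cosine"
    modality: str = "x"

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError(f"nu must be positive, got {self.nu}")
        if self.kind != "cosine":
            raise ValueError(f"unknown schedule kind {self.kind!r}")

    def alpha(self, t):
        """Interpolation fraction in [0, 1]; 0 at t=0 and 1 at t=1."""
        t = _check_t(t)
        return 1.0 - np.cos((np.pi / 2.0) * t**self.nu) ** 2

    def alpha_prime(self, t):
        """Closed-form d(alpha)/dt = (pi*nu/2) * t^(nu-1) * sin(pi * t^nu).

        At t=0 the product behaves like (pi^2 nu / 2) t^(2 nu - 1); the limit
        (0 for nu > 1/2, pi^2/4 at nu = 1/2, +inf below) is substituted
        explicitly to avoid 0 ** negative.
        """
        t = _check_t(t)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        pos = t > 0
        tp = t[pos]
        out[pos] = (np.pi * self.nu / 2.0) * tp ** (self.nu - 1.0) * np.sin(np.pi * tp**self.nu)
        if self.nu > 0.5:
            limit0 = 0.0
        elif self.nu == 0.5:
            limit0 = np.pi**2 / 4.0
        else:
            limit0 = np.inf
        out[~pos] = limit0
        return out[0] if scalar else out

    def loss_weight(self, t):
        """alpha/(1-alpha) clamped to [W_MIN, W_MAX]; nondecreasing in t."""
        a = self.alpha(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(a < 1.0, a / np.maximum(1.0 - a, 1e-300), np.inf)
        return np.clip(raw, W_MIN, W_MAX)


def _check_t(t):
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("t must lie in [0, 1]")
    return t


@dataclass(frozen=True)
class ScheduleSet:
    """One interpolant schedule per modality (X, A, C, E)."""

    x: InterpolantSchedule = field(default_factory=lambda: InterpolantSchedule(modality="x"))
    a: InterpolantSchedule = field(default_factory=lambda: InterpolantSchedule(modality="a"))
    c: InterpolantSchedule = field(default_factory=lambda: InterpolantSchedule(modality="c"))
    e: InterpolantSchedule = field(default_factory=lambda: InterpolantSchedule(modality="e"))

    @classmethod
    def from_nus(cls, nu_x=1.0, nu_a=1.0, nu_c=1.0, nu_e=1.0) -> "ScheduleSet":
        return cls(
            InterpolantSchedule(nu_x, modality="x"),
            InterpolantSchedule(nu_a, modality="a"),
            InterpolantSchedule(nu_c, modality="c"),
            InterpolantSchedule(nu_e, modality="e"),
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "ScheduleSet":
        return cls.from_nus(*(cfg.get(m, {}).get("nu", 1.0) for m in MODALITIES))

    def __iter__(self):
        return iter((self.x, self.a, self.c, self.e))

    def by_modality(self, m: str) -> InterpolantSchedule:
        return {"x": self.x, "a": self.a, "c": self.c, "e": self.e}[m]

    def to_dict(self) -> dict:
        return {m: {"nu": self.by_modality(m).nu} for m in MODALITIES}


__all__ = ["MODALITIES", "W_MAX", "W_MIN", "InterpolantSchedule", "ScheduleSet"]
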