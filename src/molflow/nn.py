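"""Network building blocks on the autodiff engine.

Linear/MLP layers for invariant (scalar) features and a geometric vector
perceptron (GVP) whose vector path mixes channels linearly, gates by learned
scalars, and optionally injects cross-product channels. Linear maps on the
channel axis commute with rotations acting on the trailing xyz axis, so vector
outputs are rotation-equivariant; cross products additionally break
reflection symmetry.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, cross

_NORM_EPS = 1e-8


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != np.asarray(arr).shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(arr, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.w = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class MLP(Module):
    """Two-layer perceptron with SiLU hidden activation, linear output."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.lin1 = Linear(d_in, d_hidden, rng)
        self.lin2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).silu())


def channel_mix(v: Tensor, lin: Linear) -> Tensor:
    """Apply a channel-axis linear map to vectors shaped (..., C, 3)."""
    return (v.swapaxes(-1, -2) @ lin.w).swapaxes(-1, -2)


def vector_norms(v: Tensor) -> Tensor:
    """Rotation-invariant per-channel norms, shape (..., C)."""
    return ((v * v).sum(axis=-1) + _NORM_EPS).sqrt()


class GVP(Module):
    """Geometric vector perceptron, optionally with cross-product channels.

    Maps (scalars (..., s_in), vectors (..., v_in, 3)) to
    (scalars (..., s_out), vectors (..., v_out, 3)). Scalar outputs see only
    rotation-invariant quantities; vector outputs are linear channel mixes
    gated by learned sigmoids of the scalar path. With ``use_cross`` enabled,
    channels built as cross products of two learned mixes are appended before
    the output mix, making vector outputs sensitive to reflections.
    """

    def __init__(
        self,
        s_in: int,
        v_in: int,
        s_out: int,
        v_out: int,
        rng: np.random.Generator,
        v_hidden: int | None = None,
        use_cross: bool = False,
        activate_scalars: bool = True,
    ):
        v_hidden = v_hidden or max(v_in, v_out)
        self.use_cross = use_cross
        self.activate_scalars = activate_scalars
        self.wh = Linear(v_in, v_hidden, rng, bias=False)
        if use_cross:
            self.wc1 = Linear(v_in, v_hidden, rng, bias=False)
            self.wc2 = Linear(v_in, v_hidden, rng, bias=False)
        n_norm = v_hidden * (2 if use_cross else 1)
        self.wmu = Linear(n_norm, v_out, rng, bias=False)
        self.ws = Linear(s_in + n_norm, s_out, rng)
        self.wg = Linear(s_out, v_out, rng)

    def __call__(self, s: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
        vh = channel_mix(v, self.wh)
        if self.use_cross:
            vc = cross(channel_mix(v, self.wc1), channel_mix(v, self.wc2))
            vh = concatenate([vh, vc], axis=-2)
        s_out = self.ws(concatenate([s, vector_norms(vh)], axis=-1))
        if self.activate_scalars:
            s_out = s_out.silu()
        gate = self.wg(s_out).sigmoid()
        v_out = channel_mix(vh, self.wmu) * gate.reshape(*gate.shape, 1)
        return s_out, v_out


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


__all__ = ["GVP", "MLP", "Adam", "Linear", "Module", "channel_mix", "vector_norms"]
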