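"""Per-cell gene regulatory network of the HIF pathway.

Seven coupled ODEs describe the dimensionless activity levels of HIF (h)
and its downstream targets: the metabolic genes LDH (l), PDK (k), PDH (q)
and the collagen-remodelling genes P4HA1 (p), MT1-MMP (m) and LOX (r).

Regulation uses the Shifted-Hill function

    S(Y, s, gamma) = s^n / (s^n + Y^n) + gamma * Y^n / (s^n + Y^n),

the sum of an inhibiting and an activating Hill term: gamma > 1 encodes
up-regulation by the regulator Y, gamma < 1 down-regulation.  HIF itself is
produced at a constant rate and degraded in an oxygen-dependent manner
(S multiplies the degradation term), so hypoxia stabilises HIF:

    dh/dt = alpha_h * beta_h - d_h * S(O, s_Oh, gamma_Oh) * h
    dl/dt = alpha_l * S(h, s_hl, gamma_hl) - d_l * l          (similarly k)
    dq/dt = alpha_q * S(k, s_kq, gamma_kq) - d_q * q
    dp,dm,dr/dt driven by h like l.

All functions are vectorised: gene levels are arrays of shape (..., 7)
so a whole cell population integrates in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "GENE_NAMES",
    "GeneLevels",
    "GrnParams",
    "shifted_hill",
    "grn_derivatives",
    "integrate_genes",
    "fixed_point",
]

#: Order of the seven species in every (..., 7) array.
GENE_NAMES = ("h", "l", "k", "q", "p", "m", "r")


class GrnError(ValueError):
    """Domain error in a gene-network computation."""


class IntegrationError(RuntimeError):
    """Non-finite state encountered during time integration."""


@dataclass
class GeneLevels:
    """The seven per-cell protein levels (dimensionless activities)."""

    h: float = 1.0
    l: float = 1.0
    k: float = 1.0
    q: float = 1.0
    p: float = 1.0
    m: float = 1.0
    r: float = 1.0

    def to_array(self) -> np.ndarray:
        return np.array([self.h, self.l, self.k, self.q, self.p, self.m, self.r])

    @classmethod
    def from_array(cls, a) -> "GeneLevels":
        a = np.asarray(a, dtype=float)
        if a.shape != (7,):
            raise GrnError(f"expected 7 gene levels, got shape {a.shape}")
        return cls(*a.tolist())


@dataclass
class GrnParams:
    """Gene-regulation parameters (production/degradation in min^-1,
    thresholds and strengths dimensionless except s_O_h in mmol/L)."""

    alpha_h: float = 0.005
    alpha_l: float = 0.005
    alpha_k: float = 0.005
    alpha_q: float = 0.005
    alpha_p: float = 0.005
    alpha_m: float = 0.005
    alpha_r: float = 0.005
    d_h: float = 0.005
    d_l: float = 0.005
    d_k: float = 0.005
    d_q: float = 0.005
    d_p: float = 0.005
    d_m: float = 0.005
    d_r: float = 0.005
    s_O_h: float = 0.02085  # mmol/L: oxygen level of half-maximal HIF degradation
    s_h_l: float = 13.04
    s_h_k: float = 13.34
    s_k_q: float = 9.94
    s_h_p: float = 13.68
    s_h_m: float = 13.25  # Table value; HIF is the regulator (see docs)
    s_h_r: float = 13.44
    gamma_O_h: float = 25.01
    gamma_h_l: float = 16.06
    gamma_h_k: float = 17.87
    gamma_k_q: float = 0.78
    gamma_h_p: float = 16.87
    gamma_h_m: float = 20.43
    gamma_h_r: float = 25.46
    beta_h: float = 25.01  # HIF production scale
    n: int = 4  # Hill coefficient

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "n":
                if int(v) < 1:
                    raise GrnError("Hill coefficient n must be >= 1")
                self.n = int(v)
            elif not (np.isfinite(v) and v > 0):
                raise GrnError(f"parameter {f.name} must be finite and > 0, got {v}")

    def with_overrides(self, overrides: Mapping[str, float]) -> "GrnParams":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise GrnError(f"unknown GRN parameter(s): {sorted(unknown)}")
        return replace(self, **dict(overrides))

    def upper_bounds(self) -> np.ndarray:
        """Per-species upper bound alpha*max(1,gamma_in)*scale/d, in
        GENE_NAMES order.  For h the incoming regulation acts on the
        degradation term, so the bound is alpha_h*beta_h/d_h (S >= min(1,
        gamma) >= ... S is bounded below by min(1, gamma_O_h))."""
        s_min = min(1.0, self.gamma_O_h)
        return np.array(
            [
                self.alpha_h * self.beta_h / (self.d_h * s_min),
                self.alpha_l * max(1.0, self.gamma_h_l) / self.d_l,
                self.alpha_k * max(1.0, self.gamma_h_k) / self.d_k,
                self.alpha_q * max(1.0, self.gamma_k_q) / self.d_q,
                self.alpha_p * max(1.0, self.gamma_h_p) / self.d_p,
                self.alpha_m * max(1.0, self.gamma_h_m) / self.d_m,
                self.alpha_r * max(1.0, self.gamma_h_r) / self.d_r,
            ]
        )


def shifted_hill(Y, s: float, gamma: float, n: int):
    """Shifted-Hill modulation factor S(Y, s, gamma).

    Monotone in Y between 1 (at Y=0) and gamma (as Y -> inf); equals
    (1+gamma)/2 at Y=s.  Vectorised over Y.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)) or np.any(Y < 0):
        raise GrnError("regulator level Y must be finite and >= 0")
    if not (np.isfinite(s) and s > 0):
        raise GrnError("half-max threshold s must be > 0")
    if not (np.isfinite(gamma) and gamma > 0):
        raise GrnError("regulation strength gamma must be > 0")
    if n < 1:
        raise GrnError("Hill coefficient n must be >= 1")
    # compute with the ratio (Y/s)^n for numerical robustness at large Y
    u = (Y / s) ** n
    out = (1.0 + gamma * u) / (1.0 + u)
    return out if out.ndim else float(out)


def _hill(Y, s: float, gamma: float, n: int):
    """shifted_hill without input validation (hot path; inputs already
    checked by the caller)."""
    u = (Y / s) ** n
    return (1.0 + gamma * u) / (1.0 + u)


def _levels_array(levels: Union[GeneLevels, np.ndarray]) -> np.ndarray:
    if isinstance(levels, GeneLevels):
        return levels.to_array()
    a = np.asarray(levels, dtype=float)
    if a.shape[-1] != 7:
        raise GrnError("gene-level array must have last dimension 7")
    return a


def grn_derivatives(levels, O, params: GrnParams = None) -> np.ndarray:
    """Time derivatives (min^-1) of the seven gene levels.

    ``levels`` may be a GeneLevels or an array (..., 7); ``O`` is the local
    oxygen concentration (mmol/L), broadcastable against the leading
    dimensions of ``levels``.
    """
    p = params or GrnParams()
    x = _levels_array(levels)
    O = np.asarray(O, dtype=float)
    if np.any(O < 0) or not np.all(np.isfinite(O)):
        raise GrnError("oxygen must be finite and >= 0")
    if np.any(x < 0):
        raise GrnError("gene levels must be >= 0")
    h, l, k, q, pp, m, r = (x[..., i] for i in range(7))
    n = p.n
    d = np.empty_like(x)
    d[..., 0] = p.alpha_h * p.beta_h - p.d_h * _hill(O, p.s_O_h, p.gamma_O_h, n) * h
    d[..., 1] = p.alpha_l * _hill(h, p.s_h_l, p.gamma_h_l, n) - p.d_l * l
    d[..., 2] = p.alpha_k * _hill(h, p.s_h_k, p.gamma_h_k, n) - p.d_k * k
    d[..., 3] = p.alpha_q * _hill(k, p.s_k_q, p.gamma_k_q, n) - p.d_q * q
    d[..., 4] = p.alpha_p * _hill(h, p.s_h_p, p.gamma_h_p, n) - p.d_p * pp
    d[..., 5] = p.alpha_m * _hill(h, p.s_h_m, p.gamma_h_m, n) - p.d_m * m
    d[..., 6] = p.alpha_r * _hill(h, p.s_h_r, p.gamma_h_r, n) - p.d_r * r
    return d


def _rk4_step(x: np.ndarray, O, dt: float, params: GrnParams) -> np.ndarray:
    """One classical RK4 step with oxygen frozen over the step."""
    k1 = grn_derivatives(x, O, params)
    k2 = grn_derivatives(np.maximum(x + 0.5 * dt * k1, 0.0), O, params)
    k3 = grn_derivatives(np.maximum(x + 0.5 * dt * k2, 0.0), O, params)
    k4 = grn_derivatives(np.maximum(x + dt * k3, 0.0), O, params)
    out = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    # production/degradation structure keeps true solutions positive; clip
    # the (tiny, O(dt^5)) integrator undershoot
    return np.maximum(out, 0.0)


def integrate_genes(
    levels,
    oxygen_trace: Union[float, Callable[[float], float]],
    params: GrnParams = None,
    dt: float = 0.01,
    horizon: float = 0.0,
    t0: float = 0.0,
):
    """Advance gene levels over ``horizon`` minutes with fixed-step RK4.

    ``oxygen_trace`` is either a constant oxygen concentration or a callable
    t -> O(t) (mmol/L); oxygen is frozen at the start of each step, matching
    the operator splitting used by the simulation engine.  Returns the same
    type as ``levels`` (GeneLevels in, GeneLevels out).
    """
    p = params or GrnParams()
    if dt <= 0:
        raise GrnError("dt must be > 0")
    if horizon < 0:
        raise GrnError("horizon must be >= 0")
    as_obj = isinstance(levels, GeneLevels)
    x = _levels_array(levels).astype(float, copy=True)
    trace = oxygen_trace if callable(oxygen_trace) else (lambda t, _O=float(oxygen_trace): _O)
    nsteps = int(round(horizon / dt))
    t = t0
    for i in range(nsteps):
        x = _rk4_step(x, trace(t), dt, p)
        t = t0 + (i + 1) * dt
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite gene level at t={t:.4f} min")
    # handle a fractional remainder so horizon need not be a dt multiple
    rem = horizon - nsteps * dt
    if rem > 1e-12 * max(1.0, horizon):
        x = _rk4_step(x, trace(t), rem, p)
    return GeneLevels.from_array(x) if as_obj else x


def fixed_point(O: float, params: GrnParams = None) -> GeneLevels:
    """Closed-form steady state at constant oxygen, cascaded down the
    network (each species' fixed point x* = alpha*S(input*)/d)."""
    p = params or GrnParams()
    n = p.n
    h = p.alpha_h * p.beta_h / (p.d_h * shifted_hill(O, p.s_O_h, p.gamma_O_h, n))
    l = p.alpha_l * shifted_hill(h, p.s_h_l, p.gamma_h_l, n) / p.d_l
    k = p.alpha_k * shifted_hill(h, p.s_h_k, p.gamma_h_k, n) / p.d_k
    q = p.alpha_q * shifted_hill(k, p.s_k_q, p.gamma_k_q, n) / p.d_q
    pp = p.alpha_p * shifted_hill(h, p.s_h_p, p.gamma_h_p, n) / p.d_p
    m = p.alpha_m * shifted_hill(h, p.s_h_m, p.gamma_h_m, n) / p.d_m
    r = p.alpha_r * shifted_hill(h, p.s_h_r, p.gamma_h_r, n) / p.d_r
    return GeneLevels(h, l, k, q, pp, m, r)
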