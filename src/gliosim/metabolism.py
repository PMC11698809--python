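"""Cell metabolism: oxygen/glucose uptake, ATP generation, proton secretion.

Oxygen uptake follows Michaelis-Menten kinetics gated by a logistic
function of the PDH level q (oxidative phosphorylation needs active PDH);
glucose uptake is demand-driven -- the cell tries to meet a target ATP
production A_0, glycolysis making up whatever respiration does not supply,
scaled up by a logistic function of the LDH level l (the glycolytic switch):

    f_O = Psi_O(q) * V_O * O/(K_O + O)
    f_G = max(0, Psi_G(l)*A_0/2 - 29*f_O/10) * G/(K_G + G)
    f_A = 2*f_G + 29/5 * f_O          (ATP stoichiometry: 2 per glucose
                                       via glycolysis, ~29/5 per O2)
    f_H = 2*f_G * k_H                 (protons co-secreted with lactate)

All rates are concentration changes per minute (mmol/L/min) in the cell's
voxel.  Functions are vectorised over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "MetabolicParams",
    "MetabolicRates",
    "logistic_modulation",
    "oxygen_uptake",
    "glucose_uptake",
    "atp_rate",
    "proton_rate",
    "metabolic_rates",
]


class MetabolismError(ValueError):
    """Domain error in a metabolic computation."""


@dataclass
class MetabolicParams:
    """Metabolic parameters; defaults are the model's calibrated values."""

    V_O: float = 0.01875  # maximal O2 consumption rate, mmol/L/min
    K_O: float = 0.0075  # Michaelis constant of O2, mmol/L
    Phi_O: float = 1.0  # max of Psi_O
    phi_O: float = 0.0  # min of Psi_O
    lam_q: float = 15.0  # steepness of Psi_O
    q_0: float = 0.575  # midpoint of Psi_O (PDH level)
    A_0: float = 0.10875  # target ATP demand, mmol/L/min
    K_G: float = 0.04  # Michaelis constant of glucose, mmol/L
    Phi_G: float = 50.0  # max of Psi_G
    phi_G: float = 1.0  # min of Psi_G
    lam_l: float = 4.0  # steepness of Psi_G
    l_0: float = 8.03  # midpoint of Psi_G (LDH level)
    k_H: float = 2.5e-4  # proton-buffering term, dimensionless

    def __post_init__(self) -> None:
        if not (self.Phi_O >= self.phi_O >= 0):
            raise MetabolismError("require Phi_O >= phi_O >= 0")
        if not (self.Phi_G >= self.phi_G >= 0):
            raise MetabolismError("require Phi_G >= phi_G >= 0")
        if self.K_O <= 0 or self.K_G <= 0:
            raise MetabolismError("Michaelis constants must be > 0")

    def with_overrides(self, overrides: Mapping[str, float]) -> "MetabolicParams":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise MetabolismError(f"unknown metabolic parameter(s): {sorted(unknown)}")
        return replace(self, **dict(overrides))


@dataclass
class MetabolicRates:
    """Per-cell uptake/secretion rates, mmol/L/min in the cell's voxel."""

    f_O: float = 0.0
    f_G: float = 0.0
    f_A: float = 0.0
    f_H: float = 0.0


def logistic_modulation(x, Phi: float, phi: float, lam: float, x0: float):
    """Logistic gene-effect factor (Phi-phi)/(1+exp(-lam*(x-x0))) + phi."""
    if Phi < phi:
        raise MetabolismError("require Phi >= phi")
    x = np.asarray(x, dtype=float)
    out = (Phi - phi) * expit(lam * (x - x0)) + phi
    return out if out.ndim else float(out)


def oxygen_uptake(O, q, params: MetabolicParams = None):
    """Oxygen consumption rate f_O (mmol/L/min)."""
    p = params or MetabolicParams()
    O = np.asarray(O, dtype=float)
    if np.any(O < 0) or not np.all(np.isfinite(O)):
        raise MetabolismError("oxygen must be finite and >= 0")
    psi = logistic_modulation(q, p.Phi_O, p.phi_O, p.lam_q, p.q_0)
    out = psi * p.V_O * O / (p.K_O + O)
    return out if np.ndim(out) else float(out)


def glucose_uptake(G, l, f_O, params: MetabolicParams = None):
    """Glucose consumption rate f_G (mmol/L/min).

    The demand term Psi_G*A_0/2 - 29*f_O/10 can turn (slightly) negative
    when respiration alone exceeds the target demand; uptake is clamped at
    zero -- cells do not excrete glucose.
    """
    p = params or MetabolicParams()
    G = np.asarray(G, dtype=float)
    f_O = np.asarray(f_O, dtype=float)
    if np.any(G < 0) or np.any(f_O < 0):
        raise MetabolismError("glucose and f_O must be >= 0")
    psi = logistic_modulation(l, p.Phi_G, p.phi_G, p.lam_l, p.l_0)
    demand = psi * p.A_0 / 2.0 - 29.0 * f_O / 10.0
    out = np.maximum(demand, 0.0) * G / (p.K_G + G)
    return out if np.ndim(out) else float(out)


def atp_rate(f_G, f_O):
    """ATP production rate f_A = 2 f_G + 29/5 f_O (mmol/L/min)."""
    f_G = np.asarray(f_G, dtype=float)
    out = 2.0 * f_G + (29.0 / 5.0) * np.asarray(f_O, dtype=float)
    return out if np.ndim(out) else float(out)


def proton_rate(f_G, k_H: float = 2.5e-4):
    """Proton secretion rate f_H = 2 f_G k_H (mmol/L/min)."""
    out = 2.0 * np.asarray(f_G, dtype=float) * k_H
    return out if np.ndim(out) else float(out)


def metabolic_rates(O, G, l, q, params: MetabolicParams = None):
    """Evaluate all four rates at once (vectorised).  Returns (f_O, f_G,
    f_A, f_H) arrays/scalars."""
    p = params or MetabolicParams()
    f_O = oxygen_uptake(O, q, p)
    f_G = glucose_uptake(G, l, f_O, p)
    return f_O, f_G, atp_rate(f_G, f_O), proton_rate(f_G, p.k_H)
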