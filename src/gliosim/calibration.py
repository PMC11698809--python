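"""Shifted-Hill parameter estimation from expression tables.

The regulation parameters (s, gamma) of each edge of the gene network can
be estimated from a bulk expression matrix by the recipe:

1. log-scale normalisation of the counts (log2(count + 1));
2. min-max interpolation of each gene to [0, 1];
3. least-squares fit of a single Hill branch -- the activating term
   Y^n/(s^n + Y^n) when the edge is an up-regulation, the inhibiting term
   s^n/(s^n + Y^n) when it is a down-regulation -- of the normalised
   regulator against the normalised target, with the Hill coefficient
   fixed at n = 4;
4. rescaling of the fitted s back to the original (log-normalised) scale;
5. gamma estimated as the fold-change of the target's expression
   (max/min for up-regulated genes, min/max for down-regulated ones).

The Shifted-Hill function S = 1 + (gamma - 1) * Y^n/(s^n + Y^n) is affine
in the single Hill branch, so min-max normalisation of the target makes
the single-branch fit exact for noise-free data.

A synthetic expression generator (regulator sampled uniformly, target on
the Shifted-Hill response with multiplicative log-normal noise) provides
parameter-recovery validation; no external data are required.  A quadratic
least-squares fitter for the collagen/speed law is included as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "ExpressionTable",
    "HillFitResult",
    "normalize_and_interpolate",
    "fit_threshold",
    "estimate_gamma",
    "fit_hill_edge",
    "generate_synthetic_expression",
    "fit_speed_polynomial",
]


class CalibrationError(ValueError):
    """Degenerate input or failed fit."""


@dataclass
class ExpressionTable:
    """Gene-by-sample non-negative count matrix."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise CalibrationError("counts must be non-negative")
        if self.counts.shape[1] < 3:
            raise CalibrationError("need at least 3 samples")

    @classmethod
    def read(cls, path, sep: Optional[str] = None) -> "ExpressionTable":
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        return cls(df)

    def write(self, path, sep: str = "\t") -> None:
        self.counts.to_csv(path, sep=sep)


@dataclass
class HillFitResult:
    """Fitted regulation parameters for one network edge."""

    s: float  # half-max threshold on the original (log-normalised) scale
    gamma: float  # fold-change regulation strength
    n: int  # Hill coefficient (fixed)
    branch: str  # "activating" or "inhibiting"
    residual: float  # sum of squared residuals of the branch fit

    def __post_init__(self) -> None:
        ok = (self.gamma > 1) == (self.branch == "activating")
        if not ok:
            raise CalibrationError("gamma > 1 must pair with the activating branch")


def _log_normalize(values: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def normalize_and_interpolate(table: ExpressionTable, gene) -> np.ndarray:
    """log2(count+1) normalisation followed by min-max interpolation of one
    gene's values to [0, 1]."""
    if gene not in table.counts.index:
        raise CalibrationError(f"gene {gene!r} not in table")
    v = _log_normalize(table.counts.loc[gene].to_numpy())
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise CalibrationError(f"gene {gene!r} has constant expression")
    return (v - lo) / (hi - lo)


def _hill_branch(Y: np.ndarray, s: float, n: int, up: bool) -> np.ndarray:
    u = (Y / s) ** n
    return u / (1.0 + u) if up else 1.0 / (1.0 + u)


def fit_threshold(
    regulator: np.ndarray,
    target: np.ndarray,
    gamma_sign: str,
    n: int = 4,
    x_range: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Least-squares fit of the half-max threshold s on [0, 1]-scale data.

    ``gamma_sign`` is "up" (activating branch) or "down" (inhibiting).
    Returns (s, residual); pass ``x_range=(x_min, x_max)`` of the original
    regulator scale to obtain s rescaled back to that scale.

    Robust 1-D search: a coarse grid over s picks the basin, then a bounded
    scalar minimisation refines it.
    """
    x = np.asarray(regulator, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise CalibrationError("need >= 3 paired regulator/target values")
    if gamma_sign not in ("up", "down"):
        raise CalibrationError("gamma_sign must be 'up' or 'down'")
    up = gamma_sign == "up"

    def sse(s: float) -> float:
        return float(np.sum((_hill_branch(x, s, n, up) - y) ** 2))

    grid = np.geomspace(1e-3, 2.0, 200)
    losses = np.array([sse(s) for s in grid])
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise CalibrationError(f"threshold fit failed: {res.message}")
    s_hat = float(res.x)
    residual = float(res.fun)
    if x_range is not None:
        x_min, x_max = x_range
        s_hat = s_hat * (x_max - x_min) + x_min
    return s_hat, residual


def estimate_gamma(values, direction: str, eps: float = 1.0) -> float:
    """Regulation strength from the fold-change of expression: max/min for
    up-regulated targets, min/max for down-regulated; a pseudo-count eps is
    added when the minimum is zero."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise CalibrationError("expression values must be >= 0")
    lo, hi = v.min(), v.max()
    if lo == 0.0:
        lo, hi = lo + eps, hi + eps
    if direction == "up":
        return float(hi / lo)
    if direction == "down":
        return float(lo / hi)
    raise CalibrationError("direction must be 'up' or 'down'")


def fit_hill_edge(
    table: ExpressionTable, regulator_gene, target_gene, direction: str, n: int = 4
) -> HillFitResult:
    """Full recipe for one edge: normalise both genes, fit the branch
    matching the regulation direction, rescale s, estimate gamma."""
    x_hat = normalize_and_interpolate(table, regulator_gene)
    y_hat = normalize_and_interpolate(table, target_gene)
    reg_log = _log_normalize(table.counts.loc[regulator_gene].to_numpy())
    tgt_log = _log_normalize(table.counts.loc[target_gene].to_numpy())
    s, residual = fit_threshold(
        x_hat, y_hat, "up" if direction == "up" else "down", n=n,
        x_range=(reg_log.min(), reg_log.max()),
    )
    gamma = estimate_gamma(tgt_log, direction)
    return HillFitResult(
        s=s,
        gamma=gamma,
        n=n,
        branch="activating" if gamma > 1 else "inhibiting",
        residual=residual,
    )


def generate_synthetic_expression(
    true_s: float,
    true_gamma: float,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    n: int = 4,
    regulator_range: Tuple[float, float] = (0.0, 16.0),
    alpha_over_d: float = 1.0,
) -> ExpressionTable:
    """Synthetic two-gene table on the Shifted-Hill response.

    The regulator's log-normalised expression is drawn uniformly over
    ``regulator_range`` (a log2 scale, so 0..16 spans typical RNA-Seq
    dynamic range); the target's log-normalised expression is
    alpha_over_d * S(regulator; true_s, true_gamma, n).  Stored counts are
    the inverse transform 2^v - 1, multiplied by log-normal measurement
    noise of standard deviation ``noise_sd`` (sequencing noise is
    multiplicative on the count scale).  ``true_s`` is on the regulator's
    (log-normalised) scale.
    """
    if n_samples < 3:
        raise CalibrationError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*regulator_range, n_samples)
    u = (x / true_s) ** n
    S = (1.0 + true_gamma * u) / (1.0 + u)
    y = alpha_over_d * S
    target_counts = 2.0**y - 1.0
    if noise_sd > 0:
        target_counts = target_counts * np.exp(rng.normal(0.0, noise_sd, n_samples))
    counts = pd.DataFrame(
        np.vstack([2.0**x - 1.0, target_counts]),
        index=["regulator", "target"],
        columns=[f"sample_{i}" for i in range(n_samples)],
    )
    return ExpressionTable(counts)


def fit_speed_polynomial(densities, speeds, normalize: bool = False) -> np.ndarray:
    """Ordinary least-squares quadratic fit speed ~ a2*C^2 + a1*C + a0.

    With ``normalize=True`` the speeds are first min-max normalised to
    [0, 1] (the preprocessing used to express the published coefficients);
    by default the fit is on the values as given.  Returns (a2, a1, a0).
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(speeds, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CalibrationError("need at least 3 (density, speed) points")
    if np.unique(x).size < 3:
        raise CalibrationError("rank-deficient design: need 3 distinct densities")
    if normalize:
        lo, hi = y.min(), y.max()
        if hi <= lo:
            raise CalibrationError("cannot normalise constant speeds")
        y = (y - lo) / (hi - lo)
    return np.polyfit(x, y, 2)
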