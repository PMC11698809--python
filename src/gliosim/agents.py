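"""Cell agents: migration, mechanics, fate rules and collagen remodelling.

Cells are off-lattice circular agents on top of the voxel grid.  Their
migration speed depends biphasically on the total collagen density
C_t = C + C_r of the voxel they occupy:

    v(C_t) = 0                                   if C_t outside [0.5, 4.0]
    v(C_t) = v0 * (-0.23 C_t^2 + 0.971 C_t - 0.048)   otherwise,

a bell-shaped law with an optimum near 2.1 mg/mL: too little collagen
offers no traction, too much obstructs movement.  Cells remodel the
collagen of their own voxel only: P4HA1 (p) drives secretion, MT1-MMP (m)
Michaelis-Menten degradation and LOX (r) cross-linking (which converts C
into degradation-resistant C_r):

    f_C  = beta_p p - beta_m m C/(K_m + C) - beta_r r C/(K_r + C)
    f_Cr =                                   beta_r r C/(K_r + C)

Fate is decided every phenotype interval from the ATP generated over that
interval and the local pH: low ATP or acidosis kills the cell (necrosis),
intermediate ATP pauses the cycle (quiescence), ample ATP lets the cell
cycle and divide, with no crowding condition on the neighbourhood.

The module exposes both a per-cell object API (:class:`Cell` plus the
single-cell operations) and the vectorised :class:`CellPopulation`
(struct-of-arrays) that the simulation engine uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .grn import GeneLevels, GrnParams, grn_derivatives
from .metabolism import MetabolicParams, MetabolicRates, metabolic_rates

__all__ = [
    "CellState",
    "Cell",
    "MotilityParams",
    "MechanicsParams",
    "FateThresholds",
    "CollagenKinetics",
    "migration_speed",
    "remodel_collagen",
    "collagen_rate_components",
    "mechanics_velocity",
    "update_motility",
    "update_phenotype",
    "CellPopulation",
    "ph_from_proton",
]


class AgentError(ValueError):
    """Domain error in an agent computation."""


class CellState:
    """Integer-coded cell states (stable codes for array storage)."""

    CYCLING = 0
    QUIESCENT = 1
    NECROTIC = 2
    REMOVED = 3

    NAMES = {0: "cycling", 1: "quiescent", 2: "necrotic", 3: "removed"}


@dataclass
class MotilityParams:
    """Biphasic collagen-dependent speed law and persistence."""

    nu_0: float = 0.8  # base speed, um/min
    window_low: float = 0.5  # permissive collagen window, mg/mL
    window_high: float = 4.0
    a2: float = -0.23  # quadratic coefficients on C_t in mg/mL
    a1: float = 0.971
    a0: float = -0.048
    persistence_time: float = 5.0  # min between direction re-draws


@dataclass
class MechanicsParams:
    """Pairwise cell-cell repulsion/adhesion (overdamped, velocities in
    um/min); adhesion_strength = 0 reproduces the no-adhesion scenario."""

    adhesion_strength: float = 0.4
    repulsion_strength: float = 10.0
    max_interaction_factor: float = 1.5  # multiple of the radii sum
    max_step_displacement: float = 6.0  # um, per-step cap for stability


@dataclass
class FateThresholds:
    """ATP/pH fate rules, as fractions of the target demand A_0 over one
    phenotype interval."""

    atp_death_fraction: float = 0.3
    atp_divide_fraction: float = 0.8
    ph_death: float = 5.6

    def __post_init__(self) -> None:
        if not (0 <= self.atp_death_fraction < self.atp_divide_fraction <= 1):
            raise AgentError("require 0 <= death fraction < divide fraction <= 1")


@dataclass
class CollagenKinetics:
    """Base rates of collagen secretion/degradation/cross-linking."""

    beta_p: float = 4.04e-6  # mg/mL/min, secretion per unit P4HA1
    beta_m: float = 2.16e-5  # mg/mL/min, degradation per unit MT1-MMP
    K_m: float = 8.7e-11  # mg/mL, half-max collagen for degradation
    beta_r: float = 2.91e-10  # mg/mL/min, cross-linking per unit LOX
    K_r: float = 6.75e-9  # mg/mL, half-max collagen for cross-linking


@dataclass
class Cell:
    """A single cell agent (object view; the engine stores populations as
    arrays)."""

    id: int = 0
    position: Tuple[float, float] = (0.0, 0.0)
    radius: float = 8.4
    state: int = CellState.CYCLING
    cycle_clock: float = 0.0
    genes: GeneLevels = field(default_factory=GeneLevels)
    rates: MetabolicRates = field(default_factory=MetabolicRates)
    atp_generated: float = 0.0
    speed: float = 0.0
    direction: Tuple[float, float] = (1.0, 0.0)
    persistence_clock: float = 0.0


def ph_from_proton(H):
    """pH of a proton concentration given in mmol/L."""
    H = np.maximum(np.asarray(H, dtype=float), 1e-30)
    out = -np.log10(H * 1e-3)
    return out if out.ndim else float(out)


def migration_speed(C_t, params: MotilityParams = None):
    """Cell migration speed (um/min) from total collagen density (mg/mL).

    Zero outside the permissive window, quadratic inside, clamped to
    [0, nu_0].  Vectorised over C_t.
    """
    p = params or MotilityParams()
    C_t = np.asarray(C_t, dtype=float)
    if np.any(C_t < 0) or not np.all(np.isfinite(C_t)):
        raise AgentError("collagen density must be finite and >= 0")
    poly = p.nu_0 * (p.a2 * C_t**2 + p.a1 * C_t + p.a0)
    inside = (C_t >= p.window_low) & (C_t <= p.window_high)
    out = np.where(inside, np.clip(poly, 0.0, p.nu_0), 0.0)
    return out if out.ndim else float(out)


def collagen_rate_components(p_level, m_level, r_level, C, kinetics: CollagenKinetics = None):
    """(secretion, degradation, cross-linking) rates in mg/mL/min for the
    occupied voxel, from the cell's current P4HA1/MT1-MMP/LOX levels."""
    k = kinetics or CollagenKinetics()
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise AgentError("collagen density must be >= 0")
    sec = k.beta_p * np.asarray(p_level, dtype=float)
    deg = k.beta_m * np.asarray(m_level, dtype=float) * C / (k.K_m + C)
    xl = k.beta_r * np.asarray(r_level, dtype=float) * C / (k.K_r + C)
    return sec, deg, xl


def remodel_collagen(cell: Cell, C: float, kinetics: CollagenKinetics = None):
    """Net collagen and cross-linked-collagen rates (f_C, f_Cr) produced by
    one cell in its own voxel."""
    sec, deg, xl = collagen_rate_components(
        cell.genes.p, cell.genes.m, cell.genes.r, C, kinetics
    )
    return float(sec - deg - xl), float(xl)


def _pair_velocity(dx, dy, dist, radii_sum, params: MechanicsParams):
    """Velocity on cell i from one neighbour j at separation (dx, dy) =
    x_i - x_j (PhysiCell-style polynomial potentials)."""
    A = params.max_interaction_factor * radii_sum
    v = 0.0
    if dist < radii_sum and params.repulsion_strength > 0:
        v += params.repulsion_strength * (1.0 - dist / radii_sum) ** 2
    if dist < A and params.adhesion_strength > 0:
        v -= params.adhesion_strength * (1.0 - dist / A) ** 2
    return v * dx / dist, v * dy / dist


def mechanics_velocity(
    cell: Cell,
    neighbors: Sequence[Cell],
    params: MechanicsParams = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Mechanical velocity (um/min) on ``cell`` from pairwise repulsion of
    overlapping neighbours and adhesion within the interaction distance.

    Coincident positions are resolved with a seeded random jitter.
    """
    p = params or MechanicsParams()
    vx = vy = 0.0
    for other in neighbors:
        if other.id == cell.id:
            continue
        dx = cell.position[0] - other.position[0]
        dy = cell.position[1] - other.position[1]
        dist = float(np.hypot(dx, dy))
        if dist == 0.0:
            rng = rng or np.random.default_rng(cell.id)
            theta = rng.uniform(0, 2 * np.pi)
            dx, dy, dist = 1e-3 * np.cos(theta), 1e-3 * np.sin(theta), 1e-3
        rsum = cell.radius + other.radius
        if dist >= p.max_interaction_factor * rsum:
            continue
        ux, uy = _pair_velocity(dx, dy, dist, rsum, p)
        vx += ux
        vy += uy
    return vx, vy


def update_motility(
    cell: Cell,
    grid,
    rng: np.random.Generator,
    dt: float,
    params: MotilityParams = None,
    mech_velocity: Tuple[float, float] = (0.0, 0.0),
) -> Cell:
    """Advance one cell's persistent random walk by dt minutes.

    Direction is re-drawn uniformly on the unit circle when the persistence
    clock expires; speed comes from the biphasic law at the local total
    collagen density.  Returns the updated cell (in place).
    """
    if cell.state in (CellState.NECROTIC, CellState.REMOVED):
        cell.speed = 0.0
        return cell
    p = params or MotilityParams()
    cell.persistence_clock -= dt
    if cell.persistence_clock <= 0:
        theta = rng.uniform(0, 2 * np.pi)
        cell.direction = (float(np.cos(theta)), float(np.sin(theta)))
        cell.persistence_clock = p.persistence_time
    iy, ix = grid.voxel_of(cell.position[0], cell.position[1])
    C_t = grid.fields["C"][iy, ix] + grid.fields["Cr"][iy, ix]
    cell.speed = float(migration_speed(C_t, p))
    x = cell.position[0] + (mech_velocity[0] + cell.speed * cell.direction[0]) * dt
    y = cell.position[1] + (mech_velocity[1] + cell.speed * cell.direction[1]) * dt
    w, h = grid.extent
    cell.position = (float(np.clip(x, 0.0, w - 1e-9)), float(np.clip(y, 0.0, h - 1e-9)))
    return cell


def update_phenotype(
    cell: Cell,
    env: Tuple[float, float, float, float],
    thresholds: FateThresholds = None,
    dt_phenotype: float = 6.0,
    metabolic: MetabolicParams = None,
    rng: Optional[np.random.Generator] = None,
    cycle_duration: float = 1080.0,
) -> Optional[Cell]:
    """Apply the ATP/pH fate rules to one cell; returns a daughter Cell if
    the cell divides, else None.

    ``env`` is the local (O, G, H, C_t).  The ATP budget accumulated since
    the last phenotype update (cell.atp_generated, mmol/L) is compared with
    fractions of the target demand A_0 * dt_phenotype.
    """
    thr = thresholds or FateThresholds()
    met = metabolic or MetabolicParams()
    if cell.state in (CellState.NECROTIC, CellState.REMOVED):
        return None
    _O, _G, H, _Ct = env
    budget = met.A_0 * dt_phenotype
    atp = cell.atp_generated
    cell.atp_generated = 0.0
    if atp < thr.atp_death_fraction * budget or ph_from_proton(H) < thr.ph_death:
        cell.state = CellState.NECROTIC
        cell.speed = 0.0
        cell.rates = MetabolicRates()
        return None
    if atp >= thr.atp_divide_fraction * budget:
        cell.state = CellState.CYCLING
        cell.cycle_clock += dt_phenotype
        if cell.cycle_clock >= cycle_duration:
            rng = rng or np.random.default_rng(cell.id)
            theta = rng.uniform(0, 2 * np.pi)
            cell.cycle_clock = 0.0
            daughter = replace(
                cell,
                id=-1,  # caller assigns
                position=(
                    cell.position[0] + cell.radius * float(np.cos(theta)),
                    cell.position[1] + cell.radius * float(np.sin(theta)),
                ),
                genes=replace(cell.genes),
                rates=MetabolicRates(),
                cycle_clock=0.0,
                atp_generated=0.0,
                persistence_clock=0.0,
            )
            return daughter
        return None
    cell.state = CellState.QUIESCENT
    return None


# ---------------------------------------------------------------------------
# Vectorised population (struct of arrays) used by the simulation engine.
# ---------------------------------------------------------------------------


class CellPopulation:
    """All cells of a simulation as parallel numpy arrays.

    Positions are continuous (um); ``genes`` has shape (n, 7) in
    grn.GENE_NAMES order.  Necrotic cells stay in the arrays (they are
    counted as dead) but never move, divide, consume or remodel.
    """

    def __init__(self, n: int = 0, radius: float = 8.4):
        self.radius_default = radius
        self.x = np.empty(n)
        self.y = np.empty(n)
        self.radius = np.full(n, radius)
        self.state = np.full(n, CellState.CYCLING, dtype=np.int8)
        self.cycle_clock = np.zeros(n)
        self.genes = np.ones((n, 7))
        self.f_O = np.zeros(n)
        self.f_G = np.zeros(n)
        self.f_A = np.zeros(n)
        self.f_H = np.zeros(n)
        self.atp_generated = np.zeros(n)
        self.speed = np.zeros(n)
        self.dir_x = np.ones(n)
        self.dir_y = np.zeros(n)
        self.persistence_clock = np.zeros(n)
        self.id = np.arange(n, dtype=np.int64)
        self._next_id = n

    # -- construction -------------------------------------------------------

    @classmethod
    def seed_disc(
        cls,
        n: int,
        center: Tuple[float, float],
        seeding_radius: float,
        rng: np.random.Generator,
        radius: float = 8.4,
        cycle_duration: float = 1080.0,
    ) -> "CellPopulation":
        """Seed n cells uniformly in a disc with randomised cycle clocks."""
        pop = cls(n, radius=radius)
        r = seeding_radius * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pop.x = center[0] + r * np.cos(th)
        pop.y = center[1] + r * np.sin(th)
        pop.cycle_clock = rng.uniform(0, cycle_duration, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        pop.dir_x, pop.dir_y = np.cos(phi), np.sin(phi)
        return pop

    def __len__(self) -> int:
        return self.x.size

    @property
    def living(self) -> np.ndarray:
        return self.state <= CellState.QUIESCENT

    @property
    def dead(self) -> np.ndarray:
        return self.state == CellState.NECROTIC

    def cell(self, i: int) -> Cell:
        """Object view of cell i (a copy, for inspection/tests)."""
        return Cell(
            id=int(self.id[i]),
            position=(float(self.x[i]), float(self.y[i])),
            radius=float(self.radius[i]),
            state=int(self.state[i]),
            cycle_clock=float(self.cycle_clock[i]),
            genes=GeneLevels.from_array(self.genes[i]),
            rates=MetabolicRates(
                float(self.f_O[i]), float(self.f_G[i]), float(self.f_A[i]), float(self.f_H[i])
            ),
            atp_generated=float(self.atp_generated[i]),
            speed=float(self.speed[i]),
            direction=(float(self.dir_x[i]), float(self.dir_y[i])),
            persistence_clock=float(self.persistence_clock[i]),
        )

    # -- engine steps --------------------------------------------------------

    def integrate_genes_step(self, O_local: np.ndarray, params: GrnParams, dt: float) -> None:
        """One RK4 step of the gene ODEs for living cells, with each cell's
        local voxel oxygen frozen over the step."""
        alive = self.living
        if not alive.any():
            return
        x = self.genes[alive]
        O = O_local[alive]
        k1 = grn_derivatives(x, O, params)
        k2 = grn_derivatives(np.maximum(x + 0.5 * dt * k1, 0.0), O, params)
        k3 = grn_derivatives(np.maximum(x + 0.5 * dt * k2, 0.0), O, params)
        k4 = grn_derivatives(np.maximum(x + dt * k3, 0.0), O, params)
        self.genes[alive] = np.maximum(x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)

    def update_metabolism(self, O_local, G_local, params: MetabolicParams, dt: float) -> None:
        """Evaluate metabolic rates for living cells and accrue ATP."""
        alive = self.living
        self.f_O.fill(0.0)
        self.f_G.fill(0.0)
        self.f_A.fill(0.0)
        self.f_H.fill(0.0)
        if not alive.any():
            return
        l = self.genes[alive, 1]
        q = self.genes[alive, 3]
        f_O, f_G, f_A, f_H = metabolic_rates(O_local[alive], G_local[alive], l, q, params)
        self.f_O[alive] = f_O
        self.f_G[alive] = f_G
        self.f_A[alive] = f_A
        self.f_H[alive] = f_H
        self.atp_generated[alive] += f_A * dt

    def pairwise_velocities(
        self, pairs: np.ndarray, params: MechanicsParams
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Mechanical velocities from a precomputed (k, 2) array of
        candidate neighbour index pairs."""
        vx = np.zeros(len(self))
        vy = np.zeros(len(self))
        if pairs.size == 0:
            return vx, vy
        i, j = pairs[:, 0], pairs[:, 1]
        dx = self.x[i] - self.x[j]
        dy = self.y[i] - self.y[j]
        dist = np.hypot(dx, dy)
        dist = np.maximum(dist, 1e-3)
        rsum = self.radius[i] + self.radius[j]
        A = params.max_interaction_factor * rsum
        v = np.zeros_like(dist)
        overlap = dist < rsum
        if params.repulsion_strength > 0:
            v[overlap] += params.repulsion_strength * (1.0 - dist[overlap] / rsum[overlap]) ** 2
        if params.adhesion_strength > 0:
            near = dist < A
            v[near] -= params.adhesion_strength * (1.0 - dist[near] / A[near]) ** 2
        ux = v * dx / dist
        uy = v * dy / dist
        np.add.at(vx, i, ux)
        np.add.at(vy, i, uy)
        np.add.at(vx, j, -ux)
        np.add.at(vy, j, -uy)
        return vx, vy

    def move(
        self,
        grid,
        rng: np.random.Generator,
        dt: float,
        motility: MotilityParams,
        mech_vx: np.ndarray,
        mech_vy: np.ndarray,
        max_step: Optional[float] = None,
    ) -> None:
        """Persistence-driven motility + mechanics displacement for dt.

        ``max_step`` caps the per-step displacement magnitude (um) so that
        coarse mechanics steps cannot overshoot a repulsive overlap.

        Living cells combine mechanics with active motility; necrotic
        cells have no motility but are still displaced passively by
        mechanical forces (corpses are pushed, not anchored).
        """
        alive = self.living
        self.persistence_clock[alive] -= dt
        expired = alive & (self.persistence_clock <= 0)
        n_new = int(expired.sum())
        if n_new:
            theta = rng.uniform(0, 2 * np.pi, n_new)
            self.dir_x[expired] = np.cos(theta)
            self.dir_y[expired] = np.sin(theta)
            self.persistence_clock[expired] = motility.persistence_time
        iy, ix = grid.voxel_of(self.x, self.y)
        C_t = grid.fields["C"][iy, ix] + grid.fields["Cr"][iy, ix]
        self.speed = np.where(alive, migration_speed(C_t, motility), 0.0)
        vx = mech_vx + self.speed * self.dir_x
        vy = mech_vy + self.speed * self.dir_y
        removed = self.state == CellState.REMOVED
        vx[removed] = 0.0
        vy[removed] = 0.0
        dx = vx * dt
        dy = vy * dt
        if max_step is not None:
            step = np.hypot(dx, dy)
            over = step > max_step
            if over.any():
                f = max_step / step[over]
                dx[over] *= f
                dy[over] *= f
        w, h = grid.extent
        self.x = np.clip(self.x + dx, 0.0, w - 1e-9)
        self.y = np.clip(self.y + dy, 0.0, h - 1e-9)

    def update_phenotypes(
        self,
        H_local: np.ndarray,
        thresholds: FateThresholds,
        metabolic: MetabolicParams,
        dt_phenotype: float,
        rng: np.random.Generator,
        cycle_duration: float = 1080.0,
    ) -> int:
        """Fate rules for all living cells; performs divisions in place and
        returns the number of daughters created."""
        alive = self.living
        budget = metabolic.A_0 * dt_phenotype
        atp = self.atp_generated.copy()
        self.atp_generated.fill(0.0)

        dies = alive & (
            (atp < thresholds.atp_death_fraction * budget)
            | (ph_from_proton(H_local) < thresholds.ph_death)
        )
        self.state[dies] = CellState.NECROTIC
        self.speed[dies] = 0.0
        for arr in (self.f_O, self.f_G, self.f_A, self.f_H):
            arr[dies] = 0.0

        alive = self.living
        high = alive & (atp >= thresholds.atp_divide_fraction * budget)
        mid = alive & ~high
        self.state[mid] = CellState.QUIESCENT
        self.state[high] = CellState.CYCLING
        self.cycle_clock[high] += dt_phenotype

        dividing = np.flatnonzero(high & (self.cycle_clock >= cycle_duration))
        if dividing.size == 0:
            return 0
        self.cycle_clock[dividing] = 0.0
        theta = rng.uniform(0, 2 * np.pi, dividing.size)
        dx = self.radius[dividing] * np.cos(theta)
        dy = self.radius[dividing] * np.sin(theta)
        self._append_daughters(dividing, dx, dy)
        return dividing.size

    def _append_daughters(self, parents: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> None:
        k = parents.size
        self.x = np.concatenate([self.x, self.x[parents] + dx])
        self.y = np.concatenate([self.y, self.y[parents] + dy])
        self.radius = np.concatenate([self.radius, self.radius[parents]])
        self.state = np.concatenate(
            [self.state, np.full(k, CellState.CYCLING, dtype=np.int8)]
        )
        self.cycle_clock = np.concatenate([self.cycle_clock, np.zeros(k)])
        self.genes = np.concatenate([self.genes, self.genes[parents].copy()])
        for name in ("f_O", "f_G", "f_A", "f_H", "atp_generated", "speed"):
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(k)]))
        self.dir_x = np.concatenate([self.dir_x, self.dir_x[parents]])
        self.dir_y = np.concatenate([self.dir_y, self.dir_y[parents]])
        self.persistence_clock = np.concatenate([self.persistence_clock, np.zeros(k)])
        self.id = np.concatenate(
            [self.id, np.arange(self._next_id, self._next_id + k, dtype=np.int64)]
        )
        self._next_id += k
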