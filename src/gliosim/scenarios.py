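"""Scenario construction, the simulation loop and analysis metrics.

A scenario fully determines one simulation: domain geometry, initial and
boundary fields, genetic parameter overrides, seeds and duration.  The
engine advances the coupled system with operator splitting:

  each diffusion step (dt_diffusion):
    1. Dirichlet boundary driver (oscillating oxygen protocol);
    2. implicit diffusion of O, G, H;
    3. per-cell gene ODE step (RK4, local voxel oxygen frozen);
    4. per-cell metabolic rates; ATP accrual; collagen remodelling rates;
    5. per-voxel source application (clamped, collagen-conserving);
  each mechanics step (dt_mechanics):
    6. pairwise repulsion/adhesion + persistent random-walk motility;
  each phenotype step (dt_phenotype):
    7. ATP/pH fate rules -- necrosis, quiescence, division.

Analysis metrics follow the study design: counts by state, tumour radius
of the proliferative and necrotic layers, metabolic-state classification
from LDH/PDH levels, and Warburg-phenotype detection (high proton export
at normoxic local oxygen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import microenv
from ._kernels import bin_cells, pair_forces
from .agents import (
    CellPopulation,
    CellState,
    CollagenKinetics,
    FateThresholds,
    MechanicsParams,
    MotilityParams,
    collagen_rate_components,
)
from .grn import GENE_NAMES, GrnParams
from .metabolism import MetabolicParams, logistic_modulation
from .microenv import BoundaryProtocol, SourceTerms, boundary_value

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioConfig",
    "MetricsReport",
    "build_scenario",
    "scaled_config",
    "warburg_study_config",
    "run_simulation",
    "tumor_radius",
    "classify_metabolic_state",
    "warburg_cells",
    "default_warburg_fh_bound",
]


class ScenarioError(ValueError):
    """Unknown scenario or inconsistent configuration."""


SCENARIO_NAMES = (
    "reference",
    "bigel",
    "restricted_oxygen",
    "bigel_restricted",
    "complex_matrix",
    "no_adhesion",
    "low_hif_degradation",
    "high_pdh_inhibition",
    "oscillating_oxygen",
    "high_pdh_inhibition_oscillating",
)


@dataclass
class ScenarioConfig:
    """Complete declarative description of one simulation."""

    name: str = "reference"
    # geometry
    nx: int = 75
    ny: int = 75
    voxel_size: float = 20.0  # um
    # duration and seeds
    duration_min: float = 14 * 24 * 60.0
    seed: int = 0
    # inoculum
    n_initial_cells: int = 50
    seeding_radius: float = 60.0  # um
    cell_radius: float = 8.4  # um
    cycle_duration: float = 1080.0  # min (18 h fixed-duration cycle)
    # initial collagen field
    collagen_mode: str = "uniform"  # uniform | bigel | complex
    collagen_density: float = 2.5  # mg/mL (uniform)
    collagen_soft: float = 2.5  # mg/mL (bigel, lower half)
    collagen_stiff: float = 5.0  # mg/mL (bigel, upper half)
    collagen_lo: float = 0.5  # mg/mL (complex matrix)
    collagen_hi: float = 4.0
    # boundaries
    boundary: BoundaryProtocol = field(default_factory=BoundaryProtocol)
    # parameter overrides / sub-models
    grn_overrides: Dict[str, float] = field(default_factory=dict)
    metabolic_overrides: Dict[str, float] = field(default_factory=dict)
    motility: MotilityParams = field(default_factory=MotilityParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    fate: FateThresholds = field(default_factory=FateThresholds)
    collagen_kinetics: CollagenKinetics = field(default_factory=CollagenKinetics)
    diffusion: Optional[Dict[str, float]] = None
    # time stepping (min)
    dt_diffusion: float = 0.01
    dt_mechanics: float = 0.1
    dt_phenotype: float = 6.0
    # output
    snapshot_interval: float = 720.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3 or self.voxel_size <= 0:
            raise ScenarioError("non-positive or degenerate domain")
        if self.duration_min < 0:
            raise ScenarioError("duration must be >= 0")
        for big, small in ((self.dt_mechanics, self.dt_diffusion),
                           (self.dt_phenotype, self.dt_diffusion)):
            if big < small or abs(round(big / small) - big / small) > 1e-9:
                raise ScenarioError("dt_mechanics and dt_phenotype must be "
                                    "multiples of dt_diffusion")

    @property
    def center(self) -> Tuple[float, float]:
        return self.nx * self.voxel_size / 2.0, self.ny * self.voxel_size / 2.0

    def resolved_grn(self) -> GrnParams:
        return GrnParams().with_overrides(self.grn_overrides)

    def resolved_metabolic(self) -> MetabolicParams:
        return MetabolicParams().with_overrides(self.metabolic_overrides)


def build_scenario(name: str, **overrides) -> ScenarioConfig:
    """Named scenario -> fully specified config.

    Keyword overrides are applied on top of the named preset (unknown names
    raise, listing the valid ones).
    """
    if name not in SCENARIO_NAMES:
        raise ScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    cfg = ScenarioConfig(name=name)
    if name == "bigel":
        cfg.collagen_mode = "bigel"
    elif name == "restricted_oxygen":
        cfg.boundary = BoundaryProtocol(mode="restricted")
    elif name == "bigel_restricted":
        cfg.collagen_mode = "bigel"
        cfg.boundary = BoundaryProtocol(mode="restricted")
    elif name == "complex_matrix":
        cfg.collagen_mode = "complex"
    elif name == "no_adhesion":
        cfg.mechanics = MechanicsParams(adhesion_strength=0.0)
    elif name == "low_hif_degradation":
        cfg.grn_overrides = {"gamma_O_h": 17.5}
    elif name == "high_pdh_inhibition":
        cfg.grn_overrides = {"gamma_k_q": 0.14}
    elif name == "oscillating_oxygen":
        cfg.boundary = BoundaryProtocol(mode="oscillating")
    elif name == "high_pdh_inhibition_oscillating":
        cfg.grn_overrides = {"gamma_k_q": 0.14}
        cfg.boundary = BoundaryProtocol(mode="oscillating")
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ScenarioError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


def scaled_config(name: str, seed: int = 0, days: float = 7.0, **overrides) -> ScenarioConfig:
    """Reduced-scale study configuration for quick comparative runs.

    A 1980x1980 um domain of 30-um voxels seeded with a 100-cell disc, run
    for 7 days with coarser (still stable, implicit) time steps.  Uptake
    and secretion act on whole-voxel concentrations, so the coarser voxels
    strengthen the per-cell sink; together with the enlarged inoculum this
    lets the tumour reach the oxygen-drawdown length scale -- and develop
    the hypoxic/glycolytic core that drives the comparative claims --
    within the shortened run, while the domain stays large enough to hold
    the final population at physical packing densities.
    """
    cfg = build_scenario(
        name,
        nx=66,
        ny=66,
        voxel_size=30.0,
        duration_min=days * 24 * 60.0,
        seed=seed,
        n_initial_cells=100,
        seeding_radius=80.0,
        dt_diffusion=3.0,
        dt_mechanics=3.0,
        dt_phenotype=6.0,
        snapshot_interval=240.0,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ScenarioError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


def warburg_study_config(name: str = "high_pdh_inhibition_oscillating",
                         seed: int = 0, days: float = 7.0, **overrides) -> ScenarioConfig:
    """Scaled configuration for the oscillating-oxygen metabolic studies.

    Same domain and steps as :func:`scaled_config` but with a denser
    500-cell inoculum -- the oxygen drawdown that lets cells surface
    briefly above the hypoxia threshold with their glycolytic program
    still active takes a 14-day tumour mass at full scale, which the
    larger inoculum recreates within 7 days -- and 120-min snapshots so
    the short reoxygenation windows around each normoxic peak are
    sampled.
    """
    cfg = scaled_config(
        name, seed=seed, days=days,
        n_initial_cells=500, seeding_radius=200.0, snapshot_interval=120.0,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ScenarioError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

SNAPSHOT_COLUMNS = (
    ["id", "x", "y", "state"] + list(GENE_NAMES) + ["speed", "f_H", "local_O"]
)


@dataclass
class MetricsReport:
    """Per-timepoint counts/radii and per-cell snapshot records."""

    config: ScenarioConfig
    times: List[float] = field(default_factory=list)
    counts: Dict[str, List[int]] = field(
        default_factory=lambda: {k: [] for k in
                                 ("cycling", "quiescent", "necrotic", "living",
                                  "dead", "total")}
    )
    radius_proliferative: List[float] = field(default_factory=list)
    radius_necrotic: List[float] = field(default_factory=list)
    snapshots: Dict[float, pd.DataFrame] = field(default_factory=dict)
    collagen_secreted: float = 0.0
    collagen_degraded: float = 0.0
    final_grid: object = None

    @property
    def final_cells(self) -> pd.DataFrame:
        return self.snapshots[max(self.snapshots)]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, **self.counts,
                             "radius_proliferative": self.radius_proliferative,
                             "radius_necrotic": self.radius_necrotic})

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(d / "timeseries.csv", index=False)
        for t, df in self.snapshots.items():
            df.to_csv(d / f"cells_t{int(t):07d}.csv", index=False)


def tumor_radius(cells, layer: str, center: Tuple[float, float]) -> float:
    """Max Euclidean distance (um) from the seeding centre over the cells
    of one layer ("proliferative" = cycling, "necrotic").

    Returns NaN for an empty layer.
    """
    if layer == "proliferative":
        want = CellState.CYCLING
    elif layer == "necrotic":
        want = CellState.NECROTIC
    else:
        raise ScenarioError("layer must be 'proliferative' or 'necrotic'")
    if isinstance(cells, CellPopulation):
        mask = cells.state == want
        x, y = cells.x[mask], cells.y[mask]
    else:
        sel = cells[cells["state"] == want]
        x, y = sel["x"].to_numpy(), sel["y"].to_numpy()
    if x.size == 0:
        return float("nan")
    return float(np.hypot(x - center[0], y - center[1]).max())


def classify_metabolic_state(l, q, grn_params: GrnParams = None) -> np.ndarray:
    """Classify cells as "oxidative", "glycolytic" or "intermediate" from
    their LDH (l) and PDH (q) levels.

    Thresholds sit at the midpoint of each gene's attainable fixed-point
    range: l in [alpha/d, alpha*gamma_hl/d], q between its S=1 fixed point
    and its maximal-regulation fixed point.  High-LDH/low-PDH cells are
    glycolytic, low-LDH/high-PDH oxidative, everything else intermediate.
    """
    p = grn_params or GrnParams()
    scalar = np.ndim(l) == 0 and np.ndim(q) == 0
    l = np.atleast_1d(np.asarray(l, dtype=float))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    l_lo = p.alpha_l / p.d_l
    l_hi = p.alpha_l * p.gamma_h_l / p.d_l
    q_a = p.alpha_q / p.d_q
    q_b = p.alpha_q * p.gamma_k_q / p.d_q
    l_thr = 0.5 * (l_lo + l_hi)
    q_thr = 0.5 * (q_a + q_b)
    l_high = l >= l_thr
    q_high = q >= q_thr
    out = np.full(l.shape, "intermediate", dtype=object)
    out[l_high & ~q_high] = "glycolytic"
    out[~l_high & q_high] = "oxidative"
    return str(out[0]) if scalar else out


def default_warburg_fh_bound(params: MetabolicParams = None) -> float:
    """Default proton-rate bound: half the theoretical maximal glycolytic
    proton rate 2*k_H*(Phi_G*A_0/2)."""
    p = params or MetabolicParams()
    return 0.5 * 2.0 * p.k_H * (p.Phi_G * p.A_0 / 2.0)


HYPOXIA_THRESHOLD = 0.02085  # mmol/L, 2% O2


def warburg_cells(
    records: pd.DataFrame,
    o_threshold: float = HYPOXIA_THRESHOLD,
    fh_bound: Optional[float] = None,
    params: MetabolicParams = None,
) -> pd.DataFrame:
    """Subset of living cells flagged as Warburg: local oxygen above the
    hypoxia threshold AND proton export above the bound (elevated
    glycolysis in normoxia)."""
    if fh_bound is None:
        fh_bound = default_warburg_fh_bound(params)
    living = records["state"] <= CellState.QUIESCENT
    flag = living & (records["local_O"] > o_threshold) & (records["f_H"] > fh_bound)
    return records[flag]


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def _mechanics_velocities(pop: CellPopulation, mech: MechanicsParams, extent):
    """Pairwise velocities for the whole population via the binned numba
    kernel (bin size = maximal interaction distance)."""
    w, h = extent
    mbin = mech.max_interaction_factor * 2.0 * float(pop.radius.max(initial=8.4))
    mnx = max(1, int(np.ceil(w / mbin)))
    mny = max(1, int(np.ceil(h / mbin)))
    ixm = np.minimum((pop.x / mbin).astype(np.int64), mnx - 1)
    iym = np.minimum((pop.y / mbin).astype(np.int64), mny - 1)
    order, starts = bin_cells(iym * mnx + ixm, mnx * mny)
    vx = np.zeros(len(pop))
    vy = np.zeros(len(pop))
    pair_forces(pop.x, pop.y, pop.radius, order, starts, mnx, mny, mbin,
                mech.adhesion_strength, mech.repulsion_strength,
                mech.max_interaction_factor, vx, vy)
    return vx, vy


def _snapshot(pop: CellPopulation, grid) -> pd.DataFrame:
    iy, ix = grid.voxel_of(pop.x, pop.y)
    data = {
        "id": pop.id,
        "x": pop.x,
        "y": pop.y,
        "state": pop.state.astype(int),
    }
    for g, name in enumerate(GENE_NAMES):
        data[name] = pop.genes[:, g]
    data["speed"] = pop.speed
    data["f_H"] = pop.f_H
    data["local_O"] = grid.fields["O"][iy, ix]
    return pd.DataFrame(data, columns=SNAPSHOT_COLUMNS)


def _record(report: MetricsReport, t: float, pop: CellPopulation, grid, center) -> None:
    st = pop.state
    counts = report.counts
    counts["cycling"].append(int((st == CellState.CYCLING).sum()))
    counts["quiescent"].append(int((st == CellState.QUIESCENT).sum()))
    counts["necrotic"].append(int((st == CellState.NECROTIC).sum()))
    counts["living"].append(int(pop.living.sum()))
    counts["dead"].append(int(pop.dead.sum()))
    counts["total"].append(len(pop))
    report.times.append(t)
    report.radius_proliferative.append(tumor_radius(pop, "proliferative", center))
    report.radius_necrotic.append(tumor_radius(pop, "necrotic", center))
    report.snapshots[t] = _snapshot(pop, grid)


def run_simulation(config: ScenarioConfig, grid=None) -> MetricsReport:
    """Run one scenario to completion and return its metrics report.

    Deterministic under a fixed config.seed (one PRNG drives seeding,
    motility and division directions).  Numerical blow-up aborts with the
    last recorded snapshot preserved in the report.
    """
    rng = np.random.default_rng(config.seed)
    if grid is None:
        grid = microenv.init_grid(config)
    grn = config.resolved_grn()
    met = config.resolved_metabolic()
    center = config.center
    pop = CellPopulation.seed_disc(
        config.n_initial_cells,
        center,
        config.seeding_radius,
        rng,
        radius=config.cell_radius,
        cycle_duration=config.cycle_duration,
    )
    w, h = grid.extent
    pop.x = np.clip(pop.x, 0.0, w - 1e-9)
    pop.y = np.clip(pop.y, 0.0, h - 1e-9)

    dtd = config.dt_diffusion
    mech_every = int(round(config.dt_mechanics / dtd))
    phen_every = int(round(config.dt_phenotype / dtd))
    snap_every = max(1, int(round(config.snapshot_interval / dtd)))
    nsteps = int(round(config.duration_min / dtd))
    oscillating = config.boundary.mode == "oscillating"

    report = MetricsReport(config=config)
    _record(report, 0.0, pop, grid, center)
    nvox = grid.ny * grid.nx

    try:
        for k in range(1, nsteps + 1):
            t = k * dtd
            if oscillating:
                grid.set_oxygen_dirichlet_value(boundary_value(config.boundary, t))

            iy, ix = grid.voxel_of(pop.x, pop.y)
            flat = iy * grid.nx + ix
            alive = pop.living
            flat_alive = flat[alive]

            # oxygen: implicit diffusion with linearised per-voxel uptake
            psi_O = logistic_modulation(
                pop.genes[alive, 3], met.Phi_O, met.phi_O, met.lam_q, met.q_0
            ) * met.V_O
            refresh = (k - 1) % 4 == 0
            vmax_O = np.bincount(flat_alive, weights=psi_O, minlength=nvox)
            U_O = vmax_O / (met.K_O + grid.fields["O"].ravel())
            microenv.uptake_diffuse_step(grid, "O", dtd, U_O, refresh=refresh)
            O_loc = grid.fields["O"].ravel()[flat]

            # per-cell oxygen consumption at the relaxed field
            pop.f_O.fill(0.0)
            pop.f_O[alive] = psi_O * O_loc[alive] / (met.K_O + O_loc[alive])

            # glucose: demand-driven uptake, implicit as well
            psi_G = logistic_modulation(
                pop.genes[alive, 1], met.Phi_G, met.phi_G, met.lam_l, met.l_0
            )
            demand = np.maximum(psi_G * met.A_0 / 2.0 - 2.9 * pop.f_O[alive], 0.0)
            dem_vox = np.bincount(flat_alive, weights=demand, minlength=nvox)
            U_G = dem_vox / (met.K_G + grid.fields["G"].ravel())
            microenv.uptake_diffuse_step(grid, "G", dtd, U_G, refresh=refresh)
            G_loc = grid.fields["G"].ravel()[flat]

            pop.f_G.fill(0.0)
            pop.f_G[alive] = demand * G_loc[alive] / (met.K_G + G_loc[alive])
            pop.f_A = 2.0 * pop.f_G + (29.0 / 5.0) * pop.f_O
            pop.f_H = 2.0 * pop.f_G * met.k_H
            pop.atp_generated += pop.f_A * dtd

            # protons: implicit diffusion with secretion in the RHS, so the
            # sampled field is the diffused quasi-steady one
            h_src = np.bincount(flat, weights=pop.f_H, minlength=nvox).reshape(grid.ny, grid.nx)
            microenv.source_diffuse_step(grid, "H", dtd, h_src)

            pop.integrate_genes_step(O_loc, grn, dtd)
            C_loc = grid.fields["C"].ravel()[flat]
            sec = np.zeros(len(pop))
            deg = np.zeros(len(pop))
            xl = np.zeros(len(pop))
            if alive.any():
                s_, d_, x_ = collagen_rate_components(
                    pop.genes[alive, 4], pop.genes[alive, 5], pop.genes[alive, 6],
                    C_loc[alive], config.collagen_kinetics,
                )
                sec[alive], deg[alive], xl[alive] = s_, d_, x_
            zeros = np.zeros((grid.ny, grid.nx))
            sums = SourceTerms(
                f_O=zeros,  # O/G uptake and H secretion applied in the solves
                f_G=zeros,
                f_H=zeros,
                sec_C=np.bincount(flat, weights=sec, minlength=nvox).reshape(grid.ny, grid.nx),
                deg_C=np.bincount(flat, weights=deg, minlength=nvox).reshape(grid.ny, grid.nx),
                xl_C=np.bincount(flat, weights=xl, minlength=nvox).reshape(grid.ny, grid.nx),
            )
            microenv.apply_sources(grid, sums, dtd)

            if k % mech_every == 0:
                vx, vy = _mechanics_velocities(pop, config.mechanics, (w, h))
                pop.move(grid, rng, config.dt_mechanics, config.motility, vx, vy,
                         max_step=config.mechanics.max_step_displacement)

            if k % phen_every == 0:
                iy, ix = grid.voxel_of(pop.x, pop.y)
                H_loc = grid.fields["H"][iy, ix]
                n_new = pop.update_phenotypes(
                    H_loc, config.fate, met, config.dt_phenotype, rng,
                    cycle_duration=config.cycle_duration,
                )
                if n_new:
                    pop.x = np.clip(pop.x, 0.0, w - 1e-9)
                    pop.y = np.clip(pop.y, 0.0, h - 1e-9)

            if k % snap_every == 0 or k == nsteps:
                if report.times and report.times[-1] == t:
                    pass
                else:
                    _record(report, t, pop, grid, center)
    except FloatingPointError:
        pass  # abort on blow-up; report holds the last good snapshot
    report.collagen_secreted = grid.collagen_secreted
    report.collagen_degraded = grid.collagen_degraded
    report.final_grid = grid
    return report
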