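"""2D voxel microenvironment: diffusible fields and collagen.

The lattice carries three diffusible concentrations -- oxygen O, glucose G
and protons H (all mmol/L) -- evolved by

    dF/dt = D_F * laplacian(F) +/- sources,

plus two non-diffusing, non-decaying matrix fields: collagen C and
cross-linked collagen C_r (mg/mL), changed only by cell-driven secretion,
degradation and cross-linking.

Diffusion uses an implicit backward-Euler step of the 5-point Laplacian
(zero-flux at edges unless a Dirichlet value is pinned there), solved with
a cached sparse LU factorisation -- unconditionally stable, and the system
matrix is an M-matrix so non-negativity is preserved exactly.  Dirichlet
boundary voxels are pinned by identity rows, which makes time-varying
boundary values (the oscillating-oxygen driver) a pure right-hand-side
update with no refactorisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "DIFFUSIBLES",
    "DEFAULT_DIFFUSION",
    "INITIAL_CONCENTRATIONS",
    "BoundaryProtocol",
    "SourceTerms",
    "VoxelGrid",
    "init_grid",
    "diffuse_step",
    "uptake_diffuse_step",
    "apply_sources",
    "boundary_value",
]

DIFFUSIBLES = ("O", "G", "H")

#: Diffusion coefficients, um^2/min.
DEFAULT_DIFFUSION = {"O": 109_200.0, "G": 30_000.0, "H": 270_000.0}

#: Initial (and default Dirichlet) concentrations, mmol/L:
#: normoxia (5% O2), serum glucose, pH 7.4.
INITIAL_CONCENTRATIONS = {"O": 0.056, "G": 5.0, "H": 3.98e-5}

#: 1% O2 expressed in mmol/L by linear scaling of the 5% <-> 0.056 mapping.
OXYGEN_1_PERCENT = 0.056 / 5.0


class GridError(ValueError):
    """Invalid grid configuration or solver failure."""


@dataclass
class BoundaryProtocol:
    """Dirichlet boundary driver for the diffusible fields.

    mode:
      * ``constant``    -- all four edges at the normoxic values;
      * ``restricted``  -- oxygen pinned on top and bottom edges only
                           (left/right become zero-flux for O); G and H
                           stay pinned on all four edges;
      * ``oscillating`` -- the oxygen edge value follows a continuous
                           triangular wave from ``o2_high`` (5% O2) down to
                           ``o2_low`` (1% O2) and back, each ramp lasting
                           ``ramp_min`` minutes (period = 2*ramp_min).
    """

    mode: str = "constant"
    o2_high: float = INITIAL_CONCENTRATIONS["O"]
    o2_low: float = OXYGEN_1_PERCENT
    ramp_min: float = 360.0
    glucose: float = INITIAL_CONCENTRATIONS["G"]
    proton: float = INITIAL_CONCENTRATIONS["H"]

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "restricted", "oscillating"):
            raise GridError(f"unknown boundary mode {self.mode!r}")
        if self.mode == "oscillating" and self.ramp_min <= 0:
            raise GridError("ramp duration must be > 0")


def boundary_value(protocol: BoundaryProtocol, t: float) -> float:
    """Oxygen Dirichlet value (mmol/L) at time t (min)."""
    if t < 0:
        raise GridError("t must be >= 0")
    if protocol.mode != "oscillating":
        return protocol.o2_high
    period = 2.0 * protocol.ramp_min
    phase = t % period
    hi, lo, ramp = protocol.o2_high, protocol.o2_low, protocol.ramp_min
    if phase <= ramp:  # down-ramp
        return hi + (lo - hi) * phase / ramp
    return lo + (hi - lo) * (phase - ramp) / ramp


@dataclass
class SourceTerms:
    """Per-voxel source/sink rates aggregated over the cells in each voxel
    (units per minute).  Collagen is split into its secretion, degradation
    and cross-linking components so that the grid can keep exact mass
    bookkeeping when a voxel runs out of collagen."""

    f_O: np.ndarray
    f_G: np.ndarray
    f_H: np.ndarray
    sec_C: np.ndarray
    deg_C: np.ndarray
    xl_C: np.ndarray

    @property
    def f_C(self) -> np.ndarray:
        """Net collagen rate (secretion - degradation - cross-linking)."""
        return self.sec_C - self.deg_C - self.xl_C

    @property
    def f_Cr(self) -> np.ndarray:
        return self.xl_C

    @classmethod
    def zeros(cls, shape) -> "SourceTerms":
        return cls(*(np.zeros(shape) for _ in range(6)))


class VoxelGrid:
    """Square-voxel 2D lattice of field values.

    Fields are arrays of shape (ny, nx); a cell at continuous position
    (x, y) in um lives in voxel (iy, ix) = floor(y/voxel_size),
    floor(x/voxel_size).
    """

    def __init__(
        self,
        nx: int,
        ny: int,
        voxel_size: float = 20.0,
        diffusion: Optional[Dict[str, float]] = None,
    ):
        if nx < 3 or ny < 3 or voxel_size <= 0:
            raise GridError("grid must be at least 3x3 voxels with positive voxel size")
        self.nx, self.ny = int(nx), int(ny)
        self.voxel_size = float(voxel_size)
        self.diffusion = dict(DEFAULT_DIFFUSION, **(diffusion or {}))
        shape = (self.ny, self.nx)
        self.fields: Dict[str, np.ndarray] = {
            "O": np.full(shape, INITIAL_CONCENTRATIONS["O"]),
            "G": np.full(shape, INITIAL_CONCENTRATIONS["G"]),
            "H": np.full(shape, INITIAL_CONCENTRATIONS["H"]),
            "C": np.full(shape, 2.5),
            "Cr": np.zeros(shape),
        }
        self.dirichlet_mask: Dict[str, np.ndarray] = {
            name: np.zeros(shape, dtype=bool) for name in DIFFUSIBLES
        }
        self.dirichlet_values: Dict[str, np.ndarray] = {
            name: np.zeros(shape) for name in DIFFUSIBLES
        }
        # cumulative collagen bookkeeping (mg/mL summed over voxels)
        self.collagen_secreted = 0.0
        self.collagen_degraded = 0.0
        self._solvers: Dict[Tuple[str, float], object] = {}

    # -- geometry -----------------------------------------------------------

    @property
    def extent(self) -> Tuple[float, float]:
        """Domain size (width, height) in um."""
        return self.nx * self.voxel_size, self.ny * self.voxel_size

    def voxel_of(self, x, y) -> Tuple[np.ndarray, np.ndarray]:
        """(iy, ix) voxel indices of continuous positions in um."""
        ix = np.clip((np.asarray(x) / self.voxel_size).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.voxel_size).astype(int), 0, self.ny - 1)
        return iy, ix

    # -- Dirichlet machinery ------------------------------------------------

    def set_edge_dirichlet(self, name: str, value: float, sides=("top", "bottom", "left", "right")):
        """Pin a field's boundary voxels to a fixed value on given sides."""
        mask = self.dirichlet_mask[name]
        vals = self.dirichlet_values[name]
        for side in sides:
            if side == "top":
                sl = (self.ny - 1, slice(None))
            elif side == "bottom":
                sl = (0, slice(None))
            elif side == "left":
                sl = (slice(None), 0)
            elif side == "right":
                sl = (slice(None), self.nx - 1)
            else:
                raise GridError(f"unknown side {side!r}")
            mask[sl] = True
            vals[sl] = value
        self._solvers = {k: v for k, v in self._solvers.items() if k[0] != name}

    def set_oxygen_dirichlet_value(self, value: float) -> None:
        """Update the pinned oxygen value (oscillating driver); the mask is
        unchanged so no refactorisation is needed."""
        m = self.dirichlet_mask["O"]
        self.dirichlet_values["O"][m] = value

    # -- diffusion ----------------------------------------------------------

    def _laplacian(self) -> sp.csr_matrix:
        """5-point Laplacian with zero-flux edges, units 1/um^2."""
        ny, nx, h2 = self.ny, self.nx, self.voxel_size**2
        idx = np.arange(ny * nx).reshape(ny, nx)
        rows, cols, vals = [], [], []
        for shift in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            dy, dx = shift
            src = idx[max(0, -dy): ny - max(0, dy), max(0, -dx): nx - max(0, dx)]
            dst = idx[max(0, dy): ny - max(0, -dy), max(0, dx): nx - max(0, -dx)]
            rows.append(src.ravel())
            cols.append(dst.ravel())
            vals.append(np.full(src.size, 1.0 / h2))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        L = sp.coo_matrix((vals, (rows, cols)), shape=(ny * nx, ny * nx)).tocsr()
        L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
        return L.tocsr()

    def _base_matrix(self, name: str, dt: float) -> sp.csc_matrix:
        """(I - dt*D*L) with Dirichlet rows pinned to identity (unfactored)."""
        key = ("base", name, float(dt))
        if key not in self._solvers:
            n = self.ny * self.nx
            A = sp.identity(n, format="csr") - dt * self.diffusion[name] * self._laplacian()
            mask = self.dirichlet_mask[name].ravel()
            if mask.any():
                A = A.tolil()
                for i in np.flatnonzero(mask):
                    A.rows[i] = [i]
                    A.data[i] = [1.0]
            self._solvers[key] = A.tocsc()
        return self._solvers[key]

    def _solver(self, name: str, dt: float):
        key = (name, float(dt))
        if key not in self._solvers:
            n = self.ny * self.nx
            A = sp.identity(n, format="csr") - dt * self.diffusion[name] * self._laplacian()
            mask = self.dirichlet_mask[name].ravel()
            if mask.any():
                A = A.tolil()
                pinned = np.flatnonzero(mask)
                for i in pinned:
                    A.rows[i] = [i]
                    A.data[i] = [1.0]
                A = A.tocsc()
            else:
                A = A.tocsc()
            self._solvers[key] = splu(A)
        return self._solvers[key]

    # -- export --------------------------------------------------------------

    def save_fields(self, directory, t: float = 0.0) -> None:
        """Write each field as CSV with a sidecar text header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        units = {"O": "mmol/L", "G": "mmol/L", "H": "mmol/L", "C": "mg/mL", "Cr": "mg/mL"}
        for name, arr in self.fields.items():
            np.savetxt(directory / f"{name}.csv", arr, delimiter=",")
            header = (
                f"field: {name}\nunits: {units[name]}\ntime_min: {t}\n"
                f"nx: {self.nx}\nny: {self.ny}\nvoxel_size_um: {self.voxel_size}\n"
                "layout: rows are y (row 0 = bottom edge), columns are x\n"
            )
            (directory / f"{name}.header.txt").write_text(header)


def init_grid(config) -> VoxelGrid:
    """Build the initial microenvironment for a scenario.

    ``config`` provides nx, ny, voxel_size, boundary (a BoundaryProtocol),
    collagen_mode in {"uniform", "bigel", "complex"} and a seed for the
    random complex matrix.
    """
    grid = VoxelGrid(config.nx, config.ny, config.voxel_size,
                     diffusion=getattr(config, "diffusion", None))
    # initial diffusible fields already set to normoxic defaults
    mode = getattr(config, "collagen_mode", "uniform")
    if mode == "uniform":
        grid.fields["C"][:] = getattr(config, "collagen_density", 2.5)
    elif mode == "bigel":
        soft = getattr(config, "collagen_soft", 2.5)
        stiff = getattr(config, "collagen_stiff", 5.0)
        grid.fields["C"][: grid.ny // 2, :] = soft
        grid.fields["C"][grid.ny // 2:, :] = stiff
    elif mode == "complex":
        rng = np.random.default_rng(getattr(config, "seed", 0))
        lo = getattr(config, "collagen_lo", 0.5)
        hi = getattr(config, "collagen_hi", 4.0)
        grid.fields["C"][:] = rng.uniform(lo, hi, size=(grid.ny, grid.nx))
    else:
        raise GridError(f"unknown collagen mode {mode!r}")
    grid.fields["Cr"][:] = 0.0

    protocol: BoundaryProtocol = config.boundary
    o_sides = ("top", "bottom") if protocol.mode == "restricted" else (
        "top", "bottom", "left", "right")
    grid.set_edge_dirichlet("O", boundary_value(protocol, 0.0), sides=o_sides)
    grid.set_edge_dirichlet("G", protocol.glucose)
    grid.set_edge_dirichlet("H", protocol.proton)
    return grid


def diffuse_step(grid: VoxelGrid, dt: float, fields: Tuple[str, ...] = DIFFUSIBLES) -> VoxelGrid:
    """Advance the diffusible fields by one implicit diffusion step (in
    place).

    Collagen fields are untouched (they neither diffuse nor decay).
    """
    if dt <= 0:
        raise GridError("dt must be > 0")
    for name in fields:
        f = grid.fields[name]
        mask = grid.dirichlet_mask[name]
        rhs = f.copy()
        rhs[mask] = grid.dirichlet_values[name][mask]
        x = grid._solver(name, dt).solve(rhs.ravel())
        if not np.all(np.isfinite(x)):
            raise GridError(f"diffusion solve produced non-finite {name} field")
        grid.fields[name] = x.reshape(grid.ny, grid.nx)
    return grid


def uptake_diffuse_step(
    grid: VoxelGrid, name: str, dt: float, uptake: np.ndarray, refresh: bool = True
) -> None:
    """One implicit step of diffusion coupled to linearised cell uptake.

    ``uptake`` is the per-voxel first-order uptake coefficient (min^-1),
    i.e. the Michaelis-Menten consumption divided by the local
    concentration; solving (I - dt*D*lap + dt*diag(U)) F_new = F_old keeps
    the scheme unconditionally stable and lets the field relax to the true
    reaction-diffusion quasi-steady state even at coarse dt, where an
    explicit (clamped) sink would be overwhelmed by the fast diffusion.
    Dirichlet voxels keep their pinned values (uptake masked there).
    ``refresh=False`` reuses the factorisation from the previous call for
    this field (the uptake map evolves on the slow cell timescale, so a
    slightly stale sink is a good approximation and saves the
    refactorisation).
    """
    if dt <= 0:
        raise GridError("dt must be > 0")
    key = ("uptake_lu", name)
    lu = grid._solvers.get(key)
    if refresh or lu is None:
        base = grid._base_matrix(name, dt)
        u = np.asarray(uptake, dtype=float).ravel().copy()
        u[grid.dirichlet_mask[name].ravel()] = 0.0
        lu = splu(base + sp.diags(dt * u, format="csc"))
        grid._solvers[key] = lu
    f = grid.fields[name]
    rhs = f.copy()
    mask = grid.dirichlet_mask[name]
    rhs[mask] = grid.dirichlet_values[name][mask]
    x = lu.solve(rhs.ravel())
    if not np.all(np.isfinite(x)):
        raise GridError(f"uptake-diffusion solve produced non-finite {name} field")
    grid.fields[name] = x.reshape(grid.ny, grid.nx)


def source_diffuse_step(grid: VoxelGrid, name: str, dt: float, source: np.ndarray) -> None:
    """One implicit diffusion step with an explicit secretion source folded
    into the right-hand side: (I - dt*D*lap) F_new = F_old + dt*S.

    Sampling F_new gives cells the diffused (quasi-steady) concentration
    rather than a transient undiluted spike in a crowded voxel.
    """
    if dt <= 0:
        raise GridError("dt must be > 0")
    f = grid.fields[name]
    rhs = f + dt * np.asarray(source, dtype=float)
    mask = grid.dirichlet_mask[name]
    rhs[mask] = grid.dirichlet_values[name][mask]
    x = grid._solver(name, dt).solve(rhs.ravel())
    if not np.all(np.isfinite(x)):
        raise GridError(f"source-diffusion solve produced non-finite {name} field")
    grid.fields[name] = x.reshape(grid.ny, grid.nx)


def apply_sources(grid: VoxelGrid, sums: SourceTerms, dt: float) -> VoxelGrid:
    """Apply aggregated cell source/sink terms over dt (in place).

    Oxygen and glucose consumption are clamped so fields stay >= 0.
    Collagen removal (degradation + cross-linking) in a voxel is scaled
    down proportionally if it would overdraw the available collagen; the
    cross-linked amount always moves to C_r, so C + C_r changes exactly by
    secretion - degradation (cross-linking conserves the total).
    """
    if dt <= 0:
        raise GridError("dt must be > 0")
    grid.fields["O"] = np.maximum(grid.fields["O"] - sums.f_O * dt, 0.0)
    grid.fields["G"] = np.maximum(grid.fields["G"] - sums.f_G * dt, 0.0)
    grid.fields["H"] = grid.fields["H"] + sums.f_H * dt

    C = grid.fields["C"]
    sec = sums.sec_C * dt
    removal = (sums.deg_C + sums.xl_C) * dt
    avail = C + sec
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(removal > avail, avail / np.where(removal > 0, removal, 1.0), 1.0)
    deg = sums.deg_C * dt * scale
    xl = sums.xl_C * dt * scale
    grid.fields["C"] = np.maximum(avail - deg - xl, 0.0)
    grid.fields["Cr"] = grid.fields["Cr"] + xl
    grid.collagen_secreted += float(sec.sum())
    grid.collagen_degraded += float(deg.sum())
    return grid
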