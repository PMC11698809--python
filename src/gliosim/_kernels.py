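"""Numba hot loops for the simulation engine.

Only the cell-cell force sum lives here: it is the one O(n * neighbours)
computation that dominates large populations.  Everything else in the
engine is numpy-vectorised.
"""

from __future__ import annotations

import numba
import numpy as np


def bin_cells(flat_voxel: np.ndarray, nvox: int):
    """CSR-style binning of cells by voxel: returns (order, starts) where
    order[starts[v]:starts[v+1]] are the cell indices in voxel v."""
    order = np.argsort(flat_voxel, kind="stable").astype(np.int64)
    counts = np.bincount(flat_voxel, minlength=nvox)
    starts = np.zeros(nvox + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    return order, starts


@numba.njit(fastmath=True)
def pair_forces(x, y, radius, order, starts, nx, ny, voxel_size,
                adhesion, repulsion, max_factor, vx, vy):  # pragma: no cover
    """PhysiCell-style pairwise velocities via 3x3 voxel neighbourhoods.

    Requires voxel_size >= the maximal interaction distance so that all
    interacting neighbours sit in adjacent voxels.
    """
    n = x.size
    for i in range(n):
        xi = x[i]
        yi = y[i]
        ri = radius[i]
        ix = int(xi / voxel_size)
        iy = int(yi / voxel_size)
        if ix < 0:
            ix = 0
        elif ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy > ny - 1:
            iy = ny - 1
        accx = 0.0
        accy = 0.0
        for dy in range(-1, 2):
            jy = iy + dy
            if jy < 0 or jy >= ny:
                continue
            for dx in range(-1, 2):
                jx = ix + dx
                if jx < 0 or jx >= nx:
                    continue
                v0 = jy * nx + jx
                for s in range(starts[v0], starts[v0 + 1]):
                    j = order[s]
                    if j == i:
                        continue
                    ddx = xi - x[j]
                    ddy = yi - y[j]
                    dist = (ddx * ddx + ddy * ddy) ** 0.5
                    if dist < 1e-6:
                        # coincident: deterministic tiny push along +x
                        ddx, ddy, dist = 1e-3, 0.0, 1e-3
                    rsum = ri + radius[j]
                    amax = max_factor * rsum
                    if dist >= amax:
                        continue
                    v = 0.0
                    if dist < rsum:
                        u = 1.0 - dist / rsum
                        v += repulsion * u * u
                    u2 = 1.0 - dist / amax
                    v -= adhesion * u2 * u2
                    accx += v * ddx / dist
                    accy += v * ddy / dist
        vx[i] = accx
        vy[i] = accy
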