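"""Wall-shear-stress extraction and the y+ wall-resolution check.

The deviatoric stress is computed locally from the non-equilibrium second
moment: eps_ij = -Pi_ij / (2 rho tau c_s^2), sigma_ij = 2 mu eps_ij.  The
traction sigma . n at a wall-adjacent cell is projected onto the tangent
plane (the pressure part drops out of the projection) and reported in Pa
through the unit map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lattice import UnitMap
from .geometry import VoxelGrid
from .kernel import equilibrium, moments, _pi_neq

__all__ = ["WallSampleSet", "wall_stress", "y_plus"]


@dataclass
class WallSampleSet:
    """Per-wall-adjacent-cell normals, tractions and shear magnitudes."""

    indices: np.ndarray        # flat cell indices
    normals: np.ndarray        # (n, d), unit outward
    traction: np.ndarray       # (n, d), tangential traction, Pa
    shear_mag: np.ndarray      # (n,), Pa
    wall_distance: np.ndarray  # (n,), m (distance of cell center to wall)

    def max_shear(self) -> float:
        return float(self.shear_mag.max()) if len(self.shear_mag) else 0.0


def wall_stress(f: np.ndarray, grid: VoxelGrid, nu_lattice: float,
                unit_map: UnitMap) -> WallSampleSet:
    """Sample the tangential wall traction at every wall-adjacent cell.

    Cells with degenerate normals (isolated voxels) are skipped with a
    warning.
    """
    desc = grid.desc
    tau = 3.0 * nu_lattice + 0.5
    rho, u = moments(f, desc)
    feq = equilibrium(rho, u, desc)
    pi = _pi_neq(f, feq, desc)                     # (d, d, *s)
    eps = -pi / (2.0 * rho * tau * desc.cs2)        # strain rate, lattice
    mu_lat = rho * nu_lattice
    sigma = 2.0 * mu_lat * eps                      # deviatoric stress, lattice

    idx = grid.wall_adjacent_indices()
    shape = grid.shape
    d = desc.dim
    normals_field = grid.normals.reshape(-1, d)
    n = normals_field[idx]
    good = np.linalg.norm(n, axis=1) > 0.5
    if not good.all():
        warnings.warn(f"skipping {np.count_nonzero(~good)} wall samples with "
                      "degenerate normals", stacklevel=2)
    idx = idx[good]
    n = n[good]

    sig_flat = sigma.reshape(d, d, -1)[:, :, idx]   # (d, d, n)
    t_full = np.einsum("ijn,nj->ni", sig_flat, n)   # traction sigma.n
    t_norm = np.einsum("ni,ni->n", t_full, n)
    t_tan = t_full - t_norm[:, None] * n
    scale = unit_map.pressure_scale
    shear = np.linalg.norm(t_tan, axis=1) * scale
    dist = grid.sdf.reshape(-1)[idx] * unit_map.dx
    return WallSampleSet(indices=idx, normals=n, traction=t_tan * scale,
                         shear_mag=shear, wall_distance=dist)


def y_plus(shear_pa: float, wall_distance_m: float,
           nu_phys: float, rho_phys: float = 1050.0) -> float:
    """Dimensionless wall distance y+ = y sqrt(tau_w / rho) / nu."""
    if shear_pa < 0:
        raise ValueError("wall shear magnitude must be >= 0")
    u_tau = np.sqrt(shear_pa / rho_phys)
    return wall_distance_m * u_tau / nu_phys
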