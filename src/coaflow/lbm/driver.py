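"""Time-stepping drivers and the mesh-refinement harness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np

from .lattice import UnitMap
from .geometry import VoxelGrid, INLET, OUTLET0
from .kernel import (equilibrium, moments, collide_smagorinsky, stream,
                     bouzidi_boundary, velocity_inlet, StabilityError)
from .wall import wall_stress, WallSampleSet

__all__ = ["MacroSnapshot", "FluctuationAccumulator", "run_pulsatile",
           "run_channel_force", "refinement_check"]


@dataclass
class MacroSnapshot:
    step: int
    time: float            # s
    rho: np.ndarray        # lattice units
    u: np.ndarray          # (*shape, d), lattice units
    wall: Optional[WallSampleSet] = None

    def u_phys(self, unit_map: UnitMap) -> np.ndarray:
        return self.u * unit_map.velocity_scale


class FluctuationAccumulator:
    """Running mean / second-moment accumulator for velocity fluctuations.

    After feeding snapshots, ``tke(rho)`` returns the turbulent kinetic
    energy field 0.5 rho sum_i <u_i'^2> and ``rss(rho, i, j)`` the Reynolds
    stress rho <u_i' u_j'>.
    """

    def __init__(self) -> None:
        self.n = 0
        self._sum = None
        self._sum_outer = None

    def add(self, u: np.ndarray) -> None:
        if self._sum is None:
            self._sum = np.zeros_like(u)
            d = u.shape[-1]
            self._sum_outer = np.zeros(u.shape[:-1] + (d, d))
        self._sum += u
        self._sum_outer += u[..., :, None] * u[..., None, :]
        self.n += 1

    def mean(self) -> np.ndarray:
        return self._sum / self.n

    def covariance(self) -> np.ndarray:
        m = self.mean()
        return self._sum_outer / self.n - m[..., :, None] * m[..., None, :]

    def tke(self, rho: float = 1.0) -> np.ndarray:
        cov = self.covariance()
        return 0.5 * rho * np.trace(cov, axis1=-2, axis2=-1)

    def rss(self, rho: float = 1.0, i: int = 0, j: int = 1) -> np.ndarray:
        return rho * self.covariance()[..., i, j]


def _init_field(grid: VoxelGrid) -> np.ndarray:
    shape = grid.shape
    rho0 = np.ones(shape)
    u0 = np.zeros(shape + (grid.desc.dim,))
    return equilibrium(rho0, u0, grid.desc)


def _apply_outlet(f: np.ndarray, grid: VoxelGrid) -> None:
    """Zero-gradient outlet with density pinned to 1: copy the neighbouring
    interior populations and rescale to the target density."""
    ax = grid.inlet_axis
    out = grid.flags == OUTLET0
    if not out.any():
        return
    desc = grid.desc
    f_nb = np.roll(f, shift=1, axis=1 + ax)  # interior neighbor along axis
    rho_nb = f_nb.sum(axis=0)
    w = desc.w.reshape((-1,) + (1,) * (f.ndim - 1))
    corr = f_nb + w * (1.0 - rho_nb)[None]
    f[:, out] = corr[:, out]


def run_pulsatile(grid: VoxelGrid, unit_map: UnitMap,
                  inlet_waveform: Callable[[float], float], n_steps: int,
                  les_on: bool = True, c_smag: float = 0.1,
                  snapshot_every: int = 0, sample_wall: bool = False,
                  inlet_profile: str = "plug",
                  f0: Optional[np.ndarray] = None) -> List[MacroSnapshot]:
    """Collide -> wall boundary -> stream -> inlet/outlet loop.

    ``inlet_waveform`` maps physical time (s) to a mean inlet velocity
    (m/s); the spatial profile is a plug (optionally parabolic) over the
    inlet plane.  Snapshots (macroscopic fields, optional wall samples) are
    recorded every ``snapshot_every`` steps plus the final step.  Divergence
    (NaN or non-positive density) aborts with the step index.
    """
    desc = grid.desc
    nu = unit_map.nu_lattice
    cs = c_smag if les_on else 0.0
    f = _init_field(grid) if f0 is None else f0.copy()
    fluid = grid.fluid_mask
    snaps: List[MacroSnapshot] = []
    inlet_mask = grid.flags == INLET
    profile = None
    if inlet_mask.any() and inlet_profile == "parabolic":
        profile = _parabolic_profile(grid, inlet_mask)
    for step in range(1, n_steps + 1):
        t_phys = step * unit_map.dt
        f_post = collide_smagorinsky(f, desc, nu, cs,
                                     fluid_mask=fluid[None] if fluid is not None else None)
        f_new = stream(f_post, grid)
        f_new = bouzidi_boundary(f_new, f_post, grid)
        if inlet_mask.any():
            u_lat = inlet_waveform(t_phys) / unit_map.velocity_scale
            target = np.zeros(desc.dim)
            target[grid.inlet_axis] = u_lat
            f_new = velocity_inlet(f_new, grid, target,
                                   tau=3.0 * nu + 0.5)
        _apply_outlet(f_new, grid)
        f = f_new
        rho = f.sum(axis=0)
        if step % 50 == 0 or step == n_steps:
            bad = ~np.isfinite(rho[fluid]) | (rho[fluid] <= 0)
            if bad.any():
                raise StabilityError(f"diverged at step {step}")
        if (snapshot_every and step % snapshot_every == 0) or step == n_steps:
            rho_s, u_s = moments(f, desc)
            wall = wall_stress(f, grid, nu, unit_map) if sample_wall else None
            snaps.append(MacroSnapshot(step=step, time=t_phys, rho=rho_s,
                                       u=u_s, wall=wall))
    return snaps


def _parabolic_profile(grid: VoxelGrid, inlet_mask: np.ndarray) -> np.ndarray:
    sdf_plane = grid.sdf[inlet_mask]
    r = sdf_plane / sdf_plane.max()
    return 2.0 * (1.0 - (1.0 - r) ** 2)


def run_channel_force(grid: VoxelGrid, nu_lattice: float, n_steps: int,
                      force: Callable[[int], np.ndarray],
                      c_smag: float = 0.0, snapshot_every: int = 0,
                      f0: Optional[np.ndarray] = None):
    """Body-force-driven periodic run (benchmark configurations).

    ``force(step)`` returns the lattice body-force vector for that step.
    Returns ``(f, snapshots)``; snapshots are (step, rho, u) tuples.
    """
    desc = grid.desc
    f = _init_field(grid) if f0 is None else f0.copy()
    fluid = grid.fluid_mask
    snaps = []
    for step in range(1, n_steps + 1):
        f_post = collide_smagorinsky(f, desc, nu_lattice, c_smag,
                                     force=force(step), fluid_mask=fluid[None])
        f_new = stream(f_post, grid)
        f_new = bouzidi_boundary(f_new, f_post, grid)
        f = f_new
        if (snapshot_every and step % snapshot_every == 0) or step == n_steps:
            rho, u = moments(f, desc)
            snaps.append((step, rho, u))
    return f, snaps


def refinement_check(run_at_resolution: Callable[[int], dict],
                     base_resolution: int, factor: float = 1.5) -> dict:
    """Rerun a case at ``factor`` x resolution and report relative changes.

    ``run_at_resolution(n)`` must return a dict with ``peak_velocity`` and
    ``pressure_drop``.  Mirrors the usual mesh-acceptance protocol: the mesh
    passes when both change by less than 2%.
    """
    coarse = run_at_resolution(base_resolution)
    fine = run_at_resolution(int(round(base_resolution * factor)))
    out = {"coarse": coarse, "fine": fine}
    for key in ("peak_velocity", "pressure_drop"):
        denom = abs(fine[key]) if fine[key] != 0 else 1.0
        out[f"delta_{key}"] = abs(fine[key] - coarse[key]) / denom
    out["accepted"] = (out["delta_peak_velocity"] < 0.02
                       and out["delta_pressure_drop"] < 0.02)
    return out
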