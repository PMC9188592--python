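"""Collision, streaming and boundary operators.

Populations are stored as ``f[alpha, *spatial]``.  Collision is
single-relaxation-time BGK; the Smagorinsky closure raises the local
relaxation time from the magnitude of the non-equilibrium second moment.
Curved walls use the Bouzidi interpolated bounce-back; the inlet imposes a
velocity with equilibrium + regularized off-equilibrium parts built from
finite-difference velocity gradients.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np

from .lattice import LatticeDescriptor
from .geometry import VoxelGrid, INLET

__all__ = ["equilibrium", "moments", "collide_smagorinsky", "stream",
           "bouzidi_boundary", "velocity_inlet", "smooth_startup",
           "outlet_split", "smagorinsky_tau"]


class StabilityError(RuntimeError):
    pass


def equilibrium(rho: np.ndarray, u: np.ndarray,
                desc: LatticeDescriptor) -> np.ndarray:
    """Second-order Maxwellian equilibrium.

    ``rho``: (*spatial), ``u``: (*spatial, d) -> f_eq (Q, *spatial).
    Zeroth/first moments reproduce rho and rho*u exactly.
    """
    cu = np.tensordot(desc.c, np.moveaxis(u, -1, 0), axes=([1], [0]))  # (Q, *s)
    usq = np.sum(u * u, axis=-1)
    feq = desc.w.reshape((-1,) + (1,) * rho.ndim) * rho * (
        1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
    return feq


def moments(f: np.ndarray, desc: LatticeDescriptor):
    """Density and velocity fields from populations."""
    rho = f.sum(axis=0)
    mom = np.tensordot(desc.c.T, f, axes=([1], [0]))  # (d, *s)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rho > 0, mom / rho, 0.0)
    return rho, np.moveaxis(u, 0, -1)


def smagorinsky_tau(tau0: float, pi_mag: np.ndarray, rho: np.ndarray,
                    c_smag: float) -> np.ndarray:
    """Effective relaxation time from the Smagorinsky closure.

    Solves tau_eff^2 - tau0 tau_eff - 18 C_s^2 |Pi| / rho = 0 (filter width
    = one cell, c_s^2 = 1/3), where |Pi| = sqrt(2 Pi_ij Pi_ij).
    """
    return 0.5 * (tau0 + np.sqrt(tau0 * tau0 + 18.0 * c_smag**2 * pi_mag / rho))


def _pi_neq(f: np.ndarray, feq: np.ndarray, desc: LatticeDescriptor) -> np.ndarray:
    """Non-equilibrium second moment Pi_ij, shape (d, d, *spatial)."""
    fneq = f - feq
    d = desc.dim
    shape = f.shape[1:]
    pi = np.empty((d, d) + shape)
    for i in range(d):
        for j in range(i, d):
            cc = (desc.c[:, i] * desc.c[:, j]).reshape((-1,) + (1,) * len(shape))
            pi[i, j] = (cc * fneq).sum(axis=0)
            pi[j, i] = pi[i, j]
    return pi


def collide_smagorinsky(f: np.ndarray, desc: LatticeDescriptor,
                        nu0_lattice: float, c_smag: float = 0.1,
                        force: Optional[np.ndarray] = None,
                        fluid_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """BGK collision with a per-cell Smagorinsky eddy viscosity.

    With ``c_smag=0`` this is bit-identical to plain BGK at tau0 = 3 nu0 +
    1/2.  ``force`` is a constant body force per unit mass (lattice units),
    applied with the Guo scheme.  Raises :class:`StabilityError` when the
    effective relaxation time would drop to 0.5 or below.
    """
    tau0 = 3.0 * nu0_lattice + 0.5
    if tau0 <= 0.5:
        raise StabilityError(f"tau0 = {tau0} <= 0.5")
    rho, u = moments(f, desc)
    if force is not None:
        # half-force velocity shift (Guo): u* = (sum f c + F/2) / rho
        u = u + 0.5 * np.asarray(force) / rho[..., None]
    feq = equilibrium(rho, u, desc)
    if c_smag > 0.0:
        pi = _pi_neq(f, feq, desc)
        pi_mag = np.sqrt(2.0 * np.einsum("ij...,ij...->...", pi, pi))
        tau = smagorinsky_tau(tau0, pi_mag, rho, c_smag)
    else:
        tau = tau0
    omega = 1.0 / tau
    out = f - omega * (f - feq)
    if force is not None:
        fvec = np.asarray(force)
        cu = np.tensordot(desc.c, np.moveaxis(u, -1, 0), axes=([1], [0]))
        cf = np.tensordot(desc.c, fvec, axes=([1], [0])).reshape(
            (-1,) + (1,) * rho.ndim)
        uf = np.sum(u * fvec, axis=-1)
        w = desc.w.reshape((-1,) + (1,) * rho.ndim)
        guo = w * (1.0 - 0.5 * omega) * (3.0 * (cf - uf) + 9.0 * cu * cf)
        out = out + guo * rho
    if fluid_mask is not None:
        out = np.where(fluid_mask, out, f)
    return out


def stream(f: np.ndarray, grid: Optional[VoxelGrid] = None,
           desc: Optional[LatticeDescriptor] = None) -> np.ndarray:
    """Advect each population one cell along its velocity (periodic wrap).

    Wall/inlet corrections are applied separately after streaming.
    """
    if desc is None:
        desc = grid.desc
    out = np.empty_like(f)
    axes = tuple(range(f.ndim - 1))
    for alpha in range(desc.q):
        out[alpha] = np.roll(f[alpha], shift=tuple(desc.c[alpha]), axis=axes)
    return out


def bouzidi_boundary(f_streamed: np.ndarray, f_post: np.ndarray,
                     grid: VoxelGrid) -> np.ndarray:
    """Overwrite populations entering from walls with Bouzidi values.

    ``f_post`` is the post-collision (pre-streaming) field.  For a fluid
    cell A whose link alpha hits the wall at fraction q:

    * q < 1/2:  f_opp(A) = 2q f_a^c(A) + (1 - 2q) f_a^c(E),  E = A - c_a
    * q >= 1/2: f_opp(A) = 1/(2q) f_a^c(A) + (2q - 1)/(2q) f_opp^c(A)

    Both branches coincide with plain bounce-back at q = 1/2.  Links whose
    upstream neighbour E is unavailable fall back to plain bounce-back.
    """
    desc = grid.desc
    nspace = f_streamed[0].size
    flat = f_streamed.reshape(desc.q, nspace)
    flat_post = f_post.reshape(desc.q, nspace)
    for alpha, rec in grid.wall_links.items():
        beta = desc.opp[alpha]
        idx, q, idx_e, e_valid = rec["idx"], rec["q"], rec["idx_e"], rec["e_valid"]
        fa = flat_post[alpha, idx]
        val = np.empty_like(fa)
        low = q < 0.5
        if low.any():
            fe = np.where(e_valid, flat_post[alpha, idx_e], fa)
            val_low = 2.0 * q * fa + (1.0 - 2.0 * q) * fe
            # fallback: without a valid upstream neighbour use bounce-back
            val_low = np.where(e_valid, val_low, fa)
            val[low] = val_low[low]
        high = ~low
        if high.any():
            fb = flat_post[beta, idx]
            val[high] = (fa / (2.0 * q) + (2.0 * q - 1.0) / (2.0 * q) * fb)[high]
        flat[beta, idx] = val
    return flat.reshape(f_streamed.shape)


def velocity_inlet(f: np.ndarray, grid: VoxelGrid, target_u: np.ndarray,
                   desc: Optional[LatticeDescriptor] = None,
                   tau: float = 1.0) -> np.ndarray:
    """Impose a velocity on the inlet plane (regularized reconstruction).

    The prescribed velocity is written into the inlet nodes as equilibrium
    plus an off-equilibrium part built from second-order finite-difference
    velocity gradients; the inlet density is copied from the nearest bulk
    node (plane + 1), which also covers corner/edge nodes.
    """
    desc = desc or grid.desc
    ax = grid.inlet_axis
    inlet = grid.flags == INLET
    if not inlet.any():
        return f
    rho, u = moments(f, desc)
    # nearest-bulk density: shift one plane inward along the inlet axis
    rho_bulk = np.roll(rho, shift=-1, axis=ax)
    u_set = np.array(u, copy=True)
    u_set[inlet] = np.broadcast_to(target_u, u[inlet].shape)
    # second-order FD strain rate of the imposed/ambient field
    grads = [np.gradient(u_set[..., i]) for i in range(desc.dim)]
    d = desc.dim
    fneq = np.zeros_like(f)
    w = desc.w.reshape((-1,) + (1,) * rho.ndim)
    for i in range(d):
        for j in range(d):
            s_ij = 0.5 * (grads[i][j] + grads[j][i])
            q_ij = (desc.c[:, i] * desc.c[:, j]
                    - (1.0 / 3.0) * (1.0 if i == j else 0.0))
            fneq += (q_ij.reshape((-1,) + (1,) * rho.ndim)
                     * s_ij[None]) * w
    fneq *= -3.0 * rho[None] * tau
    feq = equilibrium(rho_bulk, u_set, desc)
    new = feq + fneq
    f = np.where(inlet[None], new, f)
    return f


def smooth_startup(waveform: Callable[[float], float], t_ramp: float
                   ) -> Callable[[float], float]:
    """Prepend a quarter-sine ramp from zero to ``waveform(0)``.

    The returned callable is continuous at the junction: during the ramp the
    value is waveform(0) * sin(pi/2 * t / t_ramp); afterwards the original
    waveform runs with its clock shifted by ``t_ramp``.  The maximum ramp
    slope is (pi/2) * waveform(0) / t_ramp.
    """
    if t_ramp <= 0:
        raise ValueError("t_ramp must be > 0")
    u0 = waveform(0.0)

    def ramped(t: float) -> float:
        if t < t_ramp:
            return u0 * math.sin(0.5 * math.pi * t / t_ramp)
        return waveform(t - t_ramp)

    return ramped


def outlet_split(total_q: float, outlet_areas) -> np.ndarray:
    """Distribute a total flow over outlets by relative cross-section:
    q_k = Q * A_k / sum(A)."""
    areas = np.asarray(outlet_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one outlet")
    if np.any(areas <= 0):
        raise ValueError("areas must be > 0")
    return total_q * areas / areas.sum()
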