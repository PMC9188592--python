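"""Analytic flow benchmarks for the lattice kernel.

Each function sets up a canonical configuration, runs the kernel, and
returns the simulated and closed-form (oracle) quantities so callers can
judge the agreement themselves.  Lattice units unless noted.
"""

from __future__ import annotations

import math

import numpy as np

from .lattice import D2Q9, D3Q19, UnitMap
from .geometry import channel_2d, straight_tube, constricted_tube
from .kernel import (equilibrium, moments, collide_smagorinsky, stream,
                     bouzidi_boundary)
from .driver import run_channel_force, run_pulsatile
from .wall import wall_stress

__all__ = ["poiseuille_channel", "womersley_channel", "womersley_profile",
           "bouzidi_equals_bounceback", "tube_poiseuille_error",
           "stenosis_throat_speedup", "channel_refinement"]


def _channel_geometry(ny: int, desc, nx: int = 4, wall_offset: float = 2.0):
    grid = channel_2d(nx, ny, desc, wall_offset=wall_offset)
    h = ny / 2.0 - wall_offset  # half-width, cells
    y = np.arange(ny) + 0.5
    return grid, h, y, ny / 2.0


def poiseuille_channel(ny: int = 48, nu: float = 0.05, g: float = 1e-6,
                       n_steps: int = None) -> dict:
    """Body-force-driven plane Poiseuille flow vs the parabolic solution.

    Also reports the wall shear against the analytic tau_w = g h (momentum
    balance); the wall-stress routine runs with an identity unit map so the
    Pa values equal lattice values here.
    """
    desc = D2Q9()
    grid, h, y, half = _channel_geometry(ny, desc)
    if n_steps is None:
        n_steps = int(12.0 * h * h / nu)
    f, snaps = run_channel_force(grid, nu, n_steps,
                                 lambda s: np.array([g, 0.0]))
    _, rho, u = snaps[-1]
    ux = u[2, :, 0]
    fluid = grid.fluid_mask[2]
    analytic = g / (2.0 * nu) * (h**2 - (y - half) ** 2)
    center_sim = float(ux[fluid].max())
    center_ref = float(g * h * h / (2.0 * nu))
    unit_identity = UnitMap(dx=1.0, nu_phys=nu, nu_lattice=nu, rho_phys=1.0)
    samples = wall_stress(f, grid, nu, unit_identity)
    tau_sim = float(np.median(samples.shear_mag))
    tau_ref = g * h
    return {
        "centerline_sim": center_sim, "centerline_ref": center_ref,
        "centerline_rel_err": abs(center_sim - center_ref) / center_ref,
        "profile_rel_err": float(np.abs(ux[fluid] - analytic[fluid]).max()
                                 / center_ref),
        "wall_shear_sim": tau_sim, "wall_shear_ref": tau_ref,
        "wall_shear_rel_err": abs(tau_sim - tau_ref) / tau_ref,
        "cells_across_gap": int(np.count_nonzero(fluid)),
    }


def womersley_profile(y: np.ndarray, t: float, g_amp: float, omega: float,
                      nu: float, h: float) -> np.ndarray:
    """Analytic oscillatory channel flow driven by G cos(omega t).

    u(y, t) = Re[(G / (i omega)) (1 - cosh(lam y)/cosh(lam h)) e^{i omega t}],
    lam = sqrt(i omega / nu); y measured from the channel center.
    """
    lam = np.sqrt(1j * omega / nu)
    prof = (g_amp / (1j * omega)) * (1.0 - np.cosh(lam * y) / np.cosh(lam * h))
    return np.real(prof * np.exp(1j * omega * t))


def womersley_channel(wo: float = 3.0, ny: int = 42, nu: float = 0.05,
                      g_amp: float = 1e-6, n_periods: int = 5,
                      samples_per_period: int = 32) -> dict:
    """Oscillating body-force channel flow vs the analytic series.

    The Womersley number Wo = h sqrt(omega/nu) sets the frequency.  The
    amplitude envelope over the last period is compared with the analytic
    envelope; the error is reported relative to the peak amplitude.
    """
    desc = D2Q9()
    grid, h, y, half = _channel_geometry(ny, desc)
    omega = wo * wo * nu / (h * h)
    period = int(round(2.0 * math.pi / omega))
    warmup = (n_periods - 1) * period

    def force(step):
        return np.array([g_amp * math.cos(omega * step), 0.0])

    f, _ = run_channel_force(grid, nu, warmup, force)
    fluid = grid.fluid_mask[2]
    stride = max(period // samples_per_period, 1)
    yc = y - half
    sim_profiles, ref_profiles = [], []
    for k in range(warmup, warmup + period):
        f_post = collide_smagorinsky(f, desc, nu, 0.0, force=force(k + 1),
                                     fluid_mask=grid.fluid_mask[None])
        f_new = stream(f_post, grid)
        f = bouzidi_boundary(f_new, f_post, grid)
        if (k - warmup) % stride == 0:
            _, u = moments(f, desc)
            sim_profiles.append(u[2, :, 0].copy())
            # Guo half-force shift: flow lags the force clock by half a step
            ref_profiles.append(
                womersley_profile(yc, k + 1.5, g_amp, omega, nu, h))
    sim_amp = np.max(np.abs(np.array(sim_profiles)[:, fluid]), axis=0)
    ref_amp = np.max(np.abs(np.array(ref_profiles)[:, fluid]), axis=0)
    peak = ref_amp.max()
    return {
        "womersley_number": wo,
        "amplitude_rel_err": float(np.abs(sim_amp - ref_amp).max() / peak),
        "peak_amplitude_sim": float(sim_amp.max()),
        "peak_amplitude_ref": float(peak),
    }


def bouzidi_equals_bounceback(n_steps: int = 50) -> dict:
    """With all wall fractions q = 1/2 the interpolated scheme must reduce
    to plain bounce-back bit-for-bit."""
    desc = D2Q9()
    # wall_offset = 2.0 puts the wall midway between the last solid and the
    # first fluid cell center -> q = 1/2 on every wall link
    grid = channel_2d(6, 20, desc, wall_offset=2.0)
    for rec in grid.wall_links.values():
        assert np.allclose(rec["q"], 0.5), "fixture must give q = 1/2"
    rng = np.random.default_rng(42)
    rho0 = 1.0 + 0.01 * rng.random(grid.shape)
    u0 = 0.02 * (rng.random(grid.shape + (2,)) - 0.5)
    u0[~grid.fluid_mask] = 0.0
    f_a = equilibrium(rho0, u0, desc)
    f_b = f_a.copy()
    max_diff = 0.0
    for _ in range(n_steps):
        post_a = collide_smagorinsky(f_a, desc, 0.05, 0.0,
                                     fluid_mask=grid.fluid_mask[None])
        f_a = bouzidi_boundary(stream(post_a, grid), post_a, grid)
        post_b = collide_smagorinsky(f_b, desc, 0.05, 0.0,
                                     fluid_mask=grid.fluid_mask[None])
        sb = stream(post_b, grid)
        # plain bounce-back reference: reflect the post-collision population
        flat = sb.reshape(desc.q, -1)
        flat_post = post_b.reshape(desc.q, -1)
        for alpha, rec in grid.wall_links.items():
            flat[desc.opp[alpha], rec["idx"]] = flat_post[alpha, rec["idx"]]
        f_b = flat.reshape(sb.shape)
        max_diff = max(max_diff, float(np.abs(f_a - f_b).max()))
    return {"max_abs_difference": max_diff}


def tube_poiseuille_error(radius: float, nu: float = 0.05,
                          g: float = 1e-7) -> float:
    """Relative centerline error of Poiseuille flow in a circular tube.

    The cylindrical wall cuts lattice links at a spread of fractions q, so
    this exercises the full interpolated bounce-back (u_max = g R^2 / 4 nu).
    """
    desc = D3Q19()
    grid = straight_tube(4, radius, desc)
    n_steps = int(10.0 * radius * radius / nu)
    f, snaps = run_channel_force(grid, nu, n_steps,
                                 lambda s: np.array([g, 0.0, 0.0]))
    _, rho, u = snaps[-1]
    umax = float(u[..., 0][grid.fluid_mask].max())
    ref = g * radius * radius / (4.0 * nu)
    return abs(umax - ref) / ref


def stenosis_throat_speedup(radius: float = 8.0, throat_ratio: float = 0.4,
                            nx: int = 72, u_in: float = 0.04,
                            n_steps: int = 4000, les_on: bool = True) -> dict:
    """Cosine-constricted 3D tube: throat peak velocity against the
    continuity estimate (inlet peak / throat area ratio)."""
    desc = D3Q19()
    grid = constricted_tube(nx, radius, desc, throat_ratio=throat_ratio,
                            open_inlet=True, open_outlet=True)
    nu = 0.05
    um = UnitMap(dx=1e-3, nu_phys=3.3333e-6, nu_lattice=nu)
    u_phys = u_in * um.velocity_scale
    snaps = run_pulsatile(grid, um, lambda t: u_phys, n_steps,
                          les_on=les_on, snapshot_every=0)
    u = snaps[-1].u
    speed = np.linalg.norm(u, axis=-1)
    speed[~grid.fluid_mask] = 0.0
    mid = slice(nx // 2 - 3, nx // 2 + 4)
    peak_throat = float(speed[mid].max())
    inlet_peak = float(speed[3].max())
    estimate = inlet_peak / throat_ratio
    return {
        "peak_throat": peak_throat,
        "inlet_peak": inlet_peak,
        "continuity_estimate": estimate,
        "ratio_vs_estimate": peak_throat / estimate,
    }


def channel_refinement(ny: int, nu: float = 0.05) -> dict:
    """One resolution of the Poiseuille mesh-acceptance study.

    The body force scales as 1/ny^3 so the physical flow is identical
    across resolutions under diffusive scaling; peak velocity and wall
    shear are returned normalized back to the reference grid so successive
    resolutions are directly comparable.
    """
    desc = D2Q9()
    ref_ny = 24
    scale = ny / ref_ny
    g = 1e-6 / scale**3
    # wall offset scales with ny so the physical channel width is identical
    # at every resolution (ny a multiple of 12 keeps q = 1/2 exactly)
    grid, h, y, half = _channel_geometry(ny, desc, wall_offset=ny / 12.0)
    n_steps = int(12.0 * h * h / nu)
    f, snaps = run_channel_force(grid, nu, n_steps, lambda s: np.array([g, 0.0]))
    _, rho, u = snaps[-1]
    fluid = grid.fluid_mask[2]
    u_peak = float(u[2, :, 0][fluid].max()) * scale
    unit_identity = UnitMap(dx=1.0, nu_phys=nu, nu_lattice=nu, rho_phys=1.0)
    tau_w = float(np.median(wall_stress(f, grid, nu, unit_identity).shear_mag))
    return {"peak_velocity": u_peak, "pressure_drop": tau_w * scale**2}
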