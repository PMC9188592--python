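"""Velocity sets and lattice-to-physical unit mapping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatticeDescriptor", "D2Q9", "D3Q19", "UnitMap"]


@dataclass(frozen=True)
class LatticeDescriptor:
    """A discrete velocity set: c_alpha (Q x d ints), weights, opposites."""

    name: str
    c: np.ndarray
    w: np.ndarray
    opp: np.ndarray

    #: lattice sound speed squared
    cs2: float = 1.0 / 3.0

    @property
    def q(self) -> int:
        return len(self.w)

    @property
    def dim(self) -> int:
        return self.c.shape[1]

    def validate(self) -> None:
        assert abs(self.w.sum() - 1.0) < 1e-14
        assert np.all(np.abs(self.w @ self.c) < 1e-14)
        assert np.array_equal(self.opp[self.opp], np.arange(self.q))
        assert np.array_equal(self.c[self.opp], -self.c)


def _with_opposites(c: np.ndarray, w: np.ndarray, name: str) -> LatticeDescriptor:
    opp = np.array([int(np.where((c == -ci).all(axis=1))[0][0]) for ci in c])
    d = LatticeDescriptor(name=name, c=c, w=w, opp=opp)
    d.validate()
    return d


def D2Q9() -> LatticeDescriptor:
    c = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1],
                  [1, 1], [-1, -1], [1, -1], [-1, 1]])
    w = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)
    return _with_opposites(c, w, "D2Q9")


def D3Q19() -> LatticeDescriptor:
    c = [[0, 0, 0]]
    c += [v for v in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                      [0, 0, 1], [0, 0, -1])]
    diag = []
    for i in range(3):
        for j in range(i + 1, 3):
            for si in (1, -1):
                for sj in (1, -1):
                    v = [0, 0, 0]
                    v[i], v[j] = si, sj
                    diag.append(v)
    c = np.array(c + diag)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    return _with_opposites(c, w, "D3Q19")


@dataclass(frozen=True)
class UnitMap:
    """Lattice <-> physical unit conversion.

    Fixes the diffusive scaling dt = (nu_lattice / nu_phys) * dx^2; the
    lattice viscosity is chosen so the relaxation time tau0 = 3 nu + 1/2
    stays in a stable range (roughly [0.51, 0.8]).
    """

    dx: float          # m per lattice cell
    nu_phys: float     # m^2/s
    nu_lattice: float  # lattice units
    rho_phys: float = 1050.0  # kg/m^3

    @property
    def dt(self) -> float:
        """s per lattice step (diffusive scaling, exact by construction)."""
        return self.nu_lattice / self.nu_phys * self.dx ** 2

    @property
    def tau0(self) -> float:
        return 3.0 * self.nu_lattice + 0.5

    @property
    def velocity_scale(self) -> float:
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure_scale(self) -> float:
        """Pa per lattice pressure/stress unit (rho_lattice = 1)."""
        return self.rho_phys * self.velocity_scale ** 2

    @classmethod
    def for_velocity(cls, dx: float, u_phys_max: float, u_lattice_max: float = 0.08,
                     nu_phys: float = 3.3333e-6, rho_phys: float = 1050.0,
                     tau_bounds=(0.51, 0.8)) -> "UnitMap":
        """Choose nu_lattice so ``u_phys_max`` maps to ``u_lattice_max``,
        clipped to keep tau0 within ``tau_bounds``."""
        # u_lat = u_phys * dt/dx = u_phys * nu_lat * dx / nu_phys
        nu_lat = u_lattice_max * nu_phys / (u_phys_max * dx)
        lo = (tau_bounds[0] - 0.5) / 3.0
        hi = (tau_bounds[1] - 0.5) / 3.0
        nu_lat = min(max(nu_lat, lo), hi)
        return cls(dx=dx, nu_phys=nu_phys, nu_lattice=nu_lat, rho_phys=rho_phys)
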