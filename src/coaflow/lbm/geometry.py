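"""Voxel geometries for the flow kernel.

Grids are built from a signed distance function (SDF, positive in the
fluid, in units of lattice cells).  The SDF provides both the per-link
wall-distance fractions q used by the interpolated bounce-back and the
smoothed wall normals used for traction projection.

Toy vessel factories: a straight tube, a cosine-constricted tube (throat
ratio configurable) and a constricted tube with a bypass loop sized like a
clinical extra-anatomical graft (length ~8 cm, diameter ~1.6 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .lattice import LatticeDescriptor

__all__ = ["VoxelGrid", "channel_2d", "inclined_channel_2d", "straight_tube",
           "constricted_tube", "bypass_tube"]

FLUID, SOLID, INLET, OUTLET0 = 0, 1, 2, 3


class GridConstructionError(ValueError):
    pass


@dataclass
class VoxelGrid:
    """Cell flags, SDF, and per-direction wall-link data.

    ``wall_links[alpha]`` is a dict with flat fluid-cell indices ``idx``,
    fractions ``q`` in (0, 1], upstream-neighbor flat indices ``idx_e`` and
    a boolean ``e_valid`` (upstream neighbor is fluid).
    """

    flags: np.ndarray
    sdf: np.ndarray
    desc: LatticeDescriptor
    wall_links: Dict[int, dict] = field(default_factory=dict)
    normals: Optional[np.ndarray] = None  # (*shape, d), outward (into solid)
    inlet_axis: int = 0

    @property
    def shape(self) -> tuple:
        return self.flags.shape

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.flags != SOLID

    @classmethod
    def from_sdf(cls, sdf: np.ndarray, desc: LatticeDescriptor,
                 inlet_axis: int = 0, open_inlet: bool = False,
                 open_outlet: bool = False, normal_sigma: float = 1.0
                 ) -> "VoxelGrid":
        """Build a grid from an SDF sampled at cell centers (cell units).

        Fluid where sdf > 0.  With ``open_inlet``/``open_outlet`` the first/
        last plane along ``inlet_axis`` is flagged as inlet/outlet.
        """
        sdf = np.asarray(sdf, dtype=float)
        flags = np.where(sdf > 0.0, FLUID, SOLID).astype(np.uint8)
        if open_inlet:
            sl = [slice(None)] * sdf.ndim
            sl[inlet_axis] = 0
            plane = flags[tuple(sl)]
            plane[plane == FLUID] = INLET
        if open_outlet:
            sl = [slice(None)] * sdf.ndim
            sl[inlet_axis] = -1
            plane = flags[tuple(sl)]
            plane[plane == FLUID] = OUTLET0
        grid = cls(flags=flags, sdf=sdf, desc=desc, inlet_axis=inlet_axis)
        grid._build_wall_links()
        grid._build_normals(normal_sigma)
        return grid

    def _build_wall_links(self) -> None:
        desc = self.desc
        solid = self.flags == SOLID
        fluid = ~solid
        shape = self.flags.shape
        flat_sdf = self.sdf.ravel()
        for alpha in range(desc.q):
            c = desc.c[alpha]
            if not c.any():
                continue
            neighbor_solid = np.roll(solid, shift=tuple(-c), axis=tuple(range(len(c))))
            mask = fluid & neighbor_solid
            # domain-boundary wrap guard: discard links wrapping the box
            for ax, ci in enumerate(c):
                if ci == 1:
                    sl = [slice(None)] * len(shape)
                    sl[ax] = -1
                    m = np.zeros(shape, bool)
                    m[tuple(sl)] = True
                    mask &= ~m
                elif ci == -1:
                    sl = [slice(None)] * len(shape)
                    sl[ax] = 0
                    m = np.zeros(shape, bool)
                    m[tuple(sl)] = True
                    mask &= ~m
            if not mask.any():
                continue
            idx = np.flatnonzero(mask.ravel())
            coords = np.array(np.unravel_index(idx, shape)).T
            nb = coords + c
            idx_b = np.ravel_multi_index(nb.T, shape, mode="wrap")
            phi_a = flat_sdf[idx]
            phi_b = flat_sdf[idx_b]
            with np.errstate(divide="ignore", invalid="ignore"):
                qf = phi_a / (phi_a - phi_b)
            qf = np.clip(np.nan_to_num(qf, nan=0.5), 1e-3, 1.0)
            # upstream neighbor E = A - c
            up = coords - c
            in_box = np.all((up >= 0) & (up < np.array(shape)), axis=1)
            idx_e = np.where(
                in_box,
                np.ravel_multi_index(np.clip(up, 0, np.array(shape) - 1).T, shape),
                idx)
            e_valid = in_box & (~solid.ravel()[idx_e])
            self.wall_links[alpha] = {
                "idx": idx, "q": qf, "idx_e": idx_e, "e_valid": e_valid}
        if not self.wall_links and solid.any():
            raise GridConstructionError("solid present but no wall links found")

    def _build_normals(self, sigma: float) -> None:
        sm = ndimage.gaussian_filter(self.sdf, sigma=sigma, mode="nearest")
        grads = np.gradient(sm)
        n = -np.stack(grads, axis=-1)  # outward: toward decreasing sdf
        mag = np.linalg.norm(n, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(mag > 1e-12, n / mag, 0.0)
        self.normals = n

    def wall_adjacent_indices(self) -> np.ndarray:
        """Flat indices of fluid cells having at least one wall link."""
        idx = set()
        for rec in self.wall_links.values():
            idx.update(rec["idx"].tolist())
        return np.array(sorted(idx), dtype=int)


# ---------------------------------------------------------------------------
# toy geometries (SDFs in lattice-cell units)


def channel_2d(nx: int, ny: int, desc: LatticeDescriptor,
               wall_offset: float = 1.5, **kwargs) -> VoxelGrid:
    """Plane 2D channel along x; walls at y = wall_offset - 0.5 cells from
    the box edges (so q is well defined on wall links)."""
    y = np.arange(ny, dtype=float)[None, :] + 0.5
    half = ny / 2.0
    sdf = (half - wall_offset) - np.abs(y - half)
    sdf = np.broadcast_to(sdf, (nx, ny)).copy()
    return VoxelGrid.from_sdf(sdf, desc, **kwargs)


def inclined_channel_2d(nx: int, ny: int, desc: LatticeDescriptor,
                        angle_deg: float = 12.0, width: float = None,
                        **kwargs) -> VoxelGrid:
    """2D channel whose walls are inclined to the lattice: exercises the
    sub-cell wall fractions of the interpolated bounce-back."""
    th = np.deg2rad(angle_deg)
    n = np.array([-np.sin(th), np.cos(th)])  # unit normal to the wall plane
    x = np.arange(nx, dtype=float)[:, None] + 0.5
    y = np.arange(ny, dtype=float)[None, :] + 0.5
    if width is None:
        width = ny * np.cos(th) - 6.0
    mid = (n[0] * (x - nx / 2.0) + n[1] * (y - ny / 2.0))
    sdf = width / 2.0 - np.abs(mid)
    return VoxelGrid.from_sdf(sdf, desc, **kwargs)


def straight_tube(nx: int, radius: float, desc: LatticeDescriptor,
                  pad: int = 3, **kwargs) -> VoxelGrid:
    """Circular tube of constant radius (cells) along x (3D)."""
    ns = int(np.ceil(2 * radius)) + 2 * pad
    y = np.arange(ns, dtype=float)[None, :, None] + 0.5 - ns / 2.0
    z = np.arange(ns, dtype=float)[None, None, :] + 0.5 - ns / 2.0
    r = np.sqrt(y**2 + z**2)
    sdf = radius - r
    sdf = np.broadcast_to(sdf, (nx, ns, ns)).copy()
    return VoxelGrid.from_sdf(sdf, desc, **kwargs)


def constricted_tube(nx: int, radius: float, desc: LatticeDescriptor,
                     throat_ratio: float = 0.4, throat_len_frac: float = 0.5,
                     pad: int = 3, **kwargs) -> VoxelGrid:
    """Tube with a smooth cosine constriction at mid-length.

    ``throat_ratio`` is the throat-to-tube *area* ratio (EOA/A); the radius
    ratio is its square root.
    """
    if not 0 < throat_ratio <= 1:
        raise GridConstructionError("throat_ratio must lie in (0, 1]")
    ns = int(np.ceil(2 * radius)) + 2 * pad
    x = np.arange(nx, dtype=float)[:, None, None] + 0.5
    y = np.arange(ns, dtype=float)[None, :, None] + 0.5 - ns / 2.0
    z = np.arange(ns, dtype=float)[None, None, :] + 0.5 - ns / 2.0
    r = np.sqrt(y**2 + z**2)
    r_throat = radius * np.sqrt(throat_ratio)
    lc = throat_len_frac * nx
    xi = (x - nx / 2.0) / (lc / 2.0)
    profile = np.where(np.abs(xi) < 1.0,
                       0.5 * (1.0 + np.cos(np.pi * xi)), 0.0)
    local_r = radius - (radius - r_throat) * profile
    sdf = local_r - r
    return VoxelGrid.from_sdf(sdf, desc, **kwargs)


def bypass_tube(nx: int, radius: float, desc: LatticeDescriptor,
                throat_ratio: float = 0.4, graft_radius_frac: float = 0.5,
                loop_offset: float = None, pad: int = 3, **kwargs) -> VoxelGrid:
    """Constricted tube with an extra-anatomical bypass loop.

    The loop leaves the main tube upstream of the throat, arcs over it in
    the x--y plane and rejoins downstream, mimicking a graft that leaves the
    stenosis in situ.  ``graft_radius_frac`` scales the graft radius to the
    tube radius (a 1.6 cm graft on a ~3 cm aorta is about 0.5).
    """
    if loop_offset is None:
        loop_offset = 2.5 * radius
    ns_y = int(np.ceil(2 * radius + loop_offset)) + 2 * pad
    ns_z = int(np.ceil(2 * radius)) + 2 * pad
    cy = pad + radius
    x = np.arange(nx, dtype=float)[:, None, None] + 0.5
    y = np.arange(ns_y, dtype=float)[None, :, None] + 0.5
    z = np.arange(ns_z, dtype=float)[None, None, :] + 0.5 - ns_z / 2.0

    # main constricted tube centered at y = cy
    r_main = np.sqrt((y - cy) ** 2 + z**2)
    r_throat = radius * np.sqrt(throat_ratio)
    lc = 0.4 * nx
    xi = (x - nx / 2.0) / (lc / 2.0)
    profile = np.where(np.abs(xi) < 1.0, 0.5 * (1.0 + np.cos(np.pi * xi)), 0.0)
    local_r = radius - (radius - r_throat) * profile
    sdf_main = local_r - r_main

    # graft: half-ellipse arc from x1 to x2 peaking at y = cy + loop_offset
    rg = graft_radius_frac * radius
    x1, x2 = 0.22 * nx, 0.78 * nx
    xc, ax_len = 0.5 * (x1 + x2), 0.5 * (x2 - x1)
    t = np.clip((x - xc) / ax_len, -1.0, 1.0)
    y_arc = cy + loop_offset * np.sqrt(np.maximum(1.0 - t**2, 0.0))
    in_span = (x >= x1) & (x <= x2)
    d_graft = np.sqrt((y - y_arc) ** 2 + z**2)
    sdf_graft = np.where(in_span, rg - d_graft, -1e3)

    sdf = np.maximum(sdf_main, sdf_graft)
    return VoxelGrid.from_sdf(sdf, desc, **kwargs)
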