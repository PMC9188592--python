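"""Velocity-field comparison statistics.

Pipeline used to compare a high-resolution simulated velocity field with a
coarser measured one: linear down-sampling onto the coarse grid, DCT-based
penalized-least-squares smoothing with generalized-cross-validation (GCV)
parameter selection (robust option replaces outliers and imputes missing
vectors), then voxel-wise Bland--Altman agreement (bias and 1.96 SD limits
of agreement) and Pearson correlation / R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import fft as sp_fft
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

__all__ = ["VectorField", "AgreementReport", "downsample", "smooth_field",
           "bland_altman", "correlation", "smoothn"]


@dataclass
class VectorField:
    """Velocity vectors on a regular grid.

    ``data`` has shape (*grid_shape, n_components) in m/s; ``mask`` marks
    valid voxels.
    """

    origin: np.ndarray
    spacing: np.ndarray
    data: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:-1], dtype=bool)
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite velocity inside the valid mask")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:-1]

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)

    def axes(self) -> tuple:
        return tuple(self.origin[i] + self.spacing[i] * np.arange(n)
                     for i, n in enumerate(self.grid_shape))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)

    def same_grid(self, other: "VectorField") -> bool:
        return (self.grid_shape == other.grid_shape
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.spacing, other.spacing))


@dataclass
class AgreementReport:
    """Voxel-wise agreement between two fields."""

    bias: float = math.nan             # m/s
    loa_half_width: float = math.nan   # 1.96 SD of differences, m/s
    pearson_r: float = math.nan
    r_squared: float = math.nan
    n_voxels: int = 0


def downsample(fine: VectorField, coarse_origin, coarse_spacing,
               coarse_shape) -> VectorField:
    """Component-wise linear interpolation onto a coarser grid.

    A coarse voxel is valid only when every contributing fine voxel is
    valid (the mask is interpolated and thresholded at 1).
    """
    origin = np.asarray(coarse_origin, float)
    spacing = np.asarray(coarse_spacing, float)
    shape = tuple(coarse_shape)
    axes = fine.axes()
    pts = np.stack(np.meshgrid(
        *(origin[i] + spacing[i] * np.arange(n) for i, n in enumerate(shape)),
        indexing="ij"), axis=-1).reshape(-1, fine.ndim)
    lo = np.array([a[0] for a in axes])
    hi = np.array([a[-1] for a in axes])
    if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
        raise ValueError("coarse grid extends outside the fine grid")
    comps = []
    for k in range(fine.data.shape[-1]):
        interp = RegularGridInterpolator(axes, fine.data[..., k])
        comps.append(interp(pts).reshape(shape))
    mask_interp = RegularGridInterpolator(axes, fine.mask.astype(float))
    mask = mask_interp(pts).reshape(shape) >= 1.0 - 1e-9
    return VectorField(origin=origin, spacing=spacing,
                       data=np.stack(comps, axis=-1), mask=mask)


# ---------------------------------------------------------------------------
# DCT penalized least-squares smoothing with GCV (Garcia-style smoothn)


def _lambda_eigenvalues(shape: tuple) -> np.ndarray:
    lam = np.zeros(shape)
    for ax, n in enumerate(shape):
        k = np.arange(n).reshape([-1 if a == ax else 1 for a in range(len(shape))])
        lam = lam + (-2.0 + 2.0 * np.cos(np.pi * k / n))
    return lam


def smoothn(y: np.ndarray, w: Optional[np.ndarray] = None,
            robust: bool = False, s: Optional[float] = None,
            max_iter: int = 100, tol: float = 1e-3) -> Tuple[np.ndarray, float]:
    """Penalized least-squares smoothing of an n-D array.

    Minimizes ||W^(1/2) (z - y)||^2 + s ||D z||^2 in the DCT basis, with the
    smoothing parameter ``s`` selected by generalized cross-validation when
    not given.  Weights ``w`` in [0, 1] (0 = missing, imputed); ``robust``
    adds bisquare re-weighting of outliers.  NaNs in ``y`` count as missing.
    Returns ``(z, s)``.
    """
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(y)
    if w is None:
        w = np.ones_like(y)
    w = np.where(finite, w, 0.0)
    if not (w > 0).any():
        raise ValueError("no valid data to smooth")
    y_filled = np.where(finite, y, 0.0)
    lam = _lambda_eigenvalues(y.shape)
    lam2 = lam * lam
    n = y.size
    n_valid = int((w > 0).sum())

    def solve(s_val, z0):
        gamma = 1.0 / (1.0 + s_val * lam2)
        if not (w < 1.0).any():
            return sp_fft.idctn(gamma * sp_fft.dctn(y_filled, norm="ortho"),
                                norm="ortho")
        z = z0
        for _ in range(max_iter):
            rhs = w * (y_filled - z) + z
            z_new = sp_fft.idctn(gamma * sp_fft.dctn(rhs, norm="ortho"),
                                 norm="ortho")
            if np.abs(z_new - z).max() <= tol * (np.abs(z).max() + 1e-12):
                z = z_new
                break
            z = z_new
        return z

    def gcv_score(log10s, z0):
        s_val = 10.0 ** log10s
        z = solve(s_val, z0)
        gamma = 1.0 / (1.0 + s_val * lam2)
        tr_h = gamma.sum() * n_valid / n
        rss = float((w * (y_filled - z) ** 2).sum())
        denom = (1.0 - tr_h / n_valid) ** 2
        return rss / max(denom, 1e-300), z

    z = y_filled.copy()
    n_robust = 3 if robust else 1
    s_sel = s
    if robust:
        # pre-screen outliers against their local neighbourhood; a pure
        # residual criterion misses isolated spikes when GCV selects a
        # near-interpolating fit
        from scipy import ndimage
        local = ndimage.median_filter(y_filled, size=3, mode="nearest")
        r0 = y_filled - local
        mad0 = np.median(np.abs(r0[w > 0])) + 1e-12
        u0 = np.abs(r0) / (1.4826 * mad0)
        w = w * np.where(u0 < 6.0, 1.0, 0.0)
        z = np.where(w > 0, y_filled, local)
    for _ in range(n_robust):
        if s is None:
            res = minimize_scalar(lambda ls: gcv_score(ls, z)[0],
                                  bounds=(-6.0, 8.0), method="bounded",
                                  options={"xatol": 0.05})
            s_sel = 10.0 ** res.x
        z = solve(s_sel, z)
        if robust:
            r = y_filled - z
            valid = w > 0
            mad = np.median(np.abs(r[valid] - np.median(r[valid]))) + 1e-12
            u = np.abs(r) / (1.4826 * mad) / np.sqrt(1.0)
            bisq = np.where(u < 4.685, (1.0 - (u / 4.685) ** 2) ** 2, 0.0)
            w = np.where(finite, bisq, 0.0)
    return z, float(s_sel)


def smooth_field(fld: VectorField, robust: bool = False,
                 s: Optional[float] = None) -> VectorField:
    """Smooth each velocity component; missing/flagged voxels are imputed
    with their smoothed values and the output mask marks all voxels valid."""
    if int(fld.mask.sum()) < 8:
        raise ValueError("need at least 8 valid voxels to smooth")
    comps = []
    for k in range(fld.data.shape[-1]):
        y = np.where(fld.mask, fld.data[..., k], np.nan)
        z, _ = smoothn(y, robust=robust, s=s)
        comps.append(z)
    return VectorField(origin=fld.origin, spacing=fld.spacing,
                       data=np.stack(comps, axis=-1),
                       mask=np.ones(fld.grid_shape, dtype=bool))


# ---------------------------------------------------------------------------
# agreement statistics


def _paired_values(a: VectorField, b: VectorField, mode: str):
    if not a.same_grid(b):
        raise ValueError("fields must share a grid")
    m = a.mask & b.mask
    if mode == "magnitude":
        va, vb = a.magnitude()[m], b.magnitude()[m]
    elif mode == "component":
        va, vb = a.data[m].ravel(), b.data[m].ravel()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if va.size < 2:
        raise ValueError("need more than one paired voxel")
    return va, vb


def bland_altman(a: VectorField, b: VectorField,
                 mode: str = "magnitude") -> AgreementReport:
    """Bias (mean of differences a - b) and limits of agreement (1.96 SD)."""
    va, vb = _paired_values(a, b, mode)
    d = va - vb
    return AgreementReport(bias=float(d.mean()),
                           loa_half_width=float(1.96 * d.std(ddof=1)),
                           n_voxels=int(d.size))


def correlation(a: VectorField, b: VectorField,
                mode: str = "magnitude") -> AgreementReport:
    """Pearson product-moment correlation and coefficient of determination."""
    va, vb = _paired_values(a, b, mode)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in one of the fields")
    r = float(pearsonr(va, vb).statistic)
    return AgreementReport(pearson_r=r, r_squared=r * r, n_voxels=int(va.size))
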