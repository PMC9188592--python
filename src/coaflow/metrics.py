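"""Clinical hemodynamic indices derived from waveforms or printed scalars.

These are the standard bedside quantities: the simplified-Bernoulli Doppler
gradient (dP = 4 Vmax^2), systemic arterial compliance (SAC = SV / pulse
pressure), and the per-beat stroke-volume bookkeeping across the arch
branches, the coarctation and the bypass graft.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circuit import CircuitParams, CycleWaveforms

__all__ = [
    "HemodynamicSummary", "doppler_peak_gradient",
    "systemic_arterial_compliance", "stroke_volumes",
    "peak_velocity_from_gradient", "mean_relative_error",
    "summarize_hemodynamics",
]


@dataclass
class HemodynamicSummary:
    """Per-patient-state summary of the quantities clinicians track."""

    sbp: float
    dbp: float
    peak_gradient: float    # trans-COA net gradient at steady cycle, mmHg
    sac: float              # mL/mmHg
    total_sv: float
    branch_sv: float
    coa_sv: float
    graft_sv: float

    def __post_init__(self) -> None:
        parts = self.branch_sv + self.coa_sv + self.graft_sv
        if self.total_sv > 0 and abs(parts - self.total_sv) > 0.01 * self.total_sv:
            warnings.warn(
                f"stroke-volume bookkeeping off by "
                f"{abs(parts - self.total_sv) / self.total_sv:.2%}",
                stacklevel=2)

    def as_dict(self) -> dict:
        return {
            "Systolic brachial pressure (mmHg)": self.sbp,
            "Diastolic brachial pressure (mmHg)": self.dbp,
            "Peak Doppler pressure gradient (mmHg)": self.peak_gradient,
            "Systemic arterial compliance (mL/mmHg)": self.sac,
            "Total stroke volume (mL)": self.total_sv,
            "Flow rate through branches (mL)": self.branch_sv,
            "Flow rate through contraction (mL)": self.coa_sv,
            "Flow rate through bypass graft (mL)": self.graft_sv,
        }


def doppler_peak_gradient(v_max: float) -> float:
    """Simplified Bernoulli: dP = 4 Vmax^2 (Vmax in m/s, result in mmHg)."""
    if v_max < 0:
        raise ValueError("v_max must be >= 0")
    return 4.0 * v_max * v_max


def peak_velocity_from_gradient(dp: float) -> float:
    """Inverse of the simplified Bernoulli law: Vmax = sqrt(dP / 4), m/s."""
    if dp < 0:
        raise ValueError("dp must be >= 0")
    return math.sqrt(dp / 4.0)


def systemic_arterial_compliance(sv: float, sbp: float, dbp: float) -> float:
    """SAC = SV / (SBP - DBP), mL/mmHg."""
    if sbp == dbp:
        raise ZeroDivisionError("pulse pressure is zero")
    return sv / (sbp - dbp)


def stroke_volumes(waves: CycleWaveforms) -> tuple:
    """Per-beat (total, branch, coa, graft) volumes over the final cycle, mL.

    Trapezoidal quadrature of q_av, q_ub, q_coa and q_graft.  A non-steady
    input raises a warning, not an error.
    """
    if not waves.steady:
        warnings.warn("waveforms not flagged steady; stroke volumes may drift",
                      stacklevel=2)
    fc = waves.final_cycle()
    total = fc.integral("q_av")
    branch = fc.integral("q_ub")
    coa = fc.integral("q_coa")
    graft = fc.integral("q_graft")
    return total, branch, coa, graft


def mean_relative_error(sim: Sequence[float], clin: Sequence[float]) -> float:
    """Mean of |sim - clin| / clin (as a fraction)."""
    sim = np.asarray(sim, dtype=float)
    clin = np.asarray(clin, dtype=float)
    if sim.shape != clin.shape:
        raise ValueError("length mismatch")
    if np.any(clin <= 0):
        raise ValueError("clinical reference values must be > 0")
    return float(np.mean(np.abs(sim - clin) / clin))


def summarize_hemodynamics(waves: CycleWaveforms,
                           params: Optional[CircuitParams] = None
                           ) -> HemodynamicSummary:
    """Build a :class:`HemodynamicSummary` from steady waveforms.

    The peak trans-coarctation gradient is read as the steady-cycle maximum
    of the pressure drop between the bifurcation node and the systemic node
    minus the proximal-descending resistive drop — the net gradient the COA
    element itself produces.
    """
    fc = waves.final_cycle()
    total, branch, coa_sv, graft_sv = stroke_volumes(waves)
    sbp = float(fc.signals["p_ao"].max())
    dbp = float(fc.signals["p_ao"].min())
    if params is not None:
        from .circuit import coa_net_pg
        v = params.valves["coa"]
        q = fc.signals["q_coa"]
        t = fc.time
        dq = np.gradient(q, t)
        grad = np.array([coa_net_pg(qi, dqi, v.eoa, v.reference_area, v.rho)
                         for qi, dqi in zip(q, dq)])
        peak_gradient = float(grad.max())
    else:
        peak_gradient = float("nan")
    sac = systemic_arterial_compliance(total, sbp, dbp)
    return HemodynamicSummary(sbp=sbp, dbp=dbp, peak_gradient=peak_gradient,
                              sac=sac, total_sv=total, branch_sv=branch,
                              coa_sv=coa_sv, graft_sv=graft_sv)
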