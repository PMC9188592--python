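"""Lumped-parameter (0D) model of the left heart and systemic circulation.

The model couples two time-varying-elastance chambers (LV, LA), valve and
regurgitation elements written as net-pressure-gradient laws, a
trans-coarctation element of the same form, an optional bypass-graft
resistance, and a two-node (aortic / systemic) Windkessel ladder, driven by
a rectified-sine pulmonary inflow.  Pressures are in mmHg, flows in mL/s,
volumes in mL, areas in cm^2, times in s.

Topology
--------
``Q_PV -> LA -> MV -> LV -> AV -> [C_ao] -R_ao-> bifurcation -> {R_ub;
R_pda + COA element; R_graft (post only)} -> [C_SAC] -R_SA-R_SV-> P_CV0``.
Aortic and mitral regurgitation conduits run antiparallel to their valves.
The pulmonary ladder of the source circuit has negligible influence on left
heart output and is carried as documented constants
(:data:`PULMONARY_LADDER_CONSTANTS`), not simulated.

Each valve conduit integrates an inertial flow ODE while open and is clamped
to zero flow when its flow decelerates through zero (ideal-diode logic with
bisection event localization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .units import DYN_PER_MMHG, RHO_BLOOD

__all__ = [
    "ElastanceParams", "ChamberParams", "ValveParams", "CircuitParams",
    "CircuitState", "CycleWaveforms", "IntegrationError",
    "normalized_elastance", "chamber_pressure", "energy_loss_coefficient",
    "valve_net_pg", "mitral_net_pg", "coa_net_pg", "pulmonary_inflow",
    "assemble_derivatives", "simulate", "default_circuit_params",
    "PULMONARY_LADDER_CONSTANTS",
]

#: Pulmonary ladder element values (inert documented constants; a
#: sensitivity analysis of the source circuit shows they have negligible
#: effect on left-heart output, so the ladder is replaced by the prescribed
#: pulmonary inflow waveform).  Units: resistances mmHg*s/mL, compliances
#: mL/mmHg, inertances mmHg*s^2/mL.
PULMONARY_LADDER_CONSTANTS = {
    "L_PV": 0.0005, "R_PV": 0.002, "R_PVC": 0.001, "C_PVC": 40.0,
    "L_PC": 0.0003, "R_PC": 0.21, "R_PA": 0.01, "C_PA": 4.0,
}

#: cap on the energy-loss coefficient (cm^2); beyond this the element's
#: gradient is physiologically zero and an uncapped value only stiffens the
#: flow ODE (inertance ~ 1/sqrt(E_L Co)).
_ELCO_CAP = 100.0


class IntegrationError(RuntimeError):
    pass


class DegenerateOrificeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# element laws


@dataclass
class ElastanceParams:
    """Double-Hill elastance curve parameters.

    ``tau1``/``tau2`` are absolute times in seconds (the conventional
    fractions of the cycle length multiplied out).
    """

    e_max: float  # mmHg/mL
    e_min: float  # mmHg/mL
    m1: float
    m2: float
    tau1: float  # s
    tau2: float  # s
    T: float     # s

    def __post_init__(self) -> None:
        if not self.e_max > self.e_min > 0:
            raise ValueError("require e_max > e_min > 0")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("Hill exponents must be > 0")
        if not 0 < self.tau1 < self.tau2 < self.T:
            raise ValueError("require 0 < tau1 < tau2 < T")

    @classmethod
    def lv(cls, T: float) -> "ElastanceParams":
        return cls(e_max=2.1, e_min=0.06, m1=1.32, m2=27.4,
                   tau1=0.269 * T, tau2=0.452 * T, T=T)

    @classmethod
    def la(cls, T: float) -> "ElastanceParams":
        return cls(e_max=0.17, e_min=0.06, m1=1.32, m2=13.1,
                   tau1=0.110 * T, tau2=0.18 * T, T=T)


def normalized_elastance(t: float, p: ElastanceParams) -> float:
    """Double-Hill elastance E(t), mmHg/mL; periodic in ``p.T``.

    E(t) = N * [(t/tau1)^m1 / (1 + (t/tau1)^m1)] * [1 / (1 + (t/tau2)^m2)]
    + E_min with N = (E_max - E_min)/2, implemented literally (the peak is
    only approximately E_max; no renormalization is applied).
    """
    t = t % p.T
    n = 0.5 * (p.e_max - p.e_min)
    x1 = (t / p.tau1) ** p.m1
    x2 = (t / p.tau2) ** p.m2
    return n * (x1 / (1.0 + x1)) / (1.0 + x2) + p.e_min


def chamber_pressure(e_t: float, v: float, v0: float) -> float:
    """P = E(t) * (V - V0), mmHg."""
    return e_t * (v - v0)


def energy_loss_coefficient(eoa: float, a_ref: float) -> float:
    """E_L Co = EOA * A / (A - EOA), cm^2; diverges as EOA -> A."""
    if not 0 < eoa < a_ref:
        raise DegenerateOrificeError(
            f"require 0 < eoa ({eoa}) < reference area ({a_ref})")
    return eoa * a_ref / (a_ref - eoa)


def valve_net_pg(q: float, dq_dt: float, el_co: float,
                 rho: float = RHO_BLOOD) -> float:
    """Net pressure gradient across an orifice with energy-loss recovery.

    PG = (2 pi rho / sqrt(E_L Co)) dQ/dt + rho/(2 E_L Co^2) Q|Q|,
    evaluated in CGS and returned in mmHg.
    """
    if el_co <= 0:
        raise DegenerateOrificeError("el_co must be > 0")
    pg_dyn = (2.0 * math.pi * rho / math.sqrt(el_co)) * dq_dt \
        + rho / (2.0 * el_co * el_co) * q * abs(q)
    return pg_dyn / DYN_PER_MMHG


def mitral_net_pg(q: float, dq_dt: float, eoa: float, m_mv: float = 0.53,
                  rho: float = RHO_BLOOD) -> float:
    """Mitral-type net pressure gradient: (M/EOA) dQ/dt + rho/(2 EOA^2) Q|Q|."""
    if eoa <= 0:
        raise DegenerateOrificeError("eoa must be > 0")
    pg_dyn = (m_mv / eoa) * dq_dt + rho / (2.0 * eoa * eoa) * q * abs(q)
    return pg_dyn / DYN_PER_MMHG


def coa_net_pg(q: float, dq_dt: float, eoa_coa: float, a_downstream: float,
               rho: float = RHO_BLOOD) -> float:
    """Trans-coarctation net pressure gradient (mmHg)."""
    el_co = energy_loss_coefficient(eoa_coa, a_downstream)
    return valve_net_pg(q, dq_dt, el_co, rho)


def pulmonary_inflow(t: float, q_mpv: float, t_ee: float, T: float) -> float:
    """Rectified-sine pulmonary inflow: Q = Q_MPV sin(pi t / t_ee) for
    t <= t_ee, else 0; periodic in T.  Cycle integral is 2 Q_MPV t_ee / pi."""
    t = t % T
    if t <= t_ee:
        return q_mpv * math.sin(math.pi * t / t_ee)
    return 0.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ChamberParams:
    elastance: ElastanceParams
    v0: float = 10.0  # mL, unloaded volume

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be >= 0")


@dataclass
class ValveParams:
    eoa: float            # cm^2
    reference_area: float  # cm^2 (A_AO aortic, A_LVOT regurgitant, A_down COA)
    m_mv: float = 0.0     # g/cm^2 (mitral-type inertance; 0 => orifice law)
    rho: float = RHO_BLOOD

    def __post_init__(self) -> None:
        if self.eoa > 0 and not self.eoa < self.reference_area:
            raise DegenerateOrificeError("require eoa < reference_area")

    @property
    def el_co(self) -> float:
        return min(energy_loss_coefficient(self.eoa, self.reference_area), _ELCO_CAP)


@dataclass
class CircuitParams:
    """All elements of the 0D circuit (see module docstring for topology)."""

    T: float
    t_ee: float
    q_mpv: float                      # mL/s, pulmonary inflow amplitude
    chambers: Dict[str, ChamberParams]
    valves: Dict[str, Optional[ValveParams]]  # av, mv, coa required; ar, mr optional
    r_ao: float = 0.05
    r_sv: float = 0.05
    r_sa: float = 0.8
    r_ub: float = 4.0
    r_pda: float = 0.05
    r_graft: float = 0.0              # mmHg*s/mL; used only when graft_present
    c_ao: float = 0.5
    c_sac: float = 2.0
    p_cv0: float = 4.0
    graft_present: bool = False
    atrial_shift: float = 0.12        # fraction of T by which LA leads the LV clock

    def __post_init__(self) -> None:
        for name in ("r_ao", "r_sv", "r_sa", "r_ub", "r_pda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.graft_present and self.r_graft <= 0:
            raise ValueError("graft_present requires r_graft > 0")
        if self.c_ao <= 0 or self.c_sac <= 0:
            raise ValueError("compliances must be > 0")
        if self.p_cv0 < 0:
            raise ValueError("p_cv0 must be >= 0")
        for k in ("av", "mv", "coa"):
            if self.valves.get(k) is None:
                raise ValueError(f"valve {k!r} is required")


def default_circuit_params(record=None, **overrides) -> CircuitParams:
    """Build circuit parameters from a :class:`~coaflow.patient.PatientRecord`
    (or generic defaults when ``record`` is None), applying ``overrides``."""
    from .patient import graft_resistance  # local to avoid cycle

    if record is not None:
        d = record.doppler
        T, t_ee = d.cycle_duration_T, d.ejection_time
        valves: Dict[str, Optional[ValveParams]] = {
            "av": ValveParams(d.eoa_av, d.a_ao),
            "mv": ValveParams(d.eoa_mv, 2.0 * d.eoa_mv, m_mv=0.53),
            "coa": ValveParams(d.eoa_coa, d.a_downstream_coa)
            if d.eoa_coa < d.a_downstream_coa
            else ValveParams(0.999 * d.a_downstream_coa, d.a_downstream_coa),
            "ar": ValveParams(d.eoa_ar, d.a_lvot) if d.eoa_ar > 0 else None,
            "mr": ValveParams(d.eoa_mr, d.eoa_mv, m_mv=0.53) if d.eoa_mr > 0 else None,
        }
        q_mpv = math.pi * d.forward_lvot_sv / (2.0 * t_ee)
        kwargs = dict(T=T, t_ee=t_ee, q_mpv=q_mpv, valves=valves)
        if record.state == "post":
            kwargs["graft_present"] = True
            kwargs["r_graft"] = graft_resistance(record.graft)
    else:
        T, t_ee = 0.8, 0.27
        valves = {
            "av": ValveParams(2.5, 6.0),
            "mv": ValveParams(4.0, 8.0, m_mv=0.53),
            "coa": ValveParams(1.2, 3.0),
            "ar": None, "mr": None,
        }
        kwargs = dict(T=T, t_ee=t_ee, q_mpv=math.pi * 75.0 / (2.0 * t_ee),
                      valves=valves)
    kwargs["chambers"] = {
        "lv": ChamberParams(ElastanceParams.lv(T), v0=10.0),
        "la": ChamberParams(ElastanceParams.la(T), v0=5.0),
    }
    kwargs.update(overrides)
    return CircuitParams(**kwargs)


# ---------------------------------------------------------------------------
# state and derivatives

# state vector layout
_IV_LV, _IV_LA, _IP_AO, _IP_SA, _IQ_AV, _IQ_MV, _IQ_COA, _IQ_AR, _IQ_MR = range(9)
_DIODE_INDICES = (_IQ_AV, _IQ_MV, _IQ_AR, _IQ_MR)


@dataclass
class CircuitState:
    v_lv: float
    v_la: float
    p_ao: float
    p_sa: float
    q_av: float = 0.0
    q_mv: float = 0.0
    q_coa: float = 0.0
    q_ar: float = 0.0
    q_mr: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.v_lv, self.v_la, self.p_ao, self.p_sa,
                         self.q_av, self.q_mv, self.q_coa, self.q_ar, self.q_mr])


def _make_rhs(p: CircuitParams):
    """Bind circuit constants into a fast scalar RHS ``f(t, y) -> dy``.

    ``y`` is a length-9 list/array: [v_lv, v_la, p_ao, p_sa, q_av, q_mv,
    q_coa, q_ar, q_mr].  Returns a list of 9 floats.
    """
    lv, la = p.chambers["lv"], p.chambers["la"]
    elv, ela = lv.elastance, la.elastance
    n_lv = 0.5 * (elv.e_max - elv.e_min)
    n_la = 0.5 * (ela.e_max - ela.e_min)
    av, mv, coa = p.valves["av"], p.valves["mv"], p.valves["coa"]
    ar, mr = p.valves.get("ar"), p.valves.get("mr")
    rho = av.rho
    T = p.T
    shift = p.atrial_shift * T

    # inverse inertances (d(q)/dt = kin * (dP_dyn - convective_dyn))
    kin_av = math.sqrt(av.el_co) / (2.0 * math.pi * rho)
    conv_av = rho / (2.0 * av.el_co ** 2)
    kin_mv = mv.eoa / mv.m_mv
    conv_mv = rho / (2.0 * mv.eoa ** 2)
    kin_coa = math.sqrt(coa.el_co) / (2.0 * math.pi * rho)
    conv_coa = rho / (2.0 * coa.el_co ** 2)
    if ar is not None:
        kin_ar = math.sqrt(ar.el_co) / (2.0 * math.pi * rho)
        conv_ar = rho / (2.0 * ar.el_co ** 2)
    if mr is not None:
        kin_mr = mr.eoa / mr.m_mv
        conv_mr = rho / (2.0 * mr.eoa ** 2)

    g_branch = 1.0 / p.r_ub + (1.0 / p.r_graft if p.graft_present else 0.0)
    inv_r_ao = 1.0 / p.r_ao
    inv_rs = 1.0 / (p.r_sa + p.r_sv)
    r_pda = p.r_pda
    q_mpv, t_ee = p.q_mpv, p.t_ee
    c_ao, c_sac, p_cv0 = p.c_ao, p.c_sac, p.p_cv0
    v0_lv, v0_la = lv.v0, la.v0
    pi = math.pi

    def elastance_lv(t):
        x1 = (t / elv.tau1) ** elv.m1
        x2 = (t / elv.tau2) ** elv.m2
        return n_lv * (x1 / (1.0 + x1)) / (1.0 + x2) + elv.e_min

    def elastance_la(t):
        x1 = (t / ela.tau1) ** ela.m1
        x2 = (t / ela.tau2) ** ela.m2
        return n_la * (x1 / (1.0 + x1)) / (1.0 + x2) + ela.e_min

    def rhs(t, y):
        tc = t % T
        v_lv, v_la, p_ao, p_sa, q_av, q_mv, q_coa, q_ar, q_mr = y

        p_lv = elastance_lv(tc) * (v_lv - v0_lv)
        p_la = elastance_la((tc + shift) % T) * (v_la - v0_la)

        # bifurcation pressure after R_ao (algebraic node)
        p_bif = (p_ao * inv_r_ao + p_sa * g_branch - q_coa) / (inv_r_ao + g_branch)
        q_ub = (p_bif - p_sa) / p.r_ub
        q_graft = (p_bif - p_sa) / p.r_graft if p.graft_present else 0.0
        q_rao = (p_ao - p_bif) * inv_r_ao

        q_pv = q_mpv * math.sin(pi * tc / t_ee) if tc <= t_ee else 0.0
        q_out = (p_sa - p_cv0) * inv_rs

        # diode conduits: integrate while open; hold at zero while closed
        dp = p_lv - p_ao
        if q_av > 0.0 or dp > 0.0:
            dq_av = kin_av * (dp * DYN_PER_MMHG - conv_av * q_av * abs(q_av))
        else:
            dq_av = 0.0
        dp = p_la - p_lv
        if q_mv > 0.0 or dp > 0.0:
            dq_mv = kin_mv * (dp * DYN_PER_MMHG - conv_mv * q_mv * abs(q_mv))
        else:
            dq_mv = 0.0
        if ar is not None:
            dp = p_ao - p_lv
            if q_ar > 0.0 or dp > 0.0:
                dq_ar = kin_ar * (dp * DYN_PER_MMHG - conv_ar * q_ar * abs(q_ar))
            else:
                dq_ar = 0.0
        else:
            dq_ar = 0.0
        if mr is not None:
            dp = p_lv - p_la
            if q_mr > 0.0 or dp > 0.0:
                dq_mr = kin_mr * (dp * DYN_PER_MMHG - conv_mr * q_mr * abs(q_mr))
            else:
                dq_mr = 0.0
        else:
            dq_mr = 0.0

        # COA branch carries signed flow; its drop includes R_pda
        dp_coa = (p_bif - p_sa) - r_pda * q_coa
        dq_coa = kin_coa * (dp_coa * DYN_PER_MMHG - conv_coa * q_coa * abs(q_coa))

        return (
            q_mv - q_av - q_mr + q_ar,                      # dV_lv
            q_pv - q_mv + q_mr,                             # dV_la
            (q_av - q_rao - q_ar) / c_ao,                   # dP_ao
            (q_ub + q_graft + q_coa - q_out) / c_sac,       # dP_sa
            dq_av, dq_mv, dq_coa, dq_ar, dq_mr,
        )

    return rhs


def assemble_derivatives(state: CircuitState, t: float,
                         params: CircuitParams) -> np.ndarray:
    """Time derivatives of the circuit state (public, array-valued wrapper)."""
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        bad = [n for n, ok in zip(
            ("v_lv", "v_la", "p_ao", "p_sa", "q_av", "q_mv", "q_coa",
             "q_ar", "q_mr"), np.isfinite(y)) if not ok]
        raise IntegrationError(f"non-finite state value(s): {bad}")
    dy = np.array(_make_rhs(params)(t, y))
    if not np.all(np.isfinite(dy)):
        bad = [n for n, ok in zip(
            ("v_lv", "v_la", "p_ao", "p_sa", "q_av", "q_mv", "q_coa",
             "q_ar", "q_mr"), np.isfinite(dy)) if not ok]
        raise IntegrationError(f"non-finite derivative for state(s) {bad}")
    if state.v_lv <= 0 or state.v_la <= 0:
        raise IntegrationError("non-positive chamber volume")
    return dy


# ---------------------------------------------------------------------------
# waveform container


@dataclass
class CycleWaveforms:
    """Time series of named circuit signals over simulated cycles."""

    time: np.ndarray
    cycle_index: np.ndarray
    signals: Dict[str, np.ndarray]
    T: float
    steady: bool = False
    n_cycles_run: int = 0
    cycle_summary: Optional[pd.DataFrame] = None  # per-cycle SBP/DBP/SV
    final_state: Optional["CircuitState"] = None  # warm-start handle

    def final_cycle(self) -> "CycleWaveforms":
        """Waveforms restricted to the last complete cycle."""
        last = int(self.cycle_index.max())
        m = self.cycle_index == last
        return CycleWaveforms(
            time=self.time[m], cycle_index=self.cycle_index[m],
            signals={k: v[m] for k, v in self.signals.items()},
            T=self.T, steady=self.steady, n_cycles_run=self.n_cycles_run,
            cycle_summary=self.cycle_summary,
        )

    def integral(self, name: str) -> float:
        """Trapezoidal integral of a signal over the stored samples."""
        return float(np.trapezoid(self.signals[name], self.time))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format DataFrame: time, cycle, signal, value."""
        frames = []
        for name, arr in self.signals.items():
            frames.append(pd.DataFrame({
                "time": self.time, "cycle": self.cycle_index,
                "signal": name, "value": arr}))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# integrator

_SIGNAL_NAMES = ("p_lv", "p_la", "p_ao", "p_sa", "q_av", "q_mv", "q_coa",
                 "q_ar", "q_mr", "q_graft", "q_ub", "q_pv", "v_lv", "v_la")


def _derived_signals(t: float, y, p: CircuitParams) -> tuple:
    lv, la = p.chambers["lv"], p.chambers["la"]
    tc = t % p.T
    p_lv = normalized_elastance(tc, lv.elastance) * (y[_IV_LV] - lv.v0)
    p_la = normalized_elastance((tc + p.atrial_shift * p.T) % p.T,
                                la.elastance) * (y[_IV_LA] - la.v0)
    g_branch = 1.0 / p.r_ub + (1.0 / p.r_graft if p.graft_present else 0.0)
    p_bif = (y[_IP_AO] / p.r_ao + y[_IP_SA] * g_branch - y[_IQ_COA]) \
        / (1.0 / p.r_ao + g_branch)
    q_ub = (p_bif - y[_IP_SA]) / p.r_ub
    q_graft = (p_bif - y[_IP_SA]) / p.r_graft if p.graft_present else 0.0
    q_pv = pulmonary_inflow(tc, p.q_mpv, p.t_ee, p.T)
    return (p_lv, p_la, y[_IP_AO], y[_IP_SA], y[_IQ_AV], y[_IQ_MV],
            y[_IQ_COA], y[_IQ_AR], y[_IQ_MR], q_graft, q_ub, q_pv,
            y[_IV_LV], y[_IV_LA])


def _trap_step(rhs, t, y, f0, dt, newton_tol, max_iter=8):
    """One implicit-trapezoidal step solved by damped fixed-point iteration.

    Returns (y1, f1, n_iter) or None when the iteration fails to contract.
    """
    n = len(y)
    y1 = [y[i] + dt * f0[i] for i in range(n)]
    half = 0.5 * dt
    for it in range(max_iter):
        f1 = rhs(t + dt, y1)
        delta = 0.0
        y_new = [0.0] * n
        for i in range(n):
            yi = y[i] + half * (f0[i] + f1[i])
            d = abs(yi - y1[i]) / (abs(yi) + 1.0)
            if d > delta:
                delta = d
            y_new[i] = yi
        y1 = y_new
        if delta < newton_tol:
            return y1, rhs(t + dt, y1), it + 1
    return None


def simulate(params: CircuitParams, n_cycles: int = 150, dt_init: float = 1e-4,
             dt_max: float = 3e-3, newton_tol: float = 1e-6,
             lte_tol: float = 5e-4, steady_tol: float = 1e-3,
             stop_when_steady: bool = True,
             initial_state: Optional[CircuitState] = None,
             record_from_cycle: Optional[int] = None) -> CycleWaveforms:
    """Integrate the circuit over up to ``n_cycles`` cardiac cycles.

    Implicit trapezoidal rule with adaptive step (initial 0.1 ms): a step is
    rejected when the fixed-point iteration fails to reach ``newton_tol`` or
    the local-error proxy exceeds ``lte_tol``; diode-flow zero crossings are
    localized by bisection and the flow clamped at zero.  Steady state is
    flagged when SBP, DBP and stroke volume all drift by less than
    ``steady_tol`` (0.1%) between consecutive cycles; with
    ``stop_when_steady`` the run then ends early.  Non-convergence within
    ``n_cycles`` sets ``steady=False`` on the output (no exception).

    ``record_from_cycle`` limits sample storage to late cycles (default: the
    final two) to bound memory.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rhs = _make_rhs(params)
    T = params.T
    if initial_state is None:
        initial_state = CircuitState(v_lv=130.0, v_la=60.0, p_ao=70.0, p_sa=70.0)
    y = list(initial_state.as_array())

    rec_times: list = []
    rec_cycles: list = []
    rec_rows: list = []
    summaries = []
    steady = False
    prev = None
    cycle_done = 0

    g_branch = 1.0 / params.r_ub + (1.0 / params.r_graft if params.graft_present else 0.0)
    inv_r_ao = 1.0 / params.r_ao
    inv_rs_ = 1.0 / (params.r_sa + params.r_sv)
    q_mpv_, t_ee_ = params.q_mpv, params.t_ee

    def _branch_flows(yv):
        p_bif = (yv[_IP_AO] * inv_r_ao + yv[_IP_SA] * g_branch - yv[_IQ_COA]) \
            / (inv_r_ao + g_branch)
        q_ub = (p_bif - yv[_IP_SA]) / params.r_ub
        q_graft = (p_bif - yv[_IP_SA]) / params.r_graft if params.graft_present else 0.0
        return q_ub, q_graft

    for cycle in range(n_cycles):
        record = (record_from_cycle is not None and cycle >= record_from_cycle) \
            or (record_from_cycle is None and cycle >= n_cycles - 2) or steady
        t_start, t_end = cycle * T, (cycle + 1) * T
        t = t_start
        dt = dt_init
        f0 = rhs(t, y)
        # per-cycle accumulators
        p_ao_max = -math.inf
        p_ao_min = math.inf
        sv_acc = 0.0
        sv_ub = sv_coa = sv_graft = sv_pv = sv_out = 0.0
        qub0, qgr0 = _branch_flows(y)
        if record:
            rec_times.append(t)
            rec_cycles.append(cycle)
            rec_rows.append(_derived_signals(t, y, params))
        while t < t_end - 1e-12:
            dt = min(dt, t_end - t)
            out = _trap_step(rhs, t, y, f0, dt, newton_tol)
            if out is None:
                dt *= 0.5
                if dt < 1e-8:
                    raise IntegrationError(
                        f"step size underflow at t={t:.6f}s (cycle {cycle})")
                continue
            y1, f1, n_iter = out
            # local truncation proxy: TR vs forward-Euler discrepancy
            err = max(abs(0.5 * dt * (f1[i] - f0[i])) / (abs(y1[i]) + 1.0)
                      for i in range(9))
            if err > lte_tol and dt > 2e-5:
                dt *= 0.5
                continue
            # diode events: a conduit flow crossing zero from above
            crossing = [i for i in _DIODE_INDICES if y[i] > 0.0 and y1[i] < 0.0]
            if crossing:
                lo, hi = 0.0, dt
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    sub = _trap_step(rhs, t, y, f0, mid, newton_tol)
                    if sub is None:
                        hi = mid
                        continue
                    if min(sub[0][i] for i in crossing) < 0.0:
                        hi = mid
                    else:
                        lo = mid
                    if hi - lo < 1e-6:
                        break
                sub = _trap_step(rhs, t, y, f0, max(lo, 1e-9), newton_tol)
                if sub is not None:
                    y1, f1, n_iter = sub
                    dt_used = max(lo, 1e-9)
                else:
                    dt_used = dt
                for i in _DIODE_INDICES:
                    if y1[i] < 0.0:
                        y1[i] = 0.0
                f1 = rhs(t + dt_used, y1)
            else:
                dt_used = dt
            for i in _DIODE_INDICES:
                if y1[i] < 0.0:
                    y1[i] = 0.0
            if not all(math.isfinite(v) for v in y1):
                raise IntegrationError(f"non-finite state at t={t:.6f}s")
            # accept
            sv_acc += 0.5 * dt_used * (y[_IQ_AV] + y1[_IQ_AV])
            qub1, qgr1 = _branch_flows(y1)
            sv_ub += 0.5 * dt_used * (qub0 + qub1)
            sv_graft += 0.5 * dt_used * (qgr0 + qgr1)
            sv_coa += 0.5 * dt_used * (y[_IQ_COA] + y1[_IQ_COA])
            sv_pv += 0.5 * dt_used * (
                pulmonary_inflow(t % T, q_mpv_, t_ee_, T)
                + pulmonary_inflow((t + dt_used) % T, q_mpv_, t_ee_, T))
            sv_out += 0.5 * dt_used * (
                (y[_IP_SA] - params.p_cv0) + (y1[_IP_SA] - params.p_cv0)) * inv_rs_
            qub0, qgr0 = qub1, qgr1
            t += dt_used
            y = y1
            f0 = f1
            if y[_IP_AO] > p_ao_max:
                p_ao_max = y[_IP_AO]
            if y[_IP_AO] < p_ao_min:
                p_ao_min = y[_IP_AO]
            if record:
                rec_times.append(t)
                rec_cycles.append(cycle)
                rec_rows.append(_derived_signals(t, y, params))
            # grow step when both solver and error were comfortable
            if n_iter <= 3 and err < 0.25 * lte_tol:
                dt = min(dt * 1.5, dt_max)
        cycle_done = cycle + 1
        summaries.append((cycle, p_ao_max, p_ao_min, sv_acc, sv_ub, sv_coa,
                          sv_graft, sv_pv, sv_out))
        if prev is not None and prev[3] > 0:
            drift = max(abs(p_ao_max - prev[1]) / max(abs(prev[1]), 1e-9),
                        abs(p_ao_min - prev[2]) / max(abs(prev[2]), 1e-9),
                        abs(sv_acc - prev[3]) / max(abs(prev[3]), 1e-9))
            if drift < steady_tol:
                if steady and stop_when_steady and rec_times:
                    prev = (cycle, p_ao_max, p_ao_min, sv_acc)
                    break
                steady = True
            else:
                steady = False
        prev = (cycle, p_ao_max, p_ao_min, sv_acc)

    summary = pd.DataFrame(summaries, columns=[
        "cycle", "sbp", "dbp", "sv", "sv_ub", "sv_coa", "sv_graft",
        "sv_pv", "sv_out"])
    rows = np.asarray(rec_rows)
    signals = {name: rows[:, i] for i, name in enumerate(_SIGNAL_NAMES)}
    return CycleWaveforms(
        time=np.asarray(rec_times), cycle_index=np.asarray(rec_cycles),
        signals=signals, T=T, steady=steady, n_cycles_run=cycle_done,
        cycle_summary=summary, final_state=CircuitState(*y),
    )
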