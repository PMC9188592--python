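"""Patient-specific calibration: the `CoarctationModel` / results objects.

The model owns a patient record and a parameterized 0D circuit; ``fit()``
runs the sequential response optimization that makes the circuit reproduce
the patient's non-invasive measurements:

1. ``calibrate_qmpv`` — the pulmonary inflow amplitude Q_MPV is root-found
   so the simulated forward LVOT stroke volume matches the Doppler value.
2. ``calibrate_systemic`` — R_SA and the arterial compliances are adjusted
   by bound-constrained least squares so the simulated aortic pressure
   extremes match the cuff systolic/diastolic pressures (R_ao, R_SV stay
   fixed; the C_ao:C_SAC split is held at its canonical proportion — see
   the function docstring for the identifiability argument).
3. ``calibrate_flow_split`` — R_ub is root-found so the upper-body stroke
   volume matches the Doppler-derived arch-branch flow (post state) or a
   15% fraction of forward flow (pre state).

Because the flow-split step perturbs the pressures, the three steps are
iterated to joint convergence (outer loop, max 5 passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .circuit import (CircuitParams, CircuitState, CycleWaveforms,
                      default_circuit_params, simulate)
from .patient import (PatientRecord, descending_sv_from_doppler,
                      load_patient)

__all__ = [
    "CalibrationTargets", "CalibrationError", "CoarctationModel",
    "CalibrationResults", "calibrate_qmpv", "calibrate_systemic",
    "calibrate_flow_split", "run_full_calibration", "targets_from_record",
    "synthesize_record_from_params", "steady_metrics",
]

#: default pre-state arch-branch share of forward flow
PRE_BRANCH_FRACTION = 0.15

#: canonical starting values of the systemic fit (mmHg*s/mL, mL/mmHg)
SYSTEMIC_INITIAL = {"r_sa": 0.8, "c_sac": 2.0, "c_ao": 0.5}


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationTargets:
    """Measured quantities the calibrated circuit must reproduce."""

    forward_lvot_sv: float            # mL
    sbp: float                        # mmHg
    dbp: float                        # mmHg
    branch_sv_target: Optional[float] = None      # mL (post only)
    descending_sv_target: Optional[float] = None  # mL (post only)

    def __post_init__(self) -> None:
        if min(self.forward_lvot_sv, self.sbp, self.dbp) <= 0:
            raise CalibrationError("targets must be positive")
        if self.sbp <= self.dbp:
            raise CalibrationError("require sbp > dbp")
        if self.branch_sv_target is not None and self.descending_sv_target is not None:
            if abs(self.branch_sv_target + self.descending_sv_target
                   - self.forward_lvot_sv) > 0.01 * self.forward_lvot_sv:
                raise CalibrationError(
                    "branch + descending targets must equal forward SV within 1%")


def targets_from_record(record: PatientRecord) -> CalibrationTargets:
    d = record.doppler
    branch = descending = None
    if record.state == "post":
        descending = descending_sv_from_doppler(d.a_dao, d.vti_dao)
        branch = d.forward_lvot_sv - descending
    return CalibrationTargets(
        forward_lvot_sv=d.forward_lvot_sv, sbp=record.pressures.sbp,
        dbp=record.pressures.dbp, branch_sv_target=branch,
        descending_sv_target=descending)


# ---------------------------------------------------------------------------
# steady-state metric extraction


def _aitken(values: np.ndarray) -> float:
    """Extrapolate the limit of a near-geometric per-cycle sequence."""
    if len(values) < 3:
        return float(values[-1])
    v1, v2, v3 = values[-3:]
    d1, d2 = v2 - v1, v3 - v2
    if abs(d1) < 1e-14:
        return float(v3)
    r = d2 / d1
    if 0.0 < r < 0.97:
        return float(v3 + d2 * r / (1.0 - r))
    return float(v3)


def steady_metrics(waves: CycleWaveforms) -> Dict[str, float]:
    """Steady-cycle SBP, DBP and branch stroke volumes, extrapolated from
    the per-cycle summaries to remove residual cycle-to-cycle drift."""
    s = waves.cycle_summary
    return {k: _aitken(s[k].to_numpy()) for k in
            ("sbp", "dbp", "sv", "sv_ub", "sv_coa", "sv_graft", "sv_pv",
             "sv_out")}


class _Simulator:
    """Simulation cache: warm-starts each run from the previous final state."""

    def __init__(self, n_cycles: int = 80, steady_tol: float = 1e-3):
        self.state: Optional[CircuitState] = None
        self.n_cycles = n_cycles
        self.steady_tol = steady_tol
        self.n_runs = 0

    def run(self, params: CircuitParams,
            from_state: Optional[CircuitState] = None) -> Dict[str, float]:
        """Simulate to steady state.  With ``from_state`` the run starts from
        that exact state and does not advance the cache — evaluations become
        deterministic functions of ``params``, which gradient-based fitting
        needs."""
        frozen = from_state is not None
        waves = simulate(params, n_cycles=self.n_cycles,
                         steady_tol=self.steady_tol,
                         initial_state=from_state if frozen else self.state,
                         stop_when_steady=True)
        if not frozen:
            self.state = waves.final_state
        self.n_runs += 1
        return steady_metrics(waves)


# ---------------------------------------------------------------------------
# calibration steps


def calibrate_qmpv(params: CircuitParams, target_sv: float,
                   rtol: float = 1e-3, max_iter: int = 12,
                   sim: Optional[_Simulator] = None) -> float:
    """Root-find Q_MPV so the simulated forward LVOT-SV hits ``target_sv``.

    The map Q_MPV -> SV is nearly linear (per-beat volume conservation), so
    a proportional/secant update converges in a few simulations.
    """
    if target_sv <= 0:
        raise CalibrationError("target_sv must be > 0")
    sim = sim or _Simulator()
    q = params.q_mpv
    q_prev = sv_prev = None
    for _ in range(max_iter):
        sv = sim.run(replace(params, q_mpv=q))["sv"]
        if sv <= 0:
            raise CalibrationError(
                f"no forward flow at q_mpv={q:.3g}; diagnostic sweep advised")
        if abs(sv - target_sv) <= rtol * target_sv:
            return q
        if q_prev is not None and abs(sv - sv_prev) > 1e-12:
            q_new = q + (target_sv - sv) * (q - q_prev) / (sv - sv_prev)
        else:
            q_new = q * target_sv / sv
        if not 0.05 * q <= q_new <= 20.0 * q:
            q_new = q * target_sv / sv
        q_prev, sv_prev = q, sv
        q = q_new
    raise CalibrationError(
        f"Q_MPV root-find did not reach {rtol:.0e} in {max_iter} iterations "
        f"(last SV {sv:.3f} vs target {target_sv:.3f})")


def calibrate_systemic(params: CircuitParams, sbp: float, dbp: float,
                       sim: Optional[_Simulator] = None):
    """Fit the systemic parameters so the simulated aortic pressure extremes
    match the cuff systolic/diastolic pressures.

    R_SA and the compliances start from their canonical initial values
    (:data:`SYSTEMIC_INITIAL`).  The *split* between C_ao and C_SAC is not
    identifiable from two pressure values alone — the two compliances act
    nearly in parallel through the small R_ao — so the fit holds their
    ratio at the canonical proportion and adjusts a single common scale.
    The resulting 2x2 system, (R_SA, compliance scale) -> (SBP, DBP), is
    well-posed: its solution is a deterministic function of the targets,
    which makes calibration reproducible and round-trip recoverable.
    Returns ``(r_sa, c_sac, c_ao)``.
    """
    if sbp <= dbp:
        raise CalibrationError("require sbp > dbp")
    sim = sim or _Simulator()
    # settle once, then evaluate every trial from this same frozen state so
    # the residual function is smooth and deterministic in the parameters
    sim.run(params)
    state0 = sim.state

    base_r = SYSTEMIC_INITIAL["r_sa"]
    base_csac = SYSTEMIC_INITIAL["c_sac"]
    base_cao = SYSTEMIC_INITIAL["c_ao"]

    def trial(x):
        return replace(params, r_sa=base_r * x[0],
                       c_sac=base_csac * x[1], c_ao=base_cao * x[1])

    def residuals(x):
        m = sim.run(trial(x), from_state=state0)
        return np.array([m["sbp"] - sbp, m["dbp"] - dbp])

    # start from the incoming values (multiplicative factors near 1 keep
    # the relative finite-difference step above the integrator noise floor)
    x_start = np.clip(np.array([params.r_sa / base_r,
                                params.c_sac / base_csac]), 0.21, 9.5)
    res = least_squares(residuals, x_start, bounds=(0.1, 10.0),
                        diff_step=0.05, xtol=1e-8, ftol=1e-10, gtol=1e-10,
                        max_nfev=50)
    p = trial(res.x)
    return float(p.r_sa), float(p.c_sac), float(p.c_ao)


def calibrate_flow_split(params: CircuitParams, targets: CalibrationTargets,
                         rtol: float = 5e-3, max_iter: int = 15,
                         sim: Optional[_Simulator] = None) -> float:
    """Root-find R_ub so the upper-body stroke volume matches its target.

    Post state: the target is forward SV minus the Doppler descending-aorta
    SV.  Pre state (no Doppler split): upper-body flow is set to 15% of
    forward SV.  Branch SV is strictly decreasing in R_ub, so a secant on
    log(R_ub) converges quickly.
    """
    if targets.branch_sv_target is not None:
        branch_target = targets.branch_sv_target
    else:
        branch_target = PRE_BRANCH_FRACTION * targets.forward_lvot_sv
    if branch_target <= 0 or branch_target >= targets.forward_lvot_sv:
        raise CalibrationError(
            f"unattainable branch target {branch_target:.2f} mL of "
            f"{targets.forward_lvot_sv:.2f} mL forward SV")
    sim = sim or _Simulator()
    r = params.r_ub
    r_prev = sv_prev = None
    for _ in range(max_iter):
        sv_ub = sim.run(replace(params, r_ub=r))["sv_ub"]
        if abs(sv_ub - branch_target) <= rtol * branch_target:
            return r
        if r_prev is not None and abs(sv_ub - sv_prev) > 1e-12:
            # secant in log(r): branch SV ~ const / r at fixed pressures
            lr = math.log(r) + (branch_target - sv_ub) \
                * (math.log(r) - math.log(r_prev)) / (sv_ub - sv_prev)
            r_new = math.exp(lr)
        else:
            r_new = r * sv_ub / branch_target
        if not 0.05 * r <= r_new <= 20.0 * r:
            r_new = r * sv_ub / branch_target
        r_prev, sv_prev = r, sv_ub
        r = r_new
    raise CalibrationError(
        f"R_ub root-find did not reach {rtol:.0e} in {max_iter} iterations")


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class CalibrationResults:
    """Calibrated parameters, fit residuals and diagnostics.

    ``params`` holds the five calibrated quantities (q_mpv mL/s; r_sa, r_ub
    mmHg*s/mL; c_sac, c_ao mL/mmHg); ``residuals`` holds per-target relative
    errors (pressures as absolute mmHg).
    """

    model: "CoarctationModel"
    circuit_params: CircuitParams
    params: pd.Series
    residuals: Dict[str, float]
    converged: bool
    n_outer: int
    n_simulations: int

    def simulate(self, n_cycles: int = 150, **kwargs) -> CycleWaveforms:
        """Simulate the calibrated circuit (defaults: full steady protocol)."""
        kwargs.setdefault("steady_tol", 1e-3)
        return simulate(self.circuit_params, n_cycles=n_cycles, **kwargs)

    def hemodynamics(self, waves: Optional[CycleWaveforms] = None):
        """Clinical summary (Doppler gradient, SAC, branch stroke volumes)."""
        from .metrics import summarize_hemodynamics
        if waves is None:
            waves = self.simulate()
        return summarize_hemodynamics(waves, self.circuit_params)

    def summary(self) -> str:
        rec = self.model.record
        lines = [
            "          Coarctation circulation model — calibration results",
            "=" * 74,
            f"state: {rec.state:<6}  converged: {self.converged}   "
            f"outer loops: {self.n_outer}   simulations: {self.n_simulations}",
            "-" * 74,
            f"{'parameter':<12}{'value':>12}  unit",
            f"{'q_mpv':<12}{self.params['q_mpv']:>12.3f}  mL/s",
            f"{'r_sa':<12}{self.params['r_sa']:>12.4f}  mmHg*s/mL",
            f"{'c_sac':<12}{self.params['c_sac']:>12.4f}  mL/mmHg",
            f"{'c_ao':<12}{self.params['c_ao']:>12.4f}  mL/mmHg",
            f"{'r_ub':<12}{self.params['r_ub']:>12.4f}  mmHg*s/mL",
            "-" * 74,
            "residuals: " + ", ".join(
                f"{k}={v:.3g}" for k, v in self.residuals.items()),
            "=" * 74,
        ]
        return "\n".join(lines)


class CoarctationModel:
    """0D left-heart + systemic circulation model for one patient-state.

    Parameters
    ----------
    record : PatientRecord
        Doppler and cuff measurements (pre or post bypass graft).
    **circuit_overrides
        Overrides forwarded to the circuit builder (e.g. ``r_sa=1.0``).
    """

    def __init__(self, record: PatientRecord, **circuit_overrides):
        self.record = record
        self.circuit_overrides = circuit_overrides
        self.circuit_params = default_circuit_params(record, **circuit_overrides)
        self.targets = targets_from_record(record)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "CoarctationModel":
        return cls(load_patient(path), **overrides)

    def simulate(self, n_cycles: int = 150, **kwargs) -> CycleWaveforms:
        """Simulate the (possibly uncalibrated) circuit."""
        return simulate(self.circuit_params, n_cycles=n_cycles, **kwargs)

    def fit(self, sv_rtol: float = 1e-3, pressure_tol: float = 0.5,
            split_rtol: float = 5e-3, max_outer: int = 5) -> CalibrationResults:
        """Run the sequential calibration to joint convergence."""
        p = self.circuit_params
        tg = self.targets
        sim = _Simulator()
        converged = False
        n_outer = 0
        residuals: Dict[str, float] = {}
        branch_target = tg.branch_sv_target if tg.branch_sv_target \
            is not None else PRE_BRANCH_FRACTION * tg.forward_lvot_sv

        def verify():
            m = sim.run(p)
            return {
                "sv_rel": abs(m["sv"] - tg.forward_lvot_sv) / tg.forward_lvot_sv,
                "sbp_mmhg": abs(m["sbp"] - tg.sbp),
                "dbp_mmhg": abs(m["dbp"] - tg.dbp),
                "branch_rel": abs(m["sv_ub"] - branch_target) / branch_target,
            }

        for n_outer in range(1, max_outer + 1):
            # each loop re-verifies all targets and re-runs only the steps
            # whose residual is out of tolerance
            residuals = verify()
            if (residuals["sv_rel"] < sv_rtol
                    and residuals["sbp_mmhg"] < pressure_tol
                    and residuals["dbp_mmhg"] < pressure_tol
                    and residuals["branch_rel"] < split_rtol):
                converged = True
                break
            if residuals["sv_rel"] >= sv_rtol:
                p = replace(p, q_mpv=calibrate_qmpv(
                    p, tg.forward_lvot_sv, rtol=sv_rtol, sim=sim))
            if (residuals["sbp_mmhg"] >= pressure_tol
                    or residuals["dbp_mmhg"] >= pressure_tol):
                r_sa, c_sac, c_ao = calibrate_systemic(p, tg.sbp, tg.dbp, sim=sim)
                p = replace(p, r_sa=r_sa, c_sac=c_sac, c_ao=c_ao)
            if residuals["branch_rel"] >= split_rtol:
                p = replace(p, r_ub=calibrate_flow_split(
                    p, tg, rtol=split_rtol, sim=sim))
        else:
            residuals = verify()
            converged = (residuals["sv_rel"] < sv_rtol
                         and residuals["sbp_mmhg"] < pressure_tol
                         and residuals["dbp_mmhg"] < pressure_tol
                         and residuals["branch_rel"] < split_rtol)
        params = pd.Series({"q_mpv": p.q_mpv, "r_sa": p.r_sa, "c_sac": p.c_sac,
                            "c_ao": p.c_ao, "r_ub": p.r_ub})
        return CalibrationResults(
            model=self, circuit_params=p, params=params, residuals=residuals,
            converged=converged, n_outer=n_outer, n_simulations=sim.n_runs)


def synthesize_record_from_params(params: CircuitParams,
                                  template: PatientRecord) -> PatientRecord:
    """Generate the record a sonographer would measure on a virtual patient
    whose circulation is exactly ``params``.

    Simulates to steady state and rewrites the template's forward LVOT-SV,
    VTIs and cuff pressures from the simulated waveforms (anatomical areas,
    EOAs and timing stay as in the template).  Used for round-trip
    parameter-recovery experiments.
    """
    from dataclasses import replace as dc_replace
    waves = simulate(params, n_cycles=150, steady_tol=1e-4,
                     stop_when_steady=True)
    m = steady_metrics(waves)
    d = template.doppler
    sv = m["sv"]
    descending = m["sv_coa"] + m["sv_graft"]
    doppler = dc_replace(d, forward_lvot_sv=sv, vti_lvot=sv / d.a_lvot,
                         vti_dao=descending / d.a_dao)
    pressures = type(template.pressures)(sbp=m["sbp"], dbp=m["dbp"])
    return dc_replace(template, doppler=doppler, pressures=pressures)


def run_full_calibration(record: PatientRecord, **fit_kwargs):
    """Functional wrapper: calibrate a record, returning
    ``(CircuitParams, CalibrationResults)``."""
    results = CoarctationModel(record).fit(**fit_kwargs)
    return results.circuit_params, results
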