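"""Patient measurement records and the synthetic-patient generator.

A :class:`PatientRecord` bundles everything the 0D model needs about one
patient in one state (pre- or post-bypass-graft): Doppler echocardiography
scalars (areas, velocity--time integrals, effective orifice areas, volumes,
timing) and sphygmomanometer brachial pressures.  Real clinical records are
not shipped; :func:`generate_synthetic_patient` draws physiologically
plausible records spanning the envelope seen in adult coarctation cohorts.

Units are clinical throughout: cm^2, cm, mL, s, mmHg (see :mod:`coaflow.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import yaml

from .units import MU_BLOOD

__all__ = [
    "DopplerMeasurements",
    "PressureMeasurements",
    "GraftGeometry",
    "PatientRecord",
    "InvalidMeasurementError",
    "forward_lvot_sv_from_doppler",
    "descending_sv_from_doppler",
    "graft_resistance",
    "generate_synthetic_patient",
    "load_patient",
    "save_patient",
]

SEVERITY_RATIOS = {"none": 1.0, "mild": 0.6, "moderate": 0.4, "severe": 0.25}


class InvalidMeasurementError(ValueError):
    """A measurement violates its physical/physiological constraints."""


@dataclass
class DopplerMeasurements:
    """Doppler echocardiography scalars for one patient-state.

    Areas in cm^2, VTIs in cm, volumes in mL, times in s, rates in 1/min.
    """

    heart_rate: float
    cycle_duration_T: float
    ejection_time: float
    forward_lvot_sv: float
    a_lvot: float
    vti_lvot: float
    a_ao: float
    a_dao: float
    vti_dao: float
    eoa_av: float
    eoa_mv: float
    eoa_coa: float
    a_downstream_coa: float
    eoa_ar: float = 0.0
    eoa_mr: float = 0.0
    edv: float = 150.0
    esv: float = 70.0

    def validate(self) -> None:
        d = self
        for name in ("a_lvot", "a_ao", "a_dao", "eoa_av", "eoa_mv", "eoa_coa",
                     "a_downstream_coa"):
            if getattr(d, name) <= 0:
                raise InvalidMeasurementError(f"{name} must be > 0")
        if d.eoa_ar < 0 or d.eoa_mr < 0:
            raise InvalidMeasurementError("regurgitant EOAs must be >= 0")
        if not d.eoa_av < d.a_ao:
            raise InvalidMeasurementError("eoa_av must be < a_ao")
        if not d.eoa_coa <= d.a_downstream_coa:
            raise InvalidMeasurementError("eoa_coa must be <= a_downstream_coa")
        if abs(d.cycle_duration_T - 60.0 / d.heart_rate) > 0.01 * d.cycle_duration_T:
            raise InvalidMeasurementError("cycle_duration_T inconsistent with heart_rate")
        if d.forward_lvot_sv <= 0:
            raise InvalidMeasurementError("forward_lvot_sv must be > 0")
        if not 0 < d.ejection_time < d.cycle_duration_T:
            raise InvalidMeasurementError("ejection_time must lie within the cycle")

    def __post_init__(self) -> None:
        self.validate()


@dataclass
class PressureMeasurements:
    """Brachial cuff pressures, mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise InvalidMeasurementError("require sbp > dbp > 0")


@dataclass
class GraftGeometry:
    """Extra-anatomical bypass-graft conduit dimensions (cm)."""

    length: float
    diameter: float
    origin: str = "left_subclavian"  # or "aortic_arch"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidMeasurementError("graft length and diameter must be > 0")
        if self.origin not in ("left_subclavian", "aortic_arch"):
            raise InvalidMeasurementError(f"unknown graft origin {self.origin!r}")


@dataclass
class PatientRecord:
    doppler: DopplerMeasurements
    pressures: PressureMeasurements
    state: str = "pre"  # "pre" | "post"
    graft: Optional[GraftGeometry] = None

    def __post_init__(self) -> None:
        if self.state not in ("pre", "post"):
            raise InvalidMeasurementError(f"unknown state {self.state!r}")
        if self.state == "post" and self.graft is None:
            raise InvalidMeasurementError("post-intervention record requires a graft")
        if self.state == "pre" and self.graft is not None:
            raise InvalidMeasurementError("pre-intervention record must not carry a graft")


def forward_lvot_sv_from_doppler(a_lvot: float, vti_lvot: float) -> float:
    """Forward LVOT stroke volume (mL) from LVOT area (cm^2) and VTI (cm).

    The Doppler product A_LVOT * VTI_LVOT: total volume crossing the LV
    outflow tract per beat.
    """
    if a_lvot <= 0:
        raise InvalidMeasurementError("a_lvot must be > 0")
    if vti_lvot < 0:
        raise InvalidMeasurementError("vti_lvot must be >= 0")
    return a_lvot * vti_lvot


def descending_sv_from_doppler(a_dao: float, vti_dao: float) -> float:
    """Descending-aorta stroke volume (mL): A_DAO * VTI_DAO.

    Post-intervention this is the per-beat volume through COA plus graft.
    """
    if a_dao <= 0:
        raise InvalidMeasurementError("a_dao must be > 0")
    if vti_dao < 0:
        raise InvalidMeasurementError("vti_dao must be >= 0")
    return a_dao * vti_dao


def graft_resistance(geom: GraftGeometry, viscosity: float = MU_BLOOD) -> float:
    """Poiseuille resistance of the graft conduit, mmHg*s/mL.

    R = 128 mu L / (pi D^4) with geometry in cm and viscosity in Pa*s,
    converted to clinical units.
    """
    if viscosity <= 0:
        raise InvalidMeasurementError("viscosity must be > 0")
    length_m = geom.length / 100.0
    diam_m = geom.diameter / 100.0
    r_si = 128.0 * viscosity * length_m / (math.pi * diam_m**4)  # Pa*s/m^3
    return r_si / 133.322 / 1.0e6  # -> mmHg*s/mL


def generate_synthetic_patient(
    seed: int,
    severity: str = "moderate",
    state: str = "pre",
) -> PatientRecord:
    """Draw a synthetic coarctation patient record.

    Deterministic for a fixed seed.  ``severity`` controls the stenosis ratio
    EOA_coa / A_downstream via {none: 1.0, mild: 0.6, moderate: 0.4,
    severe: 0.25}, spanning peak trans-coarctation gradients of roughly
    0--14 mmHg.  Brachial pressures fall in [120, 160] / [50, 80] mmHg and
    forward LVOT-SV in [55, 90] mL, the envelope of adult COA cohorts.
    """
    if severity not in SEVERITY_RATIOS:
        raise InvalidMeasurementError(f"unknown severity {severity!r}")
    rng = np.random.default_rng(seed)
    hr = rng.uniform(60.0, 90.0)
    T = 60.0 / hr
    t_ej = rng.uniform(0.30, 0.36) * T

    sv = rng.uniform(55.0, 90.0)
    a_lvot = rng.uniform(3.0, 4.5)
    vti_lvot = sv / a_lvot

    a_ao = rng.uniform(5.0, 8.0)
    eoa_av = rng.uniform(1.5, min(3.5, 0.7 * a_ao))
    eoa_mv = rng.uniform(3.0, 5.0)

    a_down = rng.uniform(2.2, 3.5)
    eoa_coa = SEVERITY_RATIOS[severity] * a_down

    # Descending flow fraction of forward SV; the remainder crosses the
    # arch branches, so the split can never exceed the forward volume.
    frac = rng.uniform(0.55, 0.75)
    a_dao = rng.uniform(2.0, 3.0)
    vti_dao = frac * sv / a_dao

    edv = rng.uniform(max(110.0, sv + 45.0), 180.0)
    esv = edv - sv - rng.uniform(5.0, 15.0)

    sbp = rng.uniform(120.0, 160.0)
    dbp = rng.uniform(50.0, 80.0)

    doppler = DopplerMeasurements(
        heart_rate=hr, cycle_duration_T=T, ejection_time=t_ej,
        forward_lvot_sv=sv, a_lvot=a_lvot, vti_lvot=vti_lvot,
        a_ao=a_ao, a_dao=a_dao, vti_dao=vti_dao,
        eoa_av=eoa_av, eoa_mv=eoa_mv,
        eoa_coa=eoa_coa, a_downstream_coa=a_down,
        eoa_ar=0.0, eoa_mr=0.0, edv=edv, esv=esv,
    )
    pressures = PressureMeasurements(sbp=sbp, dbp=dbp)
    graft = None
    if state == "post":
        graft = GraftGeometry(
            length=rng.uniform(6.9, 8.3),
            diameter=rng.uniform(1.5, 1.7),
            origin=str(rng.choice(["left_subclavian", "aortic_arch"])),
        )
    return PatientRecord(doppler=doppler, pressures=pressures, state=state, graft=graft)


# ---------------------------------------------------------------------------
# flat-file I/O (one YAML document per patient-state; scalar keys only)

def _record_to_dict(record: PatientRecord) -> dict:
    out = {"state": record.state}
    out.update({f"doppler.{k}": float(v) for k, v in asdict(record.doppler).items()})
    out["pressures.sbp"] = float(record.pressures.sbp)
    out["pressures.dbp"] = float(record.pressures.dbp)
    if record.graft is not None:
        out["graft.length"] = float(record.graft.length)
        out["graft.diameter"] = float(record.graft.diameter)
        out["graft.origin"] = record.graft.origin
    return out


def save_patient(record: PatientRecord, path) -> None:
    """Write a record as a flat ``key: value`` YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(_record_to_dict(record), fh, sort_keys=True)


def load_patient(path) -> PatientRecord:
    """Read and strictly validate a flat patient YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidMeasurementError("patient file must be a flat mapping")
    dop = {k.split(".", 1)[1]: v for k, v in raw.items() if k.startswith("doppler.")}
    doppler = DopplerMeasurements(**dop)
    pressures = PressureMeasurements(sbp=raw["pressures.sbp"], dbp=raw["pressures.dbp"])
    graft = None
    if any(k.startswith("graft.") for k in raw):
        graft = GraftGeometry(
            length=raw["graft.length"], diameter=raw["graft.diameter"],
            origin=raw.get("graft.origin", "left_subclavian"),
        )
    known = {k for k in raw if k.startswith(("doppler.", "pressures.", "graft."))}
    extra = set(raw) - known - {"state"}
    if extra:
        raise InvalidMeasurementError(f"unknown keys in patient file: {sorted(extra)}")
    return PatientRecord(doppler=doppler, pressures=pressures,
                         state=raw.get("state", "pre"), graft=graft)
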