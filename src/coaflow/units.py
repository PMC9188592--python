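"""Unit system and conversion constants.

The 0D circulation model is evaluated in clinical units throughout:
volumes in mL, flows in mL/s (= cm^3/s), pressures in mmHg, areas in cm^2,
times in s, blood density in g/cm^3.  Element equations that are naturally
written in CGS (dyn/cm^2) are converted with ``DYN_PER_MMHG``.
"""

#: dyn/cm^2 per mmHg
DYN_PER_MMHG = 1333.22

#: blood density, g/cm^3 (1050 kg/m^3)
RHO_BLOOD = 1.05

#: blood dynamic viscosity, Pa*s
MU_BLOOD = 0.0035

#: blood kinematic viscosity, m^2/s
NU_BLOOD = MU_BLOOD / 1050.0


def mmhg_to_dyn(p_mmhg: float) -> float:
    """Convert pressure from mmHg to dyn/cm^2."""
    return p_mmhg * DYN_PER_MMHG


def dyn_to_mmhg(p_dyn: float) -> float:
    """Convert pressure from dyn/cm^2 to mmHg."""
    return p_dyn / DYN_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure from Pa to mmHg (1 Pa = 10 dyn/cm^2)."""
    return p_pa * 10.0 / DYN_PER_MMHG


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * DYN_PER_MMHG / 10.0
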