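"""Unit conversion layer.

Internally the numerical kernels work in SI (Pa, m^3, m^2, s, N/m).
All public interfaces — config files, dataclasses, CSV output — use the
units conventional in hemodynamics: mmHg, mL, cm^2, ms, kPa.  Sarcomere
length stays in micrometres everywhere (it only enters through ratios and
the twitch-duration slope).  This module is the single place where the two
systems meet.
"""

MMHG_TO_PA = 133.322
KPA_TO_PA = 1.0e3
ML_TO_M3 = 1.0e-6
CM2_TO_M2 = 1.0e-4
CM_TO_M = 1.0e-2
MS_TO_S = 1.0e-3

PA_TO_MMHG = 1.0 / MMHG_TO_PA
M3_TO_ML = 1.0 / ML_TO_M3
M2_TO_CM2 = 1.0 / CM2_TO_M2
M_TO_CM = 1.0 / CM_TO_M
S_TO_MS = 1.0 / MS_TO_S


def r_to_si(r_mmhg_s_per_ml: float) -> float:
    """Resistance mmHg*s/mL -> Pa*s/m^3."""
    return r_mmhg_s_per_ml * MMHG_TO_PA / ML_TO_M3


def r_to_iface(r_si: float) -> float:
    return r_si * ML_TO_M3 / MMHG_TO_PA


def c_to_si(c_ml_per_mmhg: float) -> float:
    """Compliance mL/mmHg -> m^3/Pa."""
    return c_ml_per_mmhg * ML_TO_M3 / MMHG_TO_PA


def c_to_iface(c_si: float) -> float:
    return c_si * MMHG_TO_PA / ML_TO_M3
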