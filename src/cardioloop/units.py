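"""Unit conversions.

The simulator works in SI internally (Pa, m3, s); every public interface
speaks clinical units (mmHg, mL, L/min, bpm). Conversion constants are fixed
here so round trips are exact.
"""

MMHG_PA = 133.322          # 1 mmHg in Pa
ML_M3 = 1e-6               # 1 mL in m3
LMIN_M3S = 1e-3 / 60.0     # 1 L/min in m3/s
G_STANDARD = 9.80665       # m/s2


def mmhg_to_pa(p):
    return p * MMHG_PA


def pa_to_mmhg(p):
    return p / MMHG_PA


def ml_to_m3(v):
    return v * ML_M3


def m3_to_ml(v):
    return v / ML_M3


def lmin_to_m3s(q):
    return q * LMIN_M3S


def m3s_to_lmin(q):
    return q / LMIN_M3S


def m3s_to_mls(q):
    return q / ML_M3


# Resistance: mmHg·s/mL  <->  Pa·s/m3
R_MMHG_S_PER_ML = MMHG_PA / ML_M3


def r_to_si(r):
    """mmHg·s/mL -> Pa·s/m3."""
    return r * R_MMHG_S_PER_ML


def r_from_si(r):
    return r / R_MMHG_S_PER_ML


# Compliance: mL/mmHg <-> m3/Pa
C_ML_PER_MMHG = ML_M3 / MMHG_PA


def c_to_si(c):
    """mL/mmHg -> m3/Pa."""
    return c * C_ML_PER_MMHG


def c_from_si(c):
    return c / C_ML_PER_MMHG


# Elastance: mmHg/mL <-> Pa/m3
def e_to_si(e):
    return e * MMHG_PA / ML_M3


def e_from_si(e):
    return e * ML_M3 / MMHG_PA


# Inertance: mmHg·s2/mL <-> Pa·s2/m3
def l_from_si(l):
    return l * ML_M3 / MMHG_PA
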