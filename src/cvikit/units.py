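"""Unit conversions used across the package.

Internally all mechanics is done in SI (Pa, m); user-facing profiles use the
clinical conventions: pressure in mmHg, wall shear stress in dyn/cm²,
lengths in mm, moduli in kPa.
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322
DYN_CM2_PER_PA = 10.0
PA_PER_DYN_CM2 = 0.1
MM_PER_M = 1000.0
M_PER_MM = 1e-3
KPA_PER_PA = 1e-3
PA_PER_KPA = 1e3


def mmhg_to_pa(p):
    return p * PA_PER_MMHG


def pa_to_mmhg(p):
    return p * MMHG_PER_PA


def dyncm2_to_pa(tau):
    return tau * PA_PER_DYN_CM2


def pa_to_dyncm2(tau):
    return tau * DYN_CM2_PER_PA
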