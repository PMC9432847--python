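"""Unit conventions and conversion constants.

All internal computations use a single CGS system:

* length         cm
* pressure       dyn/cm^2     (interfaces accept/report mmHg)
* viscosity      poise        (interfaces accept/report cP)
* flow           cm^3/s
* oxygen content cm^3 O2 / cm^3 blood
* consumption    cm^3 O2 / cm^3 tissue / s  (interfaces accept the
                 conventional cm^3 O2 / 100 cm^3 / min)

Vessel diameters are exchanged in micrometers at every public interface,
since that is how microvascular geometry is universally reported, and
converted to cm internally.
"""

MMHG_TO_DYN_CM2 = 1333.22
CP_TO_POISE = 1.0e-2
UM_TO_CM = 1.0e-4
CM_TO_UM = 1.0e4

#: cm^3 O2 / 100 cm^3 / min  ->  cm^3 O2 / cm^3 / s
M0_TO_CGS = 1.0e-2 / 60.0


def mmhg_to_cgs(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_DYN_CM2


def cgs_to_mmhg(p_dyn: float) -> float:
    return p_dyn / MMHG_TO_DYN_CM2


def cp_to_poise(mu_cp: float) -> float:
    return mu_cp * CP_TO_POISE


def um_to_cm(d_um: float) -> float:
    return d_um * UM_TO_CM


def demand_to_cgs(m0: float) -> float:
    """Convert oxygen demand from cm^3 O2/100 cm^3/min to CGS."""
    return m0 * M0_TO_CGS
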