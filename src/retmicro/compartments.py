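"""Control-state capillary / small-venule / large-venule compartment chains.

Downstream of every terminal arteriole the microcirculation is represented
by three compartments in series -- capillaries (C), small venules (SV) and
large venules (LV) -- each a set of identical parallel segments.  The chain
is constructed from the solved arteriolar pathway by symmetry assumptions:

* vessel counts:  n_SA = n_SV = 1,  n_LA = n_LV = Q_SA/Q_LA,
  n_C = Q_SA/Q_C  (fractional counts allowed; compartments are continuum
  descriptions, not integer vessel tallies)
* lengths:        L_SV = L_SA,  L_LV = L_LA
* venular diameters from wall-shear-rate symmetry:
  D_SV = D_SA (w_SA/w_SV)^(1/3),  D_LV = D_LA (w_LA/w_LV)^(1/3)

Capillary flow comes from an assumed capillary wall shear stress,
Q_C = pi tau_C D_C^3 / (32 mu_C).  Venular pressure drops follow Poiseuille;
the capillary pressure drop is the residual of the total perfusion pressure
P_a - IOP, and the capillary length follows from Poiseuille in turn.

The tissue annulus width d shared by all capillaries is fixed by a
prescribed capillary density N over the total tissue volume (arteriolar
region volume A_VOL plus the Krogh cylinders of the compartments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hemodynamics import FlowSolution, viscosity_in_vivo
from .network import VascularNetwork
from .units import CP_TO_POISE, UM_TO_CM, mmhg_to_cgs

#: wall shear rate (1/s) versus luminal diameter (um).  The two venular
#: anchor rows -- 684/s at the 69 um small-venule reference diameter and
#: 615/s at the 140 um large-venule reference diameter -- are fixed by the
#: control-state shear stresses and viscosities of the compartments; the
#: arteriolar rows are a smooth monotone extension representative of in-vivo
#: microvascular shear rates.  Synthetic default; override via
#: ``ControlStateParams.shear_rate_table``.
DEFAULT_SHEAR_RATE_TABLE: tuple[tuple[float, float], ...] = (
    (6.0, 2000.0),
    (22.0, 1650.0),
    (40.0, 1100.0),
    (69.0, 684.0),
    (100.0, 640.0),
    (140.0, 615.0),
)


@dataclass
class ControlStateParams:
    """Scalar parameters defining the healthy (control) reference state."""

    p_a: float = 40.0                 # incoming arterial pressure, mmHg
    iop: float = 15.0                 # intraocular pressure, mmHg
    arteriolar_drop: float = 16.0     # end-to-end arteriolar dP, mmHg
    d_c_um: float = 6.0               # capillary diameter
    tau_c: float = 15.0               # capillary wall shear stress, dyn/cm^2
    capillary_density: float = 50_000.0   # N, 1/cm^2
    a_vol: float = 0.0025             # arteriolar region volume, cm^3
    d_sv_anchor_um: float = 69.0      # SV reference diameter for shear lookup
    d_lv_anchor_um: float = 140.0     # LV reference diameter for shear lookup
    plasma_viscosity_cp: float = 1.0
    shear_rate_table: tuple[tuple[float, float], ...] = DEFAULT_SHEAR_RATE_TABLE

    def validate(self) -> None:
        if self.p_a <= self.iop:
            raise ValueError("P_a must exceed IOP")
        for name in ("arteriolar_drop", "d_c_um", "tau_c", "capillary_density", "a_vol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Compartment:
    kind: str              # "C", "SV" or "LV"
    n: float               # parallel segment count (may be fractional)
    diameter_um: float
    length_cm: float
    viscosity_cp: float
    wall_shear: float      # dyn/cm^2
    pressure_drop: float   # mmHg
    q_per_segment: float   # cm^3/s


@dataclass
class CompartmentChain:
    pathway_index: int
    terminal_segment: str
    capillary: Compartment
    small_venule: Compartment
    large_venule: Compartment
    hematocrit: float              # discharge hematocrit handed down the chain
    q_pathway: float               # Q_SA, cm^3/s
    d_la_um: float
    d_sa_um: float
    tissue_width_cm: float = 0.0   # d = r_t - r_v, set by solve_tissue_width

    @property
    def compartments(self) -> list[Compartment]:
        return [self.capillary, self.small_venule, self.large_venule]


def capillary_flow(tau_c: float, d_c_um: float, mu_c_cp: float) -> float:
    """Single-capillary flow Q_C = pi tau_C D_C^3 / (32 mu_C), cm^3/s."""
    if tau_c < 0 or d_c_um <= 0 or mu_c_cp <= 0:
        raise ValueError("tau >= 0 and D, mu > 0 required")
    d = d_c_um * UM_TO_CM
    mu = mu_c_cp * CP_TO_POISE
    return np.pi * tau_c * d**3 / (32.0 * mu)


def interpolate_shear_rate(d_um: float, table=DEFAULT_SHEAR_RATE_TABLE) -> float:
    """Linear interpolation of wall shear rate in diameter.

    Diameters above the tabulated range return the value at the largest knot
    (the maximum possible interpolated value -- shear rates are nearly
    constant at large calibers); below the range is an error.
    """
    tab = sorted(table)
    if len(tab) < 2:
        raise ValueError("shear-rate table needs at least two rows")
    ds = np.array([r[0] for r in tab])
    ws = np.array([r[1] for r in tab])
    if np.any(np.diff(ds) <= 0):
        raise ValueError("shear-rate table diameters must be strictly increasing")
    if d_um < ds[0]:
        raise ValueError(f"diameter {d_um} um below shear-rate table range")
    if d_um >= ds[-1]:
        return float(ws[-1])
    return float(np.interp(d_um, ds, ws))


def venular_diameters(d_sa_um: float, d_la_um: float, w_sa: float, w_la: float,
                      w_sv: float, w_lv: float) -> tuple[float, float]:
    """Venular diameters from the cube-root wall-shear-rate symmetry."""
    for v in (d_sa_um, d_la_um, w_sa, w_la, w_sv, w_lv):
        if v <= 0:
            raise ValueError("all diameters and shear rates must be positive")
    d_sv = d_sa_um * (w_sa / w_sv) ** (1.0 / 3.0)
    d_lv = d_la_um * (w_la / w_lv) ** (1.0 / 3.0)
    return d_sv, d_lv


def _poiseuille_dp_mmhg(q: float, d_um: float, l_cm: float, mu_cp: float) -> float:
    d = d_um * UM_TO_CM
    return 128.0 * (mu_cp * CP_TO_POISE) * l_cm * q / (np.pi * d**4) / 1333.22


def build_pathway_chain(
    net: VascularNetwork,
    flow: FlowSolution,
    pathway_index: int,
    params: ControlStateParams,
) -> CompartmentChain:
    """Construct the C/SV/LV chain for one classified arteriolar pathway.

    Venular drops are computed first (sequentially); the capillary drop is
    the residual of the total perfusion pressure.  A negative residual is an
    infeasible control state and raises rather than clamps.
    """
    params.validate()
    pw = net.pathways[pathway_index]
    term = net.segments[pw.terminal_segment]
    first = net.segments[pw.first_segment]

    q_sa = flow.flows[term.id]
    q_la = flow.flows[first.id]
    if q_sa <= 0 or q_la <= 0:
        raise ValueError(f"pathway {pathway_index}: non-positive flow")
    hd = flow.hematocrit[term.id]

    d_sa, d_la = term.diameter_um, first.diameter_um
    l_sa, l_la = term.length_cm, first.length_cm

    tab = params.shear_rate_table
    w_sa = interpolate_shear_rate(d_sa, tab)
    w_la = interpolate_shear_rate(d_la, tab)
    w_sv = interpolate_shear_rate(params.d_sv_anchor_um, tab)
    w_lv = interpolate_shear_rate(params.d_lv_anchor_um, tab)
    d_sv, d_lv = venular_diameters(d_sa, d_la, w_sa, w_la, w_sv, w_lv)

    mu_c = viscosity_in_vivo(params.d_c_um, hd, params.plasma_viscosity_cp)
    mu_sv = viscosity_in_vivo(d_sv, hd, params.plasma_viscosity_cp)
    mu_lv = viscosity_in_vivo(d_lv, hd, params.plasma_viscosity_cp)

    q_c = capillary_flow(params.tau_c, params.d_c_um, mu_c)
    n_c = q_sa / q_c
    n_lv = q_sa / q_la          # = n_LA by the vessel-count symmetry
    q_lv = q_sa / n_lv          # per-segment LV flow (= Q_LA)

    dp_sv = _poiseuille_dp_mmhg(q_sa, d_sv, l_sa, mu_sv)
    dp_lv = _poiseuille_dp_mmhg(q_lv, d_lv, l_la, mu_lv)
    # actual solved drop along this pathway (16 mmHg under control boundaries)
    dp_art = (flow.node_pressures[net.inlet_node()]
              - flow.node_pressures[term.to_node])
    dp_c = (params.p_a - params.iop) - dp_art - dp_sv - dp_lv
    if dp_c <= 0:
        raise ValueError(
            f"pathway {pathway_index}: infeasible control state, residual "
            f"capillary pressure drop {dp_c:.3f} mmHg <= 0"
        )
    d_c_cm = params.d_c_um * UM_TO_CM
    l_c = mmhg_to_cgs(dp_c) * np.pi * d_c_cm**4 / (128.0 * mu_c * CP_TO_POISE * q_c)

    tau_sv = w_sv * mu_sv * CP_TO_POISE
    tau_lv = w_lv * mu_lv * CP_TO_POISE

    return CompartmentChain(
        pathway_index=pathway_index,
        terminal_segment=term.id,
        capillary=Compartment("C", n_c, params.d_c_um, l_c, mu_c,
                              params.tau_c, dp_c, q_c),
        small_venule=Compartment("SV", 1.0, d_sv, l_sa, mu_sv, tau_sv, dp_sv, q_sa),
        large_venule=Compartment("LV", n_lv, d_lv, l_la, mu_lv, tau_lv, dp_lv, q_lv),
        hematocrit=hd,
        q_pathway=q_sa,
        d_la_um=d_la,
        d_sa_um=d_sa,
    )


def build_all_chains(net: VascularNetwork, flow: FlowSolution,
                     params: ControlStateParams) -> list[CompartmentChain]:
    if not net.pathways:
        raise ValueError("network pathways missing; run classify_segments first")
    return [build_pathway_chain(net, flow, i, params) for i in range(len(net.pathways))]


def capillary_density_at(d_cm: float, chains: list[CompartmentChain],
                         params: ControlStateParams) -> float:
    """Capillary length density (1/cm^2) implied by tissue annulus width d."""
    r_c = 0.5 * params.d_c_um * UM_TO_CM
    num = 0.0
    vol = params.a_vol
    for ch in chains:
        c, sv, lv = ch.capillary, ch.small_venule, ch.large_venule
        num += c.n * c.length_cm
        vol += c.n * c.length_cm * np.pi * (r_c + d_cm) ** 2
        vol += sv.n * sv.length_cm * np.pi * (0.5 * sv.diameter_um * UM_TO_CM) ** 2
        vol += lv.n * lv.length_cm * np.pi * (0.5 * lv.diameter_um * UM_TO_CM) ** 2
    return num / vol


def solve_tissue_width(chains: list[CompartmentChain], params: ControlStateParams,
                       d_max_cm: float = 1.0) -> float:
    """Solve for the Krogh annulus width d (cm) matching the capillary density.

    The implied density is strictly decreasing in d, so a bracketed root find
    over [0, d_max] is guaranteed a unique root when one exists.  The result
    is written onto every chain's ``tissue_width_cm``.
    """
    if not chains:
        raise ValueError("no compartment chains supplied")
    n_target = params.capillary_density

    def f(d):
        return capillary_density_at(d, chains, params) - n_target

    f0 = f(0.0)
    if f0 < 0:
        raise ValueError(
            f"infeasible capillary density: implied density at d=0 "
            f"({f0 + n_target:.1f}/cm^2) already below target {n_target:.1f}/cm^2"
        )
    if f(d_max_cm) > 0:
        raise ValueError("no root for tissue width d in [0, d_max]")
    d = brentq(f, 0.0, d_max_cm, xtol=1e-12, rtol=1e-12)
    for ch in chains:
        ch.tissue_width_cm = d
    return d
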