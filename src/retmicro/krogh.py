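"""Krogh-cylinder oxygen extraction along the compartment chains.

Each capillary supplies a coaxial tissue annulus of outer radius
r_t = r_v + d.  At a given axial position the radial two-point boundary-value
problem

    K * (1/r) d/dr ( r dP/dr ) = M(P),   P(r_v) = P_b,  dP/dr(r_t) = 0,

(K = D_diff*alpha, M Michaelis-Menten) yields the tissue profile and the
consumption per unit vessel length, q = integral of M(P) 2 pi r dr.  Axial
marching integrates the convective balance d f(P_b)/ds = -q(P_b) down the
capillary, inverting the oxyhemoglobin content relation at every step;
if the blood po2 reaches zero it is clamped there for the rest of the
compartment (consumption ceases without oxygen).  Venules exchange no oxygen
(tissue width zero), so their po2 is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp
from scipy.interpolate import PchipInterpolator

from .compartments import CompartmentChain
from .oxygen import (
    OxygenParams,
    convective_flux,
    hill_saturation,
    hill_saturation_slope,
    invert_content,
    oxygen_content,
)
from .units import UM_TO_CM


@dataclass
class KroghGeometry:
    r_v_cm: float
    r_t_cm: float

    def __post_init__(self) -> None:
        if not (self.r_t_cm >= self.r_v_cm > 0):
            raise ValueError("need r_t >= r_v > 0")

    @property
    def width_cm(self) -> float:
        return self.r_t_cm - self.r_v_cm


def krogh_radial_profile(p_b: float, geom: KroghGeometry, params: OxygenParams,
                         n_nodes: int = 50) -> tuple[np.ndarray, np.ndarray, float]:
    """Radial tissue po2 and consumption per unit vessel length.

    Returns ``(r, po2(r), consumption_per_length)`` with consumption in
    cm^3 O2/cm/s.  The BVP is solved by collocation with Michaelis-Menten
    kinetics evaluated on the positive part of the iterate; the returned
    profile is clamped at zero.
    """
    if p_b < 0:
        raise ValueError("wall po2 must be non-negative")
    k = params.d_diff_alpha
    m0 = params.m0_cgs
    r = np.linspace(geom.r_v_cm, geom.r_t_cm, n_nodes)
    if p_b == 0.0 or m0 == 0.0 or geom.width_cm == 0.0:
        po2 = np.full_like(r, p_b)
        cons = 0.0
        if m0 > 0.0 and p_b > 0.0 and geom.width_cm > 0.0:
            cons = (m0 * p_b / (params.p0 + p_b)
                    * np.pi * (geom.r_t_cm**2 - geom.r_v_cm**2))
        return r, po2, cons

    def rhs(x, y):
        p = np.maximum(y[0], 0.0)
        m = m0 * p / (params.p0 + p)
        return np.vstack([y[1], m / k - y[1] / x])

    def bc(ya, yb):
        return np.array([ya[0] - p_b, yb[1]])

    y0 = np.vstack([np.full_like(r, p_b), np.zeros_like(r)])
    sol = solve_bvp(rhs, bc, r, y0, tol=1e-8, max_nodes=4000)
    rr = np.linspace(geom.r_v_cm, geom.r_t_cm, 200)
    po2 = np.maximum(sol.sol(rr)[0], 0.0)
    m = m0 * po2 / (params.p0 + po2)
    cons = float(np.trapezoid(m * 2.0 * np.pi * rr, rr))
    return rr, po2, cons


class KroghConsumptionModel:
    """Tabulated consumption-per-length q(P_b) for a fixed Krogh geometry.

    The radial BVP is smooth in the wall po2, so it is solved once on a po2
    grid and interpolated monotonically (PCHIP); this keeps the axial
    marching cheap while every capillary in the network shares the same
    (D_C, d) geometry.
    """

    def __init__(self, geom: KroghGeometry, params: OxygenParams,
                 p_max: float = 120.0, n_grid: int = 28) -> None:
        self.geom = geom
        self.params = params
        grid = np.concatenate([[0.0], np.geomspace(0.25, p_max, n_grid - 1)])
        q = np.array([krogh_radial_profile(p, geom, params)[2] for p in grid])
        self._interp = PchipInterpolator(grid, q, extrapolate=False)
        self._p_max = p_max
        self._q_max = q[-1]

    def consumption_per_length(self, p_b: float) -> float:
        if p_b <= 0.0:
            return 0.0
        if p_b >= self._p_max:
            return float(self._q_max)
        return float(self._interp(p_b))


@dataclass
class CompartmentOxygenProfile:
    kind: str                 # "C", "SV" or "LV"
    s: np.ndarray             # axial positions, cm
    p_b: np.ndarray           # blood po2, mmHg
    saturation: np.ndarray
    consumption_per_length: np.ndarray   # cm^3 O2/cm/s
    clamped_from: float | None = None    # axial position where po2 hit zero

    @property
    def upstream_po2(self) -> float:
        return float(self.p_b[0])

    @property
    def downstream_po2(self) -> float:
        return float(self.p_b[-1])


def march_axial(
    chain: CompartmentChain,
    inflow_po2: float,
    params: OxygenParams,
    consumption_model: KroghConsumptionModel | None = None,
    n_steps: int = 200,
    include_dissolved: bool = True,
) -> dict[str, CompartmentOxygenProfile]:
    """Integrate blood po2 along the C -> SV -> LV chain of one pathway.

    The capillary uses fourth-order (RK4) marching of the convective balance
    with the Krogh consumption; venules carry their inflow po2 unchanged.
    The zero-clamp rule is applied: once the blood po2 reaches zero it stays
    zero for the remainder of the capillary and the clamp position is
    recorded.
    """
    if inflow_po2 < 0:
        raise ValueError("inflow po2 must be non-negative")
    cap = chain.capillary
    if consumption_model is None:
        r_v = 0.5 * cap.diameter_um * UM_TO_CM
        geom = KroghGeometry(r_v, r_v + chain.tissue_width_cm)
        consumption_model = KroghConsumptionModel(geom, params)

    q_blood = cap.q_per_segment
    hd = chain.hematocrit

    def dpds(p):
        if p <= 0.0:
            return 0.0
        q_len = consumption_model.consumption_per_length(p)
        dcdp = hd * params.c0 * hill_saturation_slope(p, params.p50, params.n_hill)
        if include_dissolved:
            dcdp += params.alpha_b
        denom = q_blood * dcdp
        if denom <= 1e-30:
            return 0.0
        return -q_len / denom

    s = np.linspace(0.0, cap.length_cm, n_steps + 1)
    h = cap.length_cm / n_steps
    p = np.empty(n_steps + 1)
    p[0] = inflow_po2
    clamped_from = None if inflow_po2 > 0 else 0.0
    for i in range(n_steps):
        if p[i] <= 0.0:
            p[i + 1] = 0.0
            continue
        k1 = dpds(p[i])
        k2 = dpds(max(p[i] + 0.5 * h * k1, 0.0))
        k3 = dpds(max(p[i] + 0.5 * h * k2, 0.0))
        k4 = dpds(max(p[i] + h * k3, 0.0))
        nxt = p[i] + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if nxt <= 0.0:
            nxt = 0.0
            if clamped_from is None:
                clamped_from = s[i + 1]
        p[i + 1] = nxt

    q_len_profile = np.array([consumption_model.consumption_per_length(v) for v in p])
    profiles = {
        "C": CompartmentOxygenProfile(
            kind="C", s=s, p_b=p,
            saturation=hill_saturation(p, params.p50, params.n_hill),
            consumption_per_length=q_len_profile,
            clamped_from=clamped_from,
        )
    }
    p_out = float(p[-1])
    for comp in (chain.small_venule, chain.large_venule):
        sv_s = np.linspace(0.0, comp.length_cm, 51)
        const = np.full_like(sv_s, p_out)
        profiles[comp.kind] = CompartmentOxygenProfile(
            kind=comp.kind, s=sv_s, p_b=const,
            saturation=hill_saturation(const, params.p50, params.n_hill),
            consumption_per_length=np.zeros_like(sv_s),
            clamped_from=None,
        )
    return profiles


def capillary_inflow_po2(
    terminal_flows: list[float],
    terminal_hematocrits: list[float],
    terminal_po2: list[float],
    params: OxygenParams,
) -> float:
    """Blood po2 entering a capillary compartment fed by several arterioles.

    The inflow oxygen content is the flow-weighted mean of the contributing
    terminal-arteriole contents (hematocrit-weighted hemoglobin-bound oxygen
    plus dissolved oxygen); the po2 is recovered by numerically inverting the
    content relation at the flow-weighted hematocrit.
    """
    q = np.asarray(terminal_flows, dtype=float)
    if q.sum() <= 0:
        raise ValueError("total inflow must be positive")
    hd = np.asarray(terminal_hematocrits, dtype=float)
    po2 = np.asarray(terminal_po2, dtype=float)
    content = float(np.sum([convective_flux(qi, hi, pi, params)
                            for qi, hi, pi in zip(q, hd, po2)]) / q.sum())
    hd_mix = float(np.sum(q * hd) / q.sum())
    return invert_content(content, hd_mix, params)


def oxygen_flux_balance_error(profile: CompartmentOxygenProfile, chain: CompartmentChain,
                              params: OxygenParams,
                              include_dissolved: bool = True) -> float:
    """Relative error of (inflow f - outflow f) vs integrated consumption."""
    cap = chain.capillary
    q = cap.q_per_segment
    hd = chain.hematocrit
    f_in = q * oxygen_content(hd, profile.p_b[0], params, include_dissolved)
    f_out = q * oxygen_content(hd, profile.p_b[-1], params, include_dissolved)
    consumed = float(np.trapezoid(profile.consumption_per_length, profile.s))
    extracted = f_in - f_out
    scale = max(abs(extracted), abs(consumed), 1e-30)
    return abs(extracted - consumed) / scale
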