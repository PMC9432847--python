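"""Network hemodynamics: Poiseuille flow, Fahraeus-Lindqvist viscosity and
phase separation of red cells at bifurcations.

Blood flow in each segment obeys Poiseuille's law

    Q = pi * dP * D^4 / (128 * mu * L)

with the apparent viscosity ``mu`` given by the empirical in-vivo
diameter/hematocrit relationship of Pries et al. and the discharge
hematocrit distributed over the tree by the empirical red-cell
phase-separation law.  The whole-network solve alternates a linear nodal
pressure solve with hematocrit propagation and viscosity updates until the
flows are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VascularNetwork, validate_network
from .units import CP_TO_POISE, UM_TO_CM, mmhg_to_cgs


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

def poiseuille_flow(dp_mmhg: float, diameter_um: float, length_cm: float,
                    viscosity_cp: float) -> float:
    """Volumetric flow (cm^3/s) through a cylindrical vessel.

    ``dp_mmhg`` may be negative; the sign of the flow follows the sign of the
    pressure drop.
    """
    if diameter_um <= 0 or length_cm <= 0 or viscosity_cp <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    dp = mmhg_to_cgs(dp_mmhg)
    d = diameter_um * UM_TO_CM
    mu = viscosity_cp * CP_TO_POISE
    return np.pi * dp * d**4 / (128.0 * mu * length_cm)


def conductance(diameter_um: float, length_cm: float, viscosity_cp: float) -> float:
    """Poiseuille conductance Q/dP in cm^3/s per dyn/cm^2."""
    d = diameter_um * UM_TO_CM
    mu = viscosity_cp * CP_TO_POISE
    return np.pi * d**4 / (128.0 * mu * length_cm)


def viscosity_in_vivo(diameter_um, hematocrit, plasma_viscosity_cp: float = 1.0):
    """Apparent in-vivo blood viscosity (cP) after Pries et al.

    Implements the in-vivo parametrization of the Fahraeus-Lindqvist effect:
    relative apparent viscosity as a function of luminal diameter (um) and
    discharge hematocrit, multiplied by the plasma viscosity.  Accepts scalars
    or arrays.
    """
    d = np.asarray(diameter_um, dtype=float)
    h = np.asarray(hematocrit, dtype=float)
    if np.any(d <= 1.1):
        raise ValueError("diameter must exceed 1.1 um for the in-vivo law")
    if np.any(h < 0.0) or np.any(h >= 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")

    mu45 = 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    frac = 1.0 / (1.0 + 1.0e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + frac) + frac
    dterm = (d / (d - 1.1)) ** 2
    eta_rel = (1.0 + (mu45 - 1.0) * ((1.0 - h) ** c - 1.0)
               / ((1.0 - 0.45) ** c - 1.0) * dterm) * dterm
    out = eta_rel * plasma_viscosity_cp
    return float(out) if out.ndim == 0 else out


def wall_shear(flow: float, diameter_um: float, viscosity_cp: float) -> tuple[float, float]:
    """Wall shear stress tau (dyn/cm^2) and shear rate omega = tau/mu (1/s).

    tau = 32 mu Q / (pi D^3), the Poiseuille wall value (equivalently
    dP * D / (4 L)).
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d = diameter_um * UM_TO_CM
    mu = viscosity_cp * CP_TO_POISE
    tau = 32.0 * mu * flow / (np.pi * d**3)
    omega = tau / mu
    return tau, omega


# ---------------------------------------------------------------------------
# Phase separation (red-cell partitioning at a diverging bifurcation)
# ---------------------------------------------------------------------------

def _logit(x):
    return np.log(x / (1.0 - x))


def phase_separation(
    hd_parent: float,
    q_parent: float,
    q_d1: float,
    q_d2: float,
    d_parent_um: float,
    d_d1_um: float,
    d_d2_um: float,
) -> tuple[float, float]:
    """Daughter discharge hematocrits at a diverging bifurcation.

    Uses the empirical logit law of Pries et al. for the fractional red-cell
    flux as a function of the fractional blood flow, with low-flow cutoffs.
    Red-cell flux is conserved exactly:
    ``q_parent*hd_parent = q_d1*hd1 + q_d2*hd2``; if the raw law would push a
    daughter hematocrit above 1 it is clamped there and the excess red-cell
    flux is rebalanced to the other daughter.
    """
    if q_parent <= 0:
        raise ValueError("parent flow must be positive for a diverging split")
    if abs(q_d1 + q_d2 - q_parent) > 1e-9 * q_parent:
        raise ValueError("daughter flows must sum to the parent flow")
    if hd_parent == 0.0:
        return 0.0, 0.0
    if q_d1 == 0.0:
        return 0.0, hd_parent * q_parent / q_d2
    if q_d2 == 0.0:
        return hd_parent * q_parent / q_d1, 0.0

    fqb = q_d1 / q_parent
    x0 = 0.964 * (1.0 - hd_parent) / d_parent_um
    if fqb <= x0:
        fqe = 0.0
    elif fqb >= 1.0 - x0:
        fqe = 1.0
    else:
        a = (-13.29 * ((d_d1_um**2 - d_d2_um**2) / (d_d1_um**2 + d_d2_um**2))
             * (1.0 - hd_parent) / d_parent_um)
        b = 1.0 + 6.98 * (1.0 - hd_parent) / d_parent_um
        logit_fqe = a + b * _logit((fqb - x0) / (1.0 - 2.0 * x0))
        fqe = 1.0 / (1.0 + np.exp(-logit_fqe))

    rbc_flux = q_parent * hd_parent
    hd1 = fqe * rbc_flux / q_d1
    hd2 = (1.0 - fqe) * rbc_flux / q_d2
    # physical ceiling with flux rebalance
    if hd1 > 1.0:
        excess = (hd1 - 1.0) * q_d1
        hd1 = 1.0
        hd2 = min(1.0, hd2 + excess / q_d2)
    elif hd2 > 1.0:
        excess = (hd2 - 1.0) * q_d2
        hd2 = 1.0
        hd1 = min(1.0, hd1 + excess / q_d1)
    return float(hd1), float(hd2)


# ---------------------------------------------------------------------------
# Whole-network solve
# ---------------------------------------------------------------------------

@dataclass
class FlowSolution:
    node_pressures: dict[str, float]          # mmHg
    flows: dict[str, float]                   # cm^3/s per segment
    hematocrit: dict[str, float]
    viscosity_cp: dict[str, float]
    pressure_drop: dict[str, float]           # mmHg per segment
    wall_shear_stress: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    iterations: int = 0


def _propagate_hematocrit(net: VascularNetwork, flows: dict[str, float],
                          hd_in: float) -> dict[str, float]:
    """Single downstream pass of discharge hematocrit over a tree.

    Bifurcations use the empirical phase-separation law; the inlet node and
    any higher-order branchings (e.g. four main branches leaving the inlet)
    distribute the upstream hematocrit uniformly, which conserves red-cell
    flux exactly for equal hematocrits.
    """
    hd: dict[str, float] = {}
    inlet = net.inlet_node()
    for seg in net.topological_segments():
        if seg.from_node == inlet:
            hd[seg.id] = hd_in
    # process junction nodes in topological order
    import networkx as nx

    g = net.to_networkx()
    for node in nx.topological_sort(g):
        if node == inlet:
            continue
        ins = net.in_segments(node)
        outs = net.out_segments(node)
        if not outs:
            continue
        parent = ins[0]
        hp = hd[parent.id]
        qp = flows[parent.id]
        if len(outs) == 1:
            hd[outs[0].id] = hp
        elif len(outs) == 2 and qp > 0:
            h1, h2 = phase_separation(
                hp, qp, flows[outs[0].id], flows[outs[1].id],
                parent.diameter_um, outs[0].diameter_um, outs[1].diameter_um,
            )
            hd[outs[0].id] = h1
            hd[outs[1].id] = h2
        else:
            for o in outs:
                hd[o.id] = hp
    return hd


def solve_network_flow(
    net: VascularNetwork,
    inlet_pressure: float | None = None,
    terminal_pressure: float | None = None,
    hd_in: float = 0.40,
    plasma_viscosity_cp: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    relax: float = 0.5,
    uniform_viscosity_cp: float | None = None,
) -> FlowSolution:
    """Solve pressures, flows, hematocrit and viscosity on an arteriolar tree.

    Boundary conditions: the inlet node is held at ``inlet_pressure`` and
    every terminal node at ``terminal_pressure`` (mmHg).  The outer loop
    alternates (i) a sparse linear solve of nodal conservation of mass with
    fixed conductances, (ii) a downstream hematocrit pass with phase
    separation, and (iii) a Pries viscosity update (under-relaxed), until the
    largest relative flow change falls below ``tol``.

    ``uniform_viscosity_cp`` short-circuits the rheology (single linear
    solve), which is useful for verification against dense linear algebra.
    """
    p_in = net.inlet_pressure if inlet_pressure is None else inlet_pressure
    p_out = net.terminal_pressure if terminal_pressure is None else terminal_pressure
    problems = validate_network(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(problems))

    node_ids = list(net.nodes)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    inlet = net.inlet_node()
    fixed = {inlet: mmhg_to_cgs(p_in)}
    for t in net.terminal_nodes():
        fixed[t] = mmhg_to_cgs(p_out)
    free = [nid for nid in node_ids if nid not in fixed]
    fidx = {nid: i for i, nid in enumerate(free)}

    seg_ids = list(net.segments)
    mu = {
        sid: (uniform_viscosity_cp if uniform_viscosity_cp is not None
              else viscosity_in_vivo(net.segments[sid].diameter_um, hd_in,
                                     plasma_viscosity_cp))
        for sid in seg_ids
    }
    hd = {sid: hd_in for sid in seg_ids}
    flows = {sid: 0.0 for sid in seg_ids}
    pressures_cgs: dict[str, float] = {}
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        g = {sid: conductance(net.segments[sid].diameter_um,
                              net.segments[sid].length_cm, mu[sid])
             for sid in seg_ids}
        # assemble nodal system on free nodes
        n_free = len(free)
        rows, cols, vals = [], [], []
        rhs = np.zeros(n_free)
        for sid in seg_ids:
            s = net.segments[sid]
            gi = g[sid]
            for a, b in ((s.from_node, s.to_node), (s.to_node, s.from_node)):
                if a in fidx:
                    ia = fidx[a]
                    rows.append(ia); cols.append(ia); vals.append(gi)
                    if b in fidx:
                        rows.append(ia); cols.append(fidx[b]); vals.append(-gi)
                    else:
                        rhs[ia] += gi * fixed[b]
        if n_free:
            mat = sp.csr_matrix((vals, (rows, cols)), shape=(n_free, n_free))
            try:
                sol = spla.spsolve(mat, rhs)
            except Exception as exc:
                raise RuntimeError(f"singular pressure system: {exc}") from exc
            if np.any(~np.isfinite(sol)):
                raise RuntimeError("singular pressure system (non-finite solution)")
        else:
            sol = np.zeros(0)
        pressures_cgs = dict(fixed)
        for nid in free:
            pressures_cgs[nid] = float(sol[fidx[nid]])

        new_flows = {}
        for sid in seg_ids:
            s = net.segments[sid]
            new_flows[sid] = g[sid] * (pressures_cgs[s.from_node] - pressures_cgs[s.to_node])

        denom = max(abs(q) for q in new_flows.values()) or 1.0
        delta = max(abs(new_flows[sid] - flows[sid]) for sid in seg_ids) / denom
        flows = new_flows

        if uniform_viscosity_cp is not None:
            converged = True
            break
        if delta < tol and it > 1:
            converged = True
            break

        hd = _propagate_hematocrit(net, flows, hd_in)
        for sid in seg_ids:
            mu_new = viscosity_in_vivo(net.segments[sid].diameter_um, hd[sid],
                                       plasma_viscosity_cp)
            mu[sid] = (1.0 - relax) * mu[sid] + relax * mu_new

    if uniform_viscosity_cp is None:
        # one last pass so the reported hematocrits split the final flows
        hd = _propagate_hematocrit(net, flows, hd_in)

    drops = {}
    shear = {}
    for sid in seg_ids:
        s = net.segments[sid]
        dp = (pressures_cgs[s.from_node] - pressures_cgs[s.to_node]) / 1333.22
        drops[sid] = dp
        tau, _ = wall_shear(flows[sid], s.diameter_um, mu[sid])
        shear[sid] = tau
        # write state back onto the segments for downstream stages
        s.flow = flows[sid]
        s.pressure_drop = dp
        s.hematocrit = hd[sid]
        s.viscosity_cp = mu[sid]
        s.wall_shear = tau

    return FlowSolution(
        node_pressures={nid: p / 1333.22 for nid, p in pressures_cgs.items()},
        flows=flows,
        hematocrit=dict(hd),
        viscosity_cp=dict(mu),
        pressure_drop=drops,
        wall_shear_stress=shear,
        converged=converged,
        iterations=it,
    )
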