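"""Green's-function solver for coupled intravascular / tissue oxygen transport.

The steady diffusion-consumption equation in tissue,

    D_diff * alpha * laplacian(P) = M(P),

is solved by superposition of free-space kernels G(x, x') = 1/(4 pi K |x-x'|)
(K = D_diff*alpha): vessel elements act as distributed oxygen sources whose
strengths are unknowns, and tissue sample points act as Michaelis-Menten
sinks linearized about the current tissue po2 (Picard iteration).  Because
the free-space kernel is defined up to an additive constant for a closed
(source = sink) system, the potential carries an unknown constant and the
solve is closed by requiring total vessel efflux to equal total tissue
consumption.  Intravascular transport follows the convective balance
df/ds = -q(s) along each vessel, with blood po2 recovered by inverting the
oxygen-content relation; blood and tissue couple through the condition that
the superposed field at each element wall equals the local blood po2
(intravascular resistance neglected).

Vessel elements use the analytic potential of a uniform finite line source,
with the self-interaction evaluated at the element's own wall radius; tissue
points are volume-equivalent spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .hemodynamics import FlowSolution
from .network import VascularNetwork
from .oxygen import (
    OxygenParams,
    hill_saturation,
    hill_saturation_slope,
    invert_content_vec,
    michaelis_menten,
    oxygen_content,
)


# ---------------------------------------------------------------------------
# Tissue sampling
# ---------------------------------------------------------------------------

@dataclass
class TissueDomain:
    """Regular tissue sampling of a slab around the vessel network.

    ``spacing`` is the in-plane grid step (cm), ``margin`` the lateral margin
    beyond the vessel bounding box, ``thickness`` the slab depth centered on
    ``z_center``.  The retinal arterioles are treated as lying in a thin
    superficial layer, so a thin slab is the natural sampled domain.
    """

    spacing: float = 0.004     # cm (40 um)
    margin: float = 0.02       # cm
    thickness: float = 0.02    # cm
    z_center: float = 0.0


def tissue_sample_points(net: VascularNetwork, domain: TissueDomain
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Grid sample points (n, 3) and per-point volumes (n,) for a network slab."""
    pos = np.array([n.position for n in net.nodes.values()])
    lo = pos[:, :2].min(axis=0) - domain.margin
    hi = pos[:, :2].max(axis=0) + domain.margin
    xs = np.arange(lo[0] + 0.5 * domain.spacing, hi[0], domain.spacing)
    ys = np.arange(lo[1] + 0.5 * domain.spacing, hi[1], domain.spacing)
    nz = max(1, int(round(domain.thickness / domain.spacing)))
    dz = domain.thickness / nz
    zs = domain.z_center - 0.5 * domain.thickness + (np.arange(nz) + 0.5) * dz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vols = np.full(len(pts), domain.spacing**2 * dz)
    return pts, vols


# ---------------------------------------------------------------------------
# Vessel discretization
# ---------------------------------------------------------------------------

@dataclass
class _Elements:
    seg_id: list[str]
    center: np.ndarray        # (n, 3)
    axis: np.ndarray          # (n, 3) unit vectors
    half_len: np.ndarray      # (n,)
    radius: np.ndarray        # (n,)
    s_mid: np.ndarray         # (n,) axial midpoint position within segment, cm
    seg_slices: dict[str, slice] = field(default_factory=dict)


def _discretize(net: VascularNetwork, max_len_cm: float) -> _Elements:
    seg_id, centers, axes, hlens, radii, smids = [], [], [], [], [], []
    slices: dict[str, slice] = {}
    pos = {n.id: n.position for n in net.nodes.values()}
    start = 0
    for seg in net.topological_segments():
        a, b = pos[seg.from_node], pos[seg.to_node]
        u = (b - a) / np.linalg.norm(b - a)
        n_el = max(1, int(np.ceil(seg.length_cm / max_len_cm)))
        le = seg.length_cm / n_el
        for j in range(n_el):
            s0 = j * le
            centers.append(a + (s0 + 0.5 * le) * u)
            axes.append(u)
            hlens.append(0.5 * le)
            radii.append(seg.radius_cm)
            smids.append(s0 + 0.5 * le)
            seg_id.append(seg.id)
        slices[seg.id] = slice(start, start + n_el)
        start += n_el
    return _Elements(
        seg_id=seg_id,
        center=np.array(centers),
        axis=np.array(axes),
        half_len=np.array(hlens),
        radius=np.array(radii),
        s_mid=np.array(smids),
        seg_slices=slices,
    )


def _line_potential_coeffs(targets: np.ndarray, elems: _Elements, kappa: float,
                           rho_floor: np.ndarray | None = None) -> np.ndarray:
    """Potential at ``targets`` per unit total strength of each line element.

    Uses the exact potential of a uniform finite line source:
    phi = q / (4 pi K * 2h) * [asinh((h - t)/rho) + asinh((h + t)/rho)],
    with the radial offset floored at the source radius (evaluation points
    inside a vessel see its wall value).
    """
    d = targets[:, None, :] - elems.center[None, :, :]      # (m, n, 3)
    t = np.einsum("mnk,nk->mn", d, elems.axis)
    rho2 = np.maximum(np.einsum("mnk,mnk->mn", d, d) - t**2, 0.0)
    rho = np.sqrt(rho2)
    floor = elems.radius[None, :] if rho_floor is None else rho_floor
    rho = np.maximum(rho, floor)
    h = elems.half_len[None, :]
    integral = np.arcsinh((h - t) / rho) + np.arcsinh((h + t) / rho)
    return integral / (4.0 * np.pi * kappa * 2.0 * h)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class TissueField:
    points: np.ndarray          # (n, 3) cm
    volumes: np.ndarray         # (n,) cm^3
    po2: np.ndarray             # (n,) mmHg, clamped >= 0
    sink_strengths: np.ndarray  # (n,) cm^3 O2/s consumed


@dataclass
class VesselOxygenProfile:
    seg_id: str
    s_mid: np.ndarray           # axial midpoint positions, cm
    p_b: np.ndarray             # blood po2 at midpoints, mmHg
    q_per_len: np.ndarray       # diffusive efflux per length, cm^3 O2/cm/s
    saturation: np.ndarray
    inflow_flux: float          # f at the upstream end, cm^3 O2/s
    outflow_flux: float         # f at the downstream end, cm^3 O2/s


@dataclass
class GreensSolution:
    tissue: TissueField
    profiles: dict[str, VesselOxygenProfile]
    terminal_po2: dict[str, float]       # blood po2 leaving each terminal segment
    converged: bool
    iterations: int
    residual: float                      # final max |delta po2|, mmHg
    inflow_flux: float                   # total oxygen delivery, cm^3 O2/s
    terminal_outflux: float              # oxygen convected into capillaries
    tissue_consumption: float            # total tissue sink, cm^3 O2/s

    def mass_balance_error(self) -> float:
        """Closure error of (delivery - outflux) vs tissue sink, relative to
        the total oxygen delivery at the inlet."""
        extracted = self.inflow_flux - self.terminal_outflux
        return abs(extracted - self.tissue_consumption) / max(self.inflow_flux, 1e-30)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class GreensSolver:
    """Assembles the geometric kernels once, then iterates to convergence."""

    def __init__(
        self,
        net: VascularNetwork,
        flow: FlowSolution,
        params: OxygenParams,
        tissue_points: np.ndarray,
        tissue_volumes: np.ndarray,
        max_element_len_cm: float = 25e-4,
    ) -> None:
        params.validate()
        self.net = net
        self.flow = flow
        self.params = params
        self.kappa = params.d_diff_alpha
        self.elems = _discretize(net, max_element_len_cm)
        self.t_pts = np.asarray(tissue_points, dtype=float)
        self.t_vol = np.asarray(tissue_volumes, dtype=float)
        if len(self.t_pts) > 8000:
            raise ValueError(
                f"{len(self.t_pts)} tissue sample points: the dense kernel "
                "matrices would be impractically large; coarsen the tissue "
                "spacing or shrink the margins for a network of this extent"
            )
        self._assemble()

    def _assemble(self) -> None:
        e, k = self.elems, self.kappa
        n_e = len(e.center)
        # vessel-vessel wall potentials (self term handled by the rho floor:
        # the diagonal evaluates the element's own line at its wall radius)
        self.a_ww = _line_potential_coeffs(e.center, e, k)

        sphere_r = (3.0 * self.t_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        self.sphere_r = sphere_r
        # tissue sink -> vessel wall
        r_vw = np.maximum(cdist(e.center, self.t_pts), sphere_r[None, :])
        self.b_vw = 1.0 / (4.0 * np.pi * k * r_vw)
        # vessel element -> tissue point
        self.b_tv = _line_potential_coeffs(self.t_pts, e, k)
        # tissue -> tissue, with the volume-averaged self potential of a
        # uniform sphere (1.2/a) on the diagonal
        r_tt = np.maximum(cdist(self.t_pts, self.t_pts), sphere_r[None, :])
        c_tt = 1.0 / (4.0 * np.pi * k * r_tt)
        np.fill_diagonal(c_tt, 1.2 / (4.0 * np.pi * k * sphere_r))
        self.c_tt = c_tt

        # per-element blood flow and hematocrit, and the upstream-influence
        # matrix W: W[i, j] is the sensitivity of the convective flux at the
        # midpoint of element i to the efflux of element j (1 within a
        # segment, scaled by the daughter flow fraction across junctions,
        # 1/2 for the element's own efflux).
        net, flow = self.net, self.flow
        self.e_flow = np.array([max(flow.flows[s], 0.0) for s in e.seg_id])
        self.e_hd = np.array([flow.hematocrit[s] for s in e.seg_id])
        w = np.zeros((n_e, n_e))
        entry: dict[str, np.ndarray] = {net.inlet_node(): np.zeros(n_e)}
        for seg in net.topological_segments():
            sl = e.seg_slices[seg.id]
            v = entry[seg.from_node]
            # flow fraction of this segment at its origin junction
            q_here = max(flow.flows[seg.id], 0.0)
            sibs = sum(max(flow.flows[s.id], 0.0) for s in net.out_segments(seg.from_node))
            frac = q_here / sibs if sibs > 0 else 0.0
            v_seg = v * frac
            idx = np.arange(sl.start, sl.stop)
            for m, i in enumerate(idx):
                w[i] = v_seg
                w[i, idx[:m]] = 1.0
                w[i, i] = 0.5
            v_end = v_seg.copy()
            v_end[idx] = 1.0
            entry[seg.to_node] = v_end
        self.w_conv = w

    def _tissue_solve(self, dphi: np.ndarray, rhs: np.ndarray,
                      x0: np.ndarray) -> np.ndarray:
        """Solve (I + C_tt diag(dphi)) x = rhs (Krylov; dense matvec only)."""
        import scipy.sparse.linalg as spla

        n_t = len(rhs)
        if n_t == 0:
            return rhs
        if n_t <= 800:
            mat = self.c_tt * dphi[None, :]
            mat[np.diag_indices(n_t)] += 1.0
            return np.linalg.solve(mat, rhs)

        def mv(x):
            return x + self.c_tt @ (dphi * x)

        op = spla.LinearOperator((n_t, n_t), matvec=mv)
        x, info = spla.gmres(op, rhs, x0=x0, rtol=1e-10, atol=0.0,
                             restart=80, maxiter=40)
        if info != 0:  # pragma: no cover - fall back to the dense solve
            mat = self.c_tt * dphi[None, :]
            mat[np.diag_indices(n_t)] += 1.0
            x = np.linalg.solve(mat, rhs)
        return x

    # -- intravascular marching --------------------------------------------
    def _march(self, q: np.ndarray):
        """Propagate convective oxygen flux through the tree for given element
        effluxes; returns blood po2 at element midpoints plus flux bookkeeping."""
        net, e, p = self.net, self.elems, self.params
        node_po2 = {net.inlet_node(): p.inflow_po2}
        p_mid = np.zeros(len(e.center))
        inflow_total = 0.0
        terminal_out = 0.0
        terminal_po2: dict[str, float] = {}
        seg_flux: dict[str, tuple[float, float]] = {}
        inlet = net.inlet_node()
        for seg in net.topological_segments():  # parents before children
            sl = e.seg_slices[seg.id]
            q_seg = max(self.flow.flows[seg.id], 0.0)
            hd = self.flow.hematocrit[seg.id]
            p_in = node_po2[seg.from_node]
            f_in = q_seg * oxygen_content(hd, p_in, p)
            if seg.from_node == inlet:
                inflow_total += f_in
            qe = q[sl]
            cum = np.cumsum(qe)
            f_mid = np.maximum(f_in - (cum - 0.5 * qe), 0.0)
            f_end = max(f_in - cum[-1], 0.0) if len(qe) else f_in
            if q_seg > 0:
                p_mid[sl] = invert_content_vec(f_mid / q_seg, hd, p)
                p_end = float(invert_content_vec(np.array([f_end / q_seg]), hd, p)[0])
            else:
                p_mid[sl] = p_in
                p_end = p_in
            node_po2[seg.to_node] = p_end
            seg_flux[seg.id] = (f_in, f_end)
            if net.nodes[seg.to_node].kind == "terminal":
                terminal_out += f_end
                terminal_po2[seg.id] = p_end
        return p_mid, inflow_total, terminal_out, terminal_po2, seg_flux

    # -- semi-implicit fixed-point solve ------------------------------------
    def solve(self, tol: float = 1e-3, max_iter: int = 200,
              relax: float = 1.0) -> GreensSolution:
        """Iterate to self-consistency of q, blood po2 and tissue po2.

        Each sweep (i) marches the convective flux for the current element
        strengths, (ii) solves the wall-condition linear system for new
        strengths with the convective response linearized through the
        upstream-influence matrix (so a strength increase simultaneously
        raises the wall potential and depletes the downstream blood po2),
        and (iii) solves the tissue superposition implicitly with the
        Michaelis-Menten sink linearized about the current tissue po2.

        The sweep starts undamped; if the residual stalls (the remaining
        cross-couplings can settle into a period-2 cycle) the relaxation
        factor is halved until progress resumes.
        """
        p, e = self.params, self.elems
        n_e, n_t = len(e.center), len(self.t_pts)
        m0 = p.m0_cgs
        p_t = np.full(n_t, p.inflow_po2)
        q = np.zeros(n_e)
        residual = np.inf
        converged = False
        it = 0
        p_mid_prev = np.full(n_e, p.inflow_po2)
        res_hist: list[float] = []
        for it in range(1, max_iter + 1):
            p_mid, f_in_tot, f_term, term_po2, seg_flux = self._march(q)
            # MM sink linearization about the current tissue po2
            phi = michaelis_menten(p_t, m0, p.p0) * self.t_vol
            dphi = m0 * p.p0 / (p.p0 + p_t) ** 2 * self.t_vol

            # content slope at element midpoints -> convective Jacobian scale
            cprime = (self.e_hd * p.c0
                      * hill_saturation_slope(p_mid, p.p50, p.n_hill) + p.alpha_b)
            d_vess = np.where(self.e_flow > 0, 1.0 / (self.e_flow * cprime), 0.0)

            aug = np.zeros((n_e + 1, n_e + 1))
            aug[:n_e, :n_e] = self.a_ww + d_vess[:, None] * self.w_conv
            aug[:n_e, n_e] = 1.0      # additive constant of the potential
            aug[n_e, :n_e] = 1.0      # closure: sum(q) = sum(phi)
            rhs = np.empty(n_e + 1)
            rhs[:n_e] = p_mid + d_vess * (self.w_conv @ q) + self.b_vw @ phi
            rhs[n_e] = phi.sum()
            sol = np.linalg.solve(aug, rhs)
            q_new = sol[:n_e]
            const = sol[n_e]
            q = q + relax * (q_new - q)

            # implicit tissue update: (I + C_tt diag(dphi)) P = ...
            rhs_t = self.b_tv @ q - self.c_tt @ (phi - dphi * p_t) + const
            p_t_new = np.maximum(self._tissue_solve(dphi, rhs_t, x0=p_t), 0.0)

            residual = float(np.max(np.abs(p_t_new - p_t))) if n_t else 0.0
            res_b = float(np.max(np.abs(p_mid - p_mid_prev))) if n_e else 0.0
            p_mid_prev = p_mid
            p_t = p_t + relax * (p_t_new - p_t)
            res = max(residual, res_b)
            if res < tol and it > 1:
                converged = True
                break
            res_hist.append(res)
            if len(res_hist) >= 8 and res > 0.5 * res_hist[-8] and relax > 0.26:
                relax *= 0.5
                res_hist.clear()

        # final consistent pass
        p_mid, f_in_tot, f_term, term_po2, seg_flux = self._march(q)
        consumption = michaelis_menten(np.maximum(p_t, 0.0), m0, p.p0) * self.t_vol

        profiles: dict[str, VesselOxygenProfile] = {}
        for seg in self.net.segments.values():
            sl = e.seg_slices[seg.id]
            lens = 2.0 * e.half_len[sl]
            f_in, f_end = seg_flux[seg.id]
            profiles[seg.id] = VesselOxygenProfile(
                seg_id=seg.id,
                s_mid=e.s_mid[sl].copy(),
                p_b=p_mid[sl].copy(),
                q_per_len=q[sl] / lens,
                saturation=hill_saturation(p_mid[sl], p.p50, p.n_hill),
                inflow_flux=f_in,
                outflow_flux=f_end,
            )
            seg.blood_po2_profile = p_mid[sl].copy()

        tissue = TissueField(self.t_pts, self.t_vol, np.maximum(p_t, 0.0), consumption)
        return GreensSolution(
            tissue=tissue,
            profiles=profiles,
            terminal_po2=term_po2,
            converged=converged,
            iterations=it,
            residual=residual,
            inflow_flux=f_in_tot,
            terminal_outflux=f_term,
            tissue_consumption=float(consumption.sum()),
        )


def solve_greens(
    net: VascularNetwork,
    flow: FlowSolution,
    params: OxygenParams,
    domain: TissueDomain | None = None,
    tissue_points: np.ndarray | None = None,
    tissue_volumes: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 200,
    max_element_len_cm: float = 25e-4,
) -> GreensSolution:
    """Convenience wrapper: sample tissue (or use explicit points) and solve."""
    if tissue_points is None:
        domain = domain or TissueDomain()
        tissue_points, tissue_volumes = tissue_sample_points(net, domain)
    if tissue_volumes is None:
        raise ValueError("tissue_volumes required with explicit tissue_points")
    solver = GreensSolver(net, flow, params, tissue_points, tissue_volumes,
                          max_element_len_cm=max_element_len_cm)
    return solver.solve(tol=tol, max_iter=max_iter)
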