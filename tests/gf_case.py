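"""Shared single-vessel verification case for the oxygen transport solver.

A straight vessel of radius 18 um and length 400 um crosses a sampled tissue
annulus of outer radius 120 um.  Blood flow is large so the intravascular po2
is nearly uniform, making the configuration directly comparable with an
axisymmetric finite-difference solution of the same continuum problem
(consumption confined to the annulus, diffusion in a large surrounding
region).  The sampled annulus is rings of points within the 500-point
budget of the comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from retmicro.greens import GreensSolver
from retmicro.hemodynamics import FlowSolution
from retmicro.network import NetworkNode, VascularNetwork, VesselSegment, classify_segments
from retmicro.oxygen import OxygenParams

L = 0.04          # vessel length, cm
R_V = 18e-4       # vessel radius, cm
R_T = 0.012       # sampled annulus outer radius, cm
P_IN = 60.0       # inflow po2, mmHg
HD = 0.4
Q_BLOOD = 1e-4    # cm^3/s, large so the axial po2 drop is negligible


def single_vessel_network() -> tuple[VascularNetwork, FlowSolution]:
    net = VascularNetwork()
    net.nodes["n0"] = NetworkNode("n0", np.array([0.0, 0.0, 0.0]), "inlet")
    net.nodes["n1"] = NetworkNode("n1", np.array([0.0, 0.0, L]), "terminal")
    net.segments["s1"] = VesselSegment("s1", "n0", "n1", 2 * R_V * 1e4, L)
    classify_segments(net)
    flow = FlowSolution(
        node_pressures={"n0": 40.0, "n1": 24.0},
        flows={"s1": Q_BLOOD}, hematocrit={"s1": HD},
        viscosity_cp={"s1": 2.0}, pressure_drop={"s1": 16.0},
    )
    return net, flow


def annulus_rings(nr: int = 5, nz: int = 8, naz: int = 12):
    """Ring-of-points sampling of the annulus; returns points, volumes and
    the (radial, axial) ring index of every point."""
    redges = np.linspace(R_V, R_T, nr + 1)
    zedges = np.linspace(0.0, L, nz + 1)
    rc = 0.5 * (redges[:-1] + redges[1:])
    zc = 0.5 * (zedges[:-1] + zedges[1:])
    pts, vols, ring = [], [], []
    for i in range(nr):
        ring_vol = np.pi * (redges[i + 1] ** 2 - redges[i] ** 2) * (zedges[1] - zedges[0])
        for j in range(nz):
            for a in range(naz):
                th = 2.0 * np.pi * (a + 0.5 * ((i + j) % 2)) / naz
                pts.append([rc[i] * np.cos(th), rc[i] * np.sin(th), zc[j]])
                vols.append(ring_vol / naz)
                ring.append((i, j))
    return np.array(pts), np.array(vols), ring, rc, zc


def greens_ring_po2(m0: float, nr: int = 5, nz: int = 8, naz: int = 12):
    """Solve the Green's function case; returns ring-averaged po2[r, z]."""
    net, flow = single_vessel_network()
    params = OxygenParams(m0=m0, inflow_po2=P_IN)
    pts, vols, ring, rc, zc = annulus_rings(nr, nz, naz)
    solver = GreensSolver(net, flow, params, pts, vols, max_element_len_cm=25e-4)
    sol = solver.solve(tol=1e-4, max_iter=300)
    po2 = np.zeros((nr, nz))
    cnt = np.zeros((nr, nz))
    for (i, j), p in zip(ring, sol.tissue.po2):
        po2[i, j] += p
        cnt[i, j] += 1
    return rc, zc, po2 / cnt, sol


def fd_reference_po2(m0: float, rc, zc):
    """Finite-difference oracle evaluated at the ring centers."""
    from oracles import fd_oxygen_oracle

    params = OxygenParams(m0=m0)
    r, z, po2 = fd_oxygen_oracle(
        r_v=R_V, r_tissue=R_T, length=L, p_wall=P_IN,
        m0_cgs=params.m0_cgs, p0=params.p0, kappa=params.d_diff_alpha,
    )
    interp = RegularGridInterpolator((r, z), po2)
    q = np.array([[ri, zj] for ri in rc for zj in zc])
    return interp(q).reshape(len(rc), len(zc))
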