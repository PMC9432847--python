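"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solver code paths: the flow oracle is
a dense nodal linear solve assembled by hand, and the oxygen oracle is an
axisymmetric finite-difference discretization of the diffusion-consumption
equation.  They are slower and simpler than the implementations under test.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def dense_flow_oracle(nodes, segments, p_fixed, conductances):
    """Nodal pressures and segment flows by dense linear algebra.

    ``nodes``: list of node ids; ``segments``: list of (seg_id, from, to);
    ``p_fixed``: dict node -> pressure (any units); ``conductances``: dict
    seg_id -> g with Q = g * (P_from - P_to).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for sid, u, v in segments:
        g = conductances[sid]
        a[idx[u], idx[u]] += g
        a[idx[u], idx[v]] -= g
        a[idx[v], idx[v]] += g
        a[idx[v], idx[u]] -= g
    for node, p in p_fixed.items():
        i = idx[node]
        a[i, :] = 0.0
        a[i, i] = 1.0
        b[i] = p
    p_sol = np.linalg.solve(a, b)
    pressures = {node: p_sol[idx[node]] for node in nodes}
    flows = {sid: conductances[sid] * (pressures[u] - pressures[v])
             for sid, u, v in segments}
    return pressures, flows


def fd_oxygen_oracle(
    r_v: float,
    r_tissue: float,
    length: float,
    p_wall: float,
    m0_cgs: float,
    p0: float,
    kappa: float,
    nr: int = 90,
    nz: int = 140,
    r_outer_factor: float = 4.0,
    z_pad_factor: float = 1.5,
    tol: float = 1e-5,
    max_picard: int = 300,
):
    """Axisymmetric finite-difference solution around a single vessel.

    The vessel (radius ``r_v``, axial extent [0, length]) holds a fixed wall
    po2; Michaelis-Menten consumption acts only inside the tissue annulus
    r <= r_tissue, 0 <= z <= length, while diffusion extends over a much
    larger surrounding region (out to ``r_outer_factor * r_tissue`` radially
    and ``z_pad_factor * length`` beyond each end) so that the remote
    boundary is effectively free space.  Returns (r, z, po2[r, z]).
    """
    r_big = r_outer_factor * r_tissue
    z_pad = z_pad_factor * length
    r = np.linspace(r_v, r_big, nr)
    z = np.linspace(-z_pad, length + z_pad, nz)
    dr, dz = r[1] - r[0], z[1] - z[0]
    n_tot = nr * nz

    def idx(i, j):
        return i * nz + j

    in_vessel = (z >= 0) & (z <= length)
    in_tissue = (r[:, None] <= r_tissue) & (z[None, :] >= 0) & (z[None, :] <= length)

    p = np.full(n_tot, 0.5 * p_wall)
    for _ in range(max_picard):
        rows, cols, vals = [], [], []
        rhs = np.zeros(n_tot)
        mcoef = m0_cgs / (p0 + np.maximum(p, 0.0))
        for i in range(nr):
            for j in range(nz):
                n = idx(i, j)
                if i == 0 and in_vessel[j]:
                    rows.append(n); cols.append(n); vals.append(1.0)
                    rhs[n] = p_wall
                    continue
                diag = 0.0
                if i < nr - 1:
                    c = kappa * 0.5 * (r[i] + r[i + 1]) / (r[i] * dr * dr)
                    rows.append(n); cols.append(idx(i + 1, j)); vals.append(c)
                    diag -= c
                if i > 0:
                    c = kappa * 0.5 * (r[i] + r[i - 1]) / (r[i] * dr * dr)
                    rows.append(n); cols.append(idx(i - 1, j)); vals.append(c)
                    diag -= c
                for jj in (j - 1, j + 1):
                    if 0 <= jj < nz:
                        c = kappa / (dz * dz)
                        rows.append(n); cols.append(idx(i, jj)); vals.append(c)
                        diag -= c
                if in_tissue[i, j]:
                    diag -= mcoef[n]
                rows.append(n); cols.append(n); vals.append(diag)
        mat = sp.csr_matrix((vals, (rows, cols)), shape=(n_tot, n_tot))
        p_new = spla.spsolve(mat, rhs)
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    return r, z, p.reshape(nr, nz)


def pries_bifurcation_oracle(hd_parent, fqb, d_parent, d1, d2):
    """Straightforward transcription of the empirical red-cell split law.

    Returns the fractional erythrocyte flux into daughter 1 given the
    fractional blood flow ``fqb``; written independently of the package's
    vectorized/rebalanced implementation.
    """
    x0 = 0.964 * (1.0 - hd_parent) / d_parent
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    a = -13.29 * ((d1 / d2) ** 2 - 1.0) / ((d1 / d2) ** 2 + 1.0) * (1.0 - hd_parent) / d_parent
    b = 1.0 + 6.98 * (1.0 - hd_parent) / d_parent
    xi = (fqb - x0) / (1.0 - 2.0 * x0)
    logit = a + b * np.log(xi / (1.0 - xi))
    return 1.0 / (1.0 + np.exp(-logit))


def trapezoid_conduction_oracle(s_loc_samples, x, s_out, length, l0, n_dense=100_000):
    """Dense-trapezoid evaluation of the conducted-signal integrals."""
    xf = np.linspace(0.0, length, n_dense + 1)
    slf = np.interp(xf, x, s_loc_samples)
    growth = np.exp(xf / l0)
    inner = np.concatenate(
        [[0.0], np.cumsum(0.5 * (slf[1:] * growth[1:] + slf[:-1] * growth[:-1])
                          * np.diff(xf))]
    )
    s = s_out * np.exp(-xf / l0) + np.exp(-xf / l0) * inner
    s_meta = np.trapezoid(s, xf) / length
    return s_meta, s[-1]
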