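"""Scalar oxygen relations shared by the transport solvers.

* Michaelis-Menten tissue consumption  M(P) = M0 * P / (P0 + P)
* Hill oxyhemoglobin saturation        S(P) = P^n / (P^n + P50^n)
* Convective oxygen flux               f(P) = Q * (H_D * C0 * S(P) + alpha_b * P)

plus robust numerical inverses of S and f used when marching oxygen along
vessels and when mixing arteriolar outflows into a capillary compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass
class OxygenParams:
    """Global oxygen-transport parameters (CGS units unless noted).

    ``d_diff_alpha`` is the product of tissue oxygen diffusivity and
    solubility, ``m0`` the maximal (demand) consumption rate in the
    conventional cm^3 O2/100 cm^3/min, ``p0`` the Michaelis constant (mmHg),
    ``p50``/``n_hill`` the oxyhemoglobin dissociation parameters, ``c0`` the
    oxygen-binding capacity of fully saturated red cells (cm^3 O2/cm^3 RBC)
    and ``alpha_b`` the effective solubility of oxygen in blood
    (cm^3 O2/cm^3/mmHg).
    """

    d_diff_alpha: float = 6.0e-10     # cm^3 O2 / cm / s / mmHg
    m0: float = 1.0                   # cm^3 O2 / 100 cm^3 / min
    p0: float = 10.0                  # mmHg
    p50: float = 26.0                 # mmHg
    n_hill: float = 2.7
    c0: float = 0.5                   # cm^3 O2 / cm^3
    alpha_b: float = 3.1e-5           # cm^3 O2 / cm^3 / mmHg
    inflow_po2: float = 84.4          # mmHg

    @property
    def m0_cgs(self) -> float:
        return self.m0 * 1.0e-2 / 60.0

    def validate(self) -> None:
        for name in ("d_diff_alpha", "m0", "p0", "p50", "c0", "alpha_b", "inflow_po2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_hill <= 1.0:
            raise ValueError("Hill exponent must exceed 1")


def michaelis_menten(po2, m0, p0=10.0):
    """Tissue consumption rate at partial pressure ``po2`` (same units as m0)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    out = m0 * po2 / (p0 + po2)
    return float(out) if out.ndim == 0 else out


def hill_saturation(p_b, p50=26.0, n=2.7):
    """Oxyhemoglobin saturation in [0, 1]; strictly increasing in ``p_b``."""
    p_b = np.asarray(p_b, dtype=float)
    if np.any(p_b < 0):
        raise ValueError("blood po2 must be non-negative")
    pn = p_b**n
    out = pn / (pn + p50**n)
    return float(out) if out.ndim == 0 else out


def hill_saturation_slope(p_b, p50=26.0, n=2.7):
    """dS/dP of the Hill curve."""
    p_b = np.asarray(p_b, dtype=float)
    pn = p_b**n
    denom = (pn + p50**n) ** 2
    out = np.where(p_b > 0, n * p_b ** (n - 1.0) * p50**n / denom, 0.0)
    return float(out) if out.ndim == 0 else out


def hill_inverse(s, p50=26.0, n=2.7):
    """Blood po2 at saturation ``s``; exact inverse of :func:`hill_saturation`."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("saturation must lie in [0, 1)")
    out = p50 * (s / (1.0 - s)) ** (1.0 / n)
    return float(out) if out.ndim == 0 else out


def convective_flux(q, h_d, p_b, params: OxygenParams):
    """Convective oxygen transport rate f = Q (H_D C0 S(P_b) + alpha_b P_b)."""
    if np.any(np.asarray(q) < 0):
        raise ValueError("flow must be non-negative (orient segments first)")
    s = hill_saturation(p_b, params.p50, params.n_hill)
    return q * (h_d * params.c0 * s + params.alpha_b * np.asarray(p_b, dtype=float))


def oxygen_content(h_d, p_b, params: OxygenParams, include_dissolved: bool = True):
    """Oxygen content per unit blood volume (cm^3 O2/cm^3)."""
    s = hill_saturation(p_b, params.p50, params.n_hill)
    c = h_d * params.c0 * s
    if include_dissolved:
        c = c + params.alpha_b * np.asarray(p_b, dtype=float)
    return c


def invert_content(content, h_d, params: OxygenParams,
                   include_dissolved: bool = True, p_max: float = 500.0):
    """Invert :func:`oxygen_content` for the blood po2 (scalar, brentq).

    Returns 0 for non-positive content.  Raises if the content exceeds what
    is attainable at ``p_max``.
    """
    if content <= 0.0:
        return 0.0
    top = oxygen_content(h_d, p_max, params, include_dissolved)
    if content >= top:
        raise ValueError(f"oxygen content {content:g} not attainable below {p_max} mmHg")

    def f(p):
        return oxygen_content(h_d, p, params, include_dissolved) - content

    return brentq(f, 0.0, p_max, xtol=1e-12, rtol=1e-14)


def invert_content_vec(content, h_d, params: OxygenParams,
                       include_dissolved: bool = True, p_max: float = 500.0,
                       tol: float = 1e-10, max_iter: int = 200):
    """Vectorized monotone-bisection inverse of the content relation."""
    content = np.asarray(content, dtype=float)
    h_d = np.broadcast_to(np.asarray(h_d, dtype=float), content.shape).copy()
    lo = np.zeros_like(content)
    hi = np.full_like(content, p_max)
    out = np.zeros_like(content)
    active = content > 0.0
    for _ in range(max_iter):
        if not np.any(active):
            break
        mid = 0.5 * (lo + hi)
        c_mid = oxygen_content(h_d, mid, params, include_dissolved)
        go_up = c_mid < content
        lo = np.where(active & go_up, mid, lo)
        hi = np.where(active & ~go_up, mid, hi)
        active = active & ((hi - lo) > tol)
    out = 0.5 * (lo + hi)
    out[content <= 0.0] = 0.0
    return out
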