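"""Conducted metabolic wall signals.

Low oxygen generates a local wall signal S_loc = P0/(P0 + PO2) at every
point of every vessel.  The signal is conducted upstream with exponential
decay (length constant L0), so the pointwise signal at upstream distance x
from a vessel's outflow end is

    S(x) = S_out * exp(-x/L0) + integral_0^x S_loc(y) exp(-(x-y)/L0) dy,

where S_out is the conducted signal arriving at the outflow node.  The
vessel's metabolic response S_meta is the length-average of S(x), and the
value S_up = S(L) is handed to the next vessel upstream.  Conduction starts
with zero signal at the downstream end of the large-venule compartment,
passes LV -> SV -> C -> terminal arteriole, and then runs through the
arteriolar tree in reverse-topological order.

The piecewise-linear local-signal profile admits an exact exponential
integrator, so the quadrature is exact for the sampled profile (no
step-size error beyond the sampling itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartments import CompartmentChain
from .greens import GreensSolution
from .krogh import CompartmentOxygenProfile
from .network import VascularNetwork


def local_signal(po2, p0: float = 10.0):
    """Local metabolic wall signal S_loc = P0/(P0 + PO2), in (0, 1]."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    out = p0 / (p0 + po2)
    return float(out) if out.ndim == 0 else out


def conduct_along_vessel(
    s_loc,
    s_out: float,
    length_cm: float,
    l0_cm: float = 1.0,
    x=None,
) -> tuple[float, float]:
    """Conduct the wall signal along one vessel; returns (S_meta, S_up).

    ``s_loc`` is the local signal sampled at upstream coordinates ``x``
    (measured from the outflow end; defaults to a uniform grid over
    [0, length]); a scalar means a constant profile.  The profile is treated
    as piecewise linear and both the pointwise signal and its length average
    are integrated exactly interval by interval.
    """
    if length_cm <= 0 or l0_cm <= 0:
        raise ValueError("length and L0 must be positive")
    if s_out < 0:
        raise ValueError("S_out must be non-negative")
    s_loc = np.atleast_1d(np.asarray(s_loc, dtype=float))
    if np.any(s_loc < 0):
        raise ValueError("S_loc must be non-negative")
    if s_loc.size == 1:
        s_loc = np.repeat(s_loc, 2)
        x = np.array([0.0, length_cm])
    if x is None:
        x = np.linspace(0.0, length_cm, s_loc.size)
    x = np.asarray(x, dtype=float)
    if x[0] != 0.0 or abs(x[-1] - length_cm) > 1e-12 * max(1.0, length_cm):
        raise ValueError("x must span [0, length]")

    s = s_out
    integral = 0.0
    for i in range(len(x) - 1):
        h = x[i + 1] - x[i]
        if h <= 0:
            raise ValueError("x must be strictly increasing")
        a, b = s_loc[i], s_loc[i + 1]
        c = (b - a) / h
        e = np.exp(-h / l0_cm)
        s_next = s * e + b * l0_cm * (1.0 - e) - c * l0_cm**2 * (1.0 - e * (1.0 + h / l0_cm))
        # integral of S over the interval via the ODE S' = -S/L0 + S_loc
        integral += l0_cm * (0.5 * (a + b) * h - (s_next - s))
        s = s_next
    return integral / length_cm, s


@dataclass
class SignalProfile:
    vessel_id: str          # segment id or "<pathway>:C/SV/LV"
    kind: str               # "LA", "SA", "C", "SV", "LV"
    s_meta: float
    s_up: float
    s_out: float
    mean_po2: float
    length_cm: float


def _conduct_profile(po2: np.ndarray, s_axial: np.ndarray, s_out: float,
                     length_cm: float, p0: float, l0: float) -> tuple[float, float, float]:
    """Helper: po2 sampled at axial positions (0 = upstream) -> conduction."""
    x = length_cm - s_axial[::-1]          # upstream coordinate from outflow
    sl = local_signal(po2, p0)[::-1]
    # ensure the sample grid spans [0, L]
    if x[0] > 0.0:
        x = np.concatenate([[0.0], x])
        sl = np.concatenate([[sl[0]], sl])
    if x[-1] < length_cm:
        x = np.concatenate([x, [length_cm]])
        sl = np.concatenate([sl, [sl[-1]]])
    s_meta, s_up = conduct_along_vessel(sl, s_out, length_cm, l0, x=x)
    return s_meta, s_up, float(np.mean(po2))


def propagate_network(
    net: VascularNetwork,
    chains: list[CompartmentChain],
    oxygen: GreensSolution,
    chain_profiles: list[dict[str, CompartmentOxygenProfile]],
    p0: float = 10.0,
    l0_cm: float = 1.0,
    combination: str = "sum",
) -> dict[str, SignalProfile]:
    """Propagate conducted metabolic signals through the whole hybrid model.

    ``combination`` controls how daughter signals merge at arteriolar
    bifurcations when conducting upstream: ``"sum"`` adds the daughters'
    upstream-end signals (additive conduction); ``"flow_weighted"`` averages
    them weighted by daughter flow.
    """
    if combination not in ("sum", "flow_weighted"):
        raise ValueError("combination must be 'sum' or 'flow_weighted'")
    if len(chains) != len(chain_profiles):
        raise ValueError("chains and chain_profiles must align")

    results: dict[str, SignalProfile] = {}
    terminal_s_out: dict[str, float] = {}

    # compartments: LV (zero downstream signal) -> SV -> C, per pathway
    for ch, profs in zip(chains, chain_profiles):
        s_out = 0.0
        for comp in (ch.large_venule, ch.small_venule, ch.capillary):
            prof = profs[comp.kind]
            s_meta, s_up, mean_po2 = _conduct_profile(
                prof.p_b, prof.s, s_out, comp.length_cm, p0, l0_cm
            )
            results[f"{ch.pathway_index}:{comp.kind}"] = SignalProfile(
                vessel_id=f"{ch.pathway_index}:{comp.kind}",
                kind=comp.kind, s_meta=s_meta, s_up=s_up, s_out=s_out,
                mean_po2=mean_po2, length_cm=comp.length_cm,
            )
            s_out = s_up
        terminal_s_out[ch.terminal_segment] = s_out

    # arterioles in reverse-topological order (children before parents)
    children: dict[str, list[str]] = {}
    for seg in net.segments.values():
        children.setdefault(seg.to_node, [])
    for seg in net.segments.values():
        children.setdefault(seg.from_node, []).append(seg.id)

    for seg in reversed(net.topological_segments()):
        if net.nodes[seg.to_node].kind == "terminal":
            if seg.id not in terminal_s_out:
                raise ValueError(f"terminal segment {seg.id} has no compartment chain")
            s_out = terminal_s_out[seg.id]
        else:
            kids = children.get(seg.to_node, [])
            if not kids:
                raise ValueError(f"segment {seg.id} ends at a dead junction")
            ups = [results[k].s_up for k in kids]
            if combination == "sum":
                s_out = float(np.sum(ups))
            else:
                w = np.array([max(net.segments[k].flow, 0.0) for k in kids])
                s_out = float(np.sum(w * ups) / w.sum()) if w.sum() > 0 else float(np.mean(ups))
        prof = oxygen.profiles[seg.id]
        s_meta, s_up, mean_po2 = _conduct_profile(
            prof.p_b, prof.s_mid, s_out, seg.length_cm, p0, l0_cm
        )
        results[seg.id] = SignalProfile(
            vessel_id=seg.id, kind=seg.seg_class or "LA",
            s_meta=s_meta, s_up=s_up, s_out=s_out,
            mean_po2=mean_po2, length_cm=seg.length_cm,
        )
    return results
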