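"""Arteriolar network representation, validation, scaling and synthesis.

The arteriolar bed is a directed tree: one inlet (the downstream end of the
central retinal artery), internal junction nodes, and terminal nodes where
terminal arterioles hand blood to the capillary compartments.  Each edge is a
straight vessel segment with a diameter (um) and length (cm).

Because the confocal-image-derived network geometry underlying the original
human extrapolation is not publicly deposited, this module also provides a
seeded synthetic generator that emulates its gross statistics: a small number
of main branches leaving the inlet, recursive bifurcation, uniform terminal
diameters, Murray-law parent/daughter calibers and log-normal length jitter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .units import UM_TO_CM

NODE_KINDS = ("inlet", "junction", "terminal")
SEGMENT_CLASSES = ("LA", "SA")


@dataclass
class NetworkNode:
    id: str
    position: np.ndarray  # 3-vector, cm
    kind: str = "junction"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class VesselSegment:
    """One arteriole edge: geometry plus mutable hemodynamic/oxygen state."""

    id: str
    from_node: str
    to_node: str
    diameter_um: float
    length_cm: float
    seg_class: str | None = None      # "LA" or "SA"
    flow: float = 0.0                 # cm^3/s, oriented from_node -> to_node
    pressure_drop: float = 0.0        # mmHg
    hematocrit: float = 0.0           # discharge hematocrit, fraction
    viscosity_cp: float = 0.0         # apparent viscosity, cP
    wall_shear: float = 0.0           # dyn/cm^2
    blood_po2_profile: np.ndarray | None = None  # mmHg at axial samples

    @property
    def diameter_cm(self) -> float:
        return self.diameter_um * UM_TO_CM

    @property
    def radius_cm(self) -> float:
        return 0.5 * self.diameter_um * UM_TO_CM


@dataclass
class Pathway:
    """Inlet-to-terminal vascular pathway (one per terminal arteriole)."""

    terminal_segment: str
    segment_ids: list[str]           # inlet-first order
    first_segment: str               # most upstream vessel of the pathway

    def __len__(self) -> int:
        return len(self.segment_ids)


@dataclass
class VascularNetwork:
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    segments: dict[str, VesselSegment] = field(default_factory=dict)
    inlet_pressure: float = 40.0     # mmHg
    terminal_pressure: float = 24.0  # mmHg
    pathways: list[Pathway] = field(default_factory=list)

    # -- topology helpers ---------------------------------------------------
    def inlet_node(self) -> str:
        inlets = [n.id for n in self.nodes.values() if n.kind == "inlet"]
        if len(inlets) != 1:
            raise ValueError(f"network must have exactly one inlet, found {len(inlets)}")
        return inlets[0]

    def terminal_nodes(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind == "terminal"]

    def out_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.from_node == node_id]

    def in_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.to_node == node_id]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, kind=n.kind, position=n.position)
        for s in self.segments.values():
            g.add_edge(s.from_node, s.to_node, segment=s.id)
        return g

    def topological_segments(self) -> list[VesselSegment]:
        """Segments ordered so that every parent precedes its children."""
        import networkx as nx

        g = self.to_networkx()
        order = list(nx.topological_sort(g))
        rank = {nid: i for i, nid in enumerate(order)}
        return sorted(self.segments.values(), key=lambda s: rank[s.from_node])

    def copy(self) -> "VascularNetwork":
        net = VascularNetwork(
            inlet_pressure=self.inlet_pressure,
            terminal_pressure=self.terminal_pressure,
        )
        for n in self.nodes.values():
            net.nodes[n.id] = NetworkNode(n.id, n.position.copy(), n.kind)
        for s in self.segments.values():
            net.segments[s.id] = replace(s)
        net.pathways = [
            Pathway(p.terminal_segment, list(p.segment_ids), p.first_segment)
            for p in self.pathways
        ]
        return net


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_network(net: VascularNetwork) -> list[str]:
    """Check structural invariants; returns a list of human-readable violations.

    An empty list means the network is a valid single-inlet directed tree with
    positive geometry, finite coordinates and every terminal reachable from
    the inlet.
    """
    violations: list[str] = []

    inlets = [n for n in net.nodes.values() if n.kind == "inlet"]
    if len(inlets) != 1:
        violations.append(f"inlet must be unique: found {len(inlets)}")

    for n in net.nodes.values():
        if n.kind not in NODE_KINDS:
            violations.append(f"node {n.id}: unknown kind {n.kind!r}")
        if not np.all(np.isfinite(n.position)):
            violations.append(f"node {n.id}: non-finite position")

    for s in net.segments.values():
        if s.diameter_um <= 0:
            violations.append(f"segment {s.id}: diameter > 0 violated")
        if s.length_cm <= 0:
            violations.append(f"segment {s.id}: length > 0 violated")
        if not (0.0 <= s.hematocrit <= 1.0):
            violations.append(f"segment {s.id}: hematocrit outside [0, 1]")
        for nid in (s.from_node, s.to_node):
            if nid not in net.nodes:
                violations.append(f"segment {s.id}: unknown node {nid}")

    out_deg = {nid: 0 for nid in net.nodes}
    for s in net.segments.values():
        if s.from_node in out_deg:
            out_deg[s.from_node] += 1
    for n in net.nodes.values():
        if n.kind == "terminal" and out_deg.get(n.id, 0) != 0:
            violations.append(f"node {n.id}: terminal nodes must have out-degree 0")

    # tree: connected and acyclic, #segments = #nodes - 1
    if len(net.segments) != len(net.nodes) - 1:
        violations.append(
            f"acyclic tree violated: {len(net.segments)} segments, "
            f"{len(net.nodes)} nodes (need #segments = #nodes - 1)"
        )
    try:
        import networkx as nx

        g = net.to_networkx()
        if g.number_of_nodes() and not nx.is_weakly_connected(g):
            violations.append("network is not connected")
        if not nx.is_directed_acyclic_graph(g):
            violations.append("acyclic violated: directed cycle present")
        elif inlets and len(inlets) == 1:
            reachable = nx.descendants(g, inlets[0].id) | {inlets[0].id}
            for t in net.terminal_nodes():
                if t not in reachable:
                    violations.append(f"terminal {t} not reachable from inlet")
    except Exception as exc:  # pragma: no cover - graph build failure
        violations.append(f"graph construction failed: {exc}")

    return violations


# ---------------------------------------------------------------------------
# Mouse -> human scaling
# ---------------------------------------------------------------------------

def scale_mouse_to_human(
    net: VascularNetwork,
    diameter_factor: float = 3.6,
    length_factor: float = 5.9,
) -> VascularNetwork:
    """Scale a murine network into a human-caliber network.

    Every diameter is multiplied by ``diameter_factor`` and every length and
    node coordinate by ``length_factor``; topology is untouched.  The default
    factors carry mouse retinal geometry to human scale (diameters x3.6 from
    oximetry calibers, lengths x5.9 from the CRA-to-fovea distance).
    """
    if diameter_factor <= 0 or length_factor <= 0:
        raise ValueError("scaling factors must be positive")
    out = net.copy()
    for n in out.nodes.values():
        n.position = n.position * length_factor
    for s in out.segments.values():
        s.diameter_um *= diameter_factor
        s.length_cm *= length_factor
    return out


# ---------------------------------------------------------------------------
# Synthetic tree generation
# ---------------------------------------------------------------------------

def generate_synthetic_tree(
    n_main_branches: int = 4,
    bifurcation_levels: int = 3,
    murray_exponent: float = 3.0,
    terminal_diameter_um: float | None = 22.0,
    root_diameter_um: float | None = None,
    length_to_diameter_ratio: float = 30.0,
    jitter: float = 0.0,
    seed: int = 0,
    branch_angles: Sequence[float] | None = None,
    spread_angle: float = math.pi / 5,
) -> VascularNetwork:
    """Generate a seeded planar bifurcating arteriolar tree.

    ``bifurcation_levels`` counts vessel generations: level 1 is the set of
    ``n_main_branches`` main branches leaving the inlet; each deeper level
    bifurcates symmetrically, so the tree carries
    ``n_main_branches * 2**(bifurcation_levels-1)`` terminal arterioles.

    Diameters follow the Murray relation ``D_parent^k = sum(D_daughter^k)``
    with symmetric splits.  Exactly one of ``terminal_diameter_um`` (diameters
    propagated upward, all terminals identical) or ``root_diameter_um``
    (propagated downward from each main branch) must be given.  Lengths are
    ``length_to_diameter_ratio * D``, perturbed by log-normal jitter of
    sigma ``jitter``; positions are laid out in the z = 0 plane with the main
    branches at configurable angles.
    """
    if n_main_branches < 1:
        raise ValueError("n_main_branches must be >= 1")
    if bifurcation_levels < 1:
        raise ValueError("bifurcation_levels must be >= 1")
    if murray_exponent <= 0:
        raise ValueError("murray_exponent must be positive")
    if (terminal_diameter_um is None) == (root_diameter_um is None):
        raise ValueError(
            "specify exactly one of terminal_diameter_um or root_diameter_um"
        )
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if seed is None:
        raise ValueError("a seed is required")

    rng = np.random.default_rng(seed)
    halving = 2.0 ** (1.0 / murray_exponent)  # symmetric Murray daughter ratio
    if terminal_diameter_um is not None:
        if terminal_diameter_um <= 0:
            raise ValueError("terminal_diameter_um must be positive")
        level_diam = [
            terminal_diameter_um * halving ** (bifurcation_levels - lv)
            for lv in range(1, bifurcation_levels + 1)
        ]
    else:
        if root_diameter_um <= 0:
            raise ValueError("root_diameter_um must be positive")
        level_diam = [
            root_diameter_um / halving ** (lv - 1)
            for lv in range(1, bifurcation_levels + 1)
        ]

    if branch_angles is None:
        # four main branches default to the superior/inferior temporal/nasal
        # quadrant directions; otherwise spread uniformly
        branch_angles = [
            2.0 * math.pi * j / n_main_branches + math.pi / n_main_branches
            for j in range(n_main_branches)
        ]
    if len(branch_angles) != n_main_branches:
        raise ValueError("branch_angles length must equal n_main_branches")

    net = VascularNetwork()
    net.nodes["n0"] = NetworkNode("n0", np.zeros(3), "inlet")
    counter = {"node": 0, "seg": 0}

    def new_node(pos: np.ndarray, kind: str) -> str:
        counter["node"] += 1
        nid = f"n{counter['node']}"
        net.nodes[nid] = NetworkNode(nid, pos, kind)
        return nid

    def new_segment(frm: str, to: str, d_um: float, l_cm: float) -> str:
        counter["seg"] += 1
        sid = f"s{counter['seg']}"
        net.segments[sid] = VesselSegment(sid, frm, to, d_um, l_cm)
        return sid

    def grow(from_id: str, angle: float, level: int) -> None:
        d_um = level_diam[level - 1]
        length = length_to_diameter_ratio * d_um * UM_TO_CM
        if jitter > 0:
            length *= float(rng.lognormal(mean=0.0, sigma=jitter))
        start = net.nodes[from_id].position
        pos = start + length * np.array([math.cos(angle), math.sin(angle), 0.0])
        kind = "terminal" if level == bifurcation_levels else "junction"
        to_id = new_node(pos, kind)
        new_segment(from_id, to_id, d_um, length)
        if level < bifurcation_levels:
            spread = spread_angle / (1.25 ** (level - 1))
            grow(to_id, angle - spread, level + 1)
            grow(to_id, angle + spread, level + 1)

    for ang in branch_angles:
        grow("n0", float(ang), 1)

    problems = validate_network(net)
    if problems:  # pragma: no cover - generator should always be valid
        raise RuntimeError("generated network invalid: " + "; ".join(problems))
    return net


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_segments(net: VascularNetwork) -> VascularNetwork:
    """Label segments LA/SA and enumerate inlet-to-terminal pathways in place.

    A segment ending at a terminal node is a small (terminal) arteriole, SA;
    every other segment is part of a large arteriole, LA.  One pathway is
    recorded per terminal arteriole; its ``first_segment`` is the most
    upstream vessel (the main branch leaving the inlet) whose diameter and
    inflow define the pathway's large-arteriole caliber and flow.
    """
    terminals = net.terminal_nodes()
    if not terminals:
        raise ValueError("network has no terminal nodes")

    parent_of = {s.to_node: s for s in net.segments.values()}
    for s in net.segments.values():
        is_terminal = net.nodes[s.to_node].kind == "terminal"
        s.seg_class = "SA" if is_terminal else "LA"

    net.pathways = []
    for t in terminals:
        chain: list[str] = []
        node = t
        while node in parent_of:
            seg = parent_of[node]
            chain.append(seg.id)
            node = seg.from_node
        chain.reverse()  # inlet-first
        net.pathways.append(
            Pathway(terminal_segment=chain[-1], segment_ids=chain, first_segment=chain[0])
        )
    return net


# ---------------------------------------------------------------------------
# I/O: CSV pair and JSON single file
# ---------------------------------------------------------------------------

def write_csv(net: VascularNetwork, nodes_path: str | Path, segments_path: str | Path) -> None:
    nodes = pd.DataFrame(
        [
            {"id": n.id, "x": n.position[0], "y": n.position[1], "z": n.position[2], "kind": n.kind}
            for n in net.nodes.values()
        ]
    )
    segs = pd.DataFrame(
        [
            {
                "id": s.id,
                "from": s.from_node,
                "to": s.to_node,
                "diameter_um": s.diameter_um,
                "length_cm": s.length_cm,
            }
            for s in net.segments.values()
        ]
    )
    nodes.to_csv(nodes_path, index=False, float_format="%.17g")
    segs.to_csv(segments_path, index=False, float_format="%.17g")


def read_csv(nodes_path: str | Path, segments_path: str | Path) -> VascularNetwork:
    net = VascularNetwork()
    nodes = pd.read_csv(nodes_path, dtype={"id": str}, float_precision="round_trip")
    segs = pd.read_csv(segments_path, dtype={"id": str, "from": str, "to": str},
                       float_precision="round_trip")
    for _, row in nodes.iterrows():
        net.nodes[row["id"]] = NetworkNode(
            row["id"], np.array([row["x"], row["y"], row["z"]]), row["kind"]
        )
    for _, row in segs.iterrows():
        net.segments[row["id"]] = VesselSegment(
            row["id"], row["from"], row["to"], row["diameter_um"], row["length_cm"]
        )
    return net


def to_json_dict(net: VascularNetwork) -> dict:
    return {
        "inlet_pressure_mmHg": net.inlet_pressure,
        "terminal_pressure_mmHg": net.terminal_pressure,
        "nodes": [
            {"id": n.id, "position": list(map(float, n.position)), "kind": n.kind}
            for n in net.nodes.values()
        ],
        "segments": [
            {
                "id": s.id,
                "from": s.from_node,
                "to": s.to_node,
                "diameter_um": s.diameter_um,
                "length_cm": s.length_cm,
            }
            for s in net.segments.values()
        ],
    }


def write_json(net: VascularNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_json_dict(net), indent=1))


def read_json(path: str | Path) -> VascularNetwork:
    data = json.loads(Path(path).read_text())
    net = VascularNetwork(
        inlet_pressure=data.get("inlet_pressure_mmHg", 40.0),
        terminal_pressure=data.get("terminal_pressure_mmHg", 24.0),
    )
    for nd in data["nodes"]:
        net.nodes[nd["id"]] = NetworkNode(nd["id"], np.array(nd["position"]), nd["kind"])
    for sd in data["segments"]:
        net.segments[sd["id"]] = VesselSegment(
            sd["id"], sd["from"], sd["to"], sd["diameter_um"], sd["length_cm"]
        )
    return net
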