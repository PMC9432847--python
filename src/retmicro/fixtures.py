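"""Deterministic networks for tests, demos and statistical emulation.

``make_toy_network`` returns tiny hand-specified trees with analytically
known flow splits; ``default_network`` is the seeded mid-size synthetic tree
used for demand sweeps; ``make_human_scale_network`` emulates the gross
statistics of an image-derived human retinal arteriolar bed (four main
branches, uniform terminal-arteriole calibers, a hundred-plus terminals).
"""

from __future__ import annotations

import numpy as np

from .network import (
    NetworkNode,
    VascularNetwork,
    VesselSegment,
    classify_segments,
    generate_synthetic_tree,
    validate_network,
)

TOY_KINDS = ("single", "y_split", "two_level", "four_branch")


def make_toy_network(kind: str) -> VascularNetwork:
    """Small hand-built trees with documented expected behavior.

    * ``single``:     one 22 um segment; flow is pure Poiseuille.
    * ``y_split``:    symmetric bifurcation; daughters carry half the parent
                      flow each.
    * ``two_level``:  asymmetric bifurcation (unequal daughter diameters and
                      lengths); checked against dense linear algebra.
    * ``four_branch``: four identical terminal branches from the inlet.
    """
    net = VascularNetwork()

    def node(nid, x, y, kind_):
        net.nodes[nid] = NetworkNode(nid, np.array([x, y, 0.0]), kind_)

    def seg(sid, a, b, d_um, l_cm):
        net.segments[sid] = VesselSegment(sid, a, b, d_um, l_cm)

    if kind == "single":
        node("n0", 0.0, 0.0, "inlet")
        node("n1", 0.1, 0.0, "terminal")
        seg("s1", "n0", "n1", 22.0, 0.1)
    elif kind == "y_split":
        node("n0", 0.0, 0.0, "inlet")
        node("n1", 0.08, 0.0, "junction")
        node("n2", 0.14, 0.05, "terminal")
        node("n3", 0.14, -0.05, "terminal")
        seg("s1", "n0", "n1", 28.0, 0.08)
        seg("s2", "n1", "n2", 22.0, 0.06)
        seg("s3", "n1", "n3", 22.0, 0.06)
    elif kind == "two_level":
        node("n0", 0.0, 0.0, "inlet")
        node("n1", 0.09, 0.0, "junction")
        node("n2", 0.16, 0.04, "terminal")
        node("n3", 0.14, -0.06, "terminal")
        seg("s1", "n0", "n1", 30.0, 0.09)
        seg("s2", "n1", "n2", 24.0, 0.08)
        seg("s3", "n1", "n3", 20.0, 0.07)
    elif kind == "four_branch":
        node("n0", 0.0, 0.0, "inlet")
        for j in range(4):
            ang = np.pi / 4 + j * np.pi / 2
            node(f"n{j+1}", 0.07 * np.cos(ang), 0.07 * np.sin(ang), "terminal")
            seg(f"s{j+1}", "n0", f"n{j+1}", 22.0, 0.07)
    else:
        raise ValueError(f"unknown toy network kind {kind!r}; choose from {TOY_KINDS}")

    problems = validate_network(net)
    assert not problems, problems
    return classify_segments(net)


def default_network(seed: int = 42) -> VascularNetwork:
    """Default mid-size synthetic arteriolar tree (4 branches, 32 terminals).

    Terminal arterioles share a 22 um caliber (a murine ~6 um terminal
    arteriole carried to human scale); lengths are 30 diameters with mild
    log-normal jitter so pathways are heterogeneous.
    """
    net = generate_synthetic_tree(
        n_main_branches=4,
        bifurcation_levels=3,
        murray_exponent=3.0,
        terminal_diameter_um=22.0,
        length_to_diameter_ratio=30.0,
        jitter=0.2,
        seed=seed,
    )
    return classify_segments(net)


def make_human_scale_network(seed: int = 0) -> VascularNetwork:
    """Human-scale emulation: four main branches, 128 uniform terminals."""
    net = generate_synthetic_tree(
        n_main_branches=4,
        bifurcation_levels=6,
        murray_exponent=3.0,
        terminal_diameter_um=22.0,
        length_to_diameter_ratio=28.0,
        jitter=0.25,
        seed=seed,
    )
    return classify_segments(net)
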