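"""Network representation, validation, scaling, synthesis and I/O."""

import numpy as np
import pytest

from retmicro.network import (
    NetworkNode,
    VascularNetwork,
    VesselSegment,
    classify_segments,
    generate_synthetic_tree,
    read_csv,
    read_json,
    scale_mouse_to_human,
    to_json_dict,
    validate_network,
    write_csv,
    write_json,
)
from retmicro.fixtures import make_toy_network


def _single():
    net = VascularNetwork()
    net.nodes["a"] = NetworkNode("a", np.zeros(3), "inlet")
    net.nodes["b"] = NetworkNode("b", np.array([0.1, 0, 0]), "terminal")
    net.segments["s"] = VesselSegment("s", "a", "b", 20.0, 0.1)
    return net


class TestValidation:
    def test_minimal_tree_is_valid(self):
        assert validate_network(_single()) == []

    def test_cycle_is_reported(self):
        net = _single()
        net.segments["back"] = VesselSegment("back", "b", "a", 20.0, 0.1)
        msgs = " ".join(validate_network(net))
        assert "acyclic" in msgs

    def test_nonpositive_diameter_is_reported(self):
        net = _single()
        net.segments["s"].diameter_um = 0.0
        assert any("diameter > 0" in v for v in validate_network(net))

    def test_duplicate_inlet_and_terminal_outdegree(self):
        net = _single()
        net.nodes["b"].kind = "inlet"
        assert any("inlet must be unique" in v for v in validate_network(net))
        net2 = _single()
        net2.nodes["c"] = NetworkNode("c", np.array([0.2, 0, 0]), "terminal")
        net2.segments["s2"] = VesselSegment("s2", "b", "c", 15.0, 0.1)
        # b is terminal but now has out-degree 1
        assert any("out-degree" in v for v in validate_network(net2))


class TestScaling:
    def test_mouse_to_human_factors(self):
        net = _single()
        net.segments["s"].diameter_um = 10.0
        out = scale_mouse_to_human(net, 3.6, 5.9)
        assert out.segments["s"].diameter_um == pytest.approx(36.0)
        assert out.segments["s"].length_cm == pytest.approx(0.59)
        assert np.allclose(out.nodes["b"].position, [0.59, 0, 0])

    def test_identity_and_inverse(self):
        net = make_toy_network("two_level")
        same = scale_mouse_to_human(net, 1.0, 1.0)
        back = scale_mouse_to_human(scale_mouse_to_human(net, 3.6, 5.9), 1 / 3.6, 1 / 5.9)
        for ref in (same, back):
            for sid, seg in net.segments.items():
                assert ref.segments[sid].diameter_um == pytest.approx(seg.diameter_um, rel=1e-12)
                assert ref.segments[sid].length_cm == pytest.approx(seg.length_cm, rel=1e-12)

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_mouse_to_human(_single(), 0.0, 1.0)


class TestGenerator:
    def test_seeded_determinism(self):
        a = generate_synthetic_tree(seed=7, jitter=0.3)
        b = generate_synthetic_tree(seed=7, jitter=0.3)
        c = generate_synthetic_tree(seed=8, jitter=0.3)
        assert to_json_dict(a) == to_json_dict(b)
        assert to_json_dict(a) != to_json_dict(c)

    def test_level_one_four_branches(self):
        net = generate_synthetic_tree(n_main_branches=4, bifurcation_levels=1, seed=0)
        assert len(net.terminal_nodes()) == 4
        assert len(net.segments) == 4

    def test_murray_closed_form_top_down(self):
        net = generate_synthetic_tree(
            n_main_branches=1, bifurcation_levels=2, murray_exponent=3.0,
            terminal_diameter_um=None, root_diameter_um=36.0, jitter=0.0, seed=1,
        )
        classify_segments(net)
        diams = sorted({s.diameter_um for s in net.segments.values()})
        assert diams[-1] == pytest.approx(36.0)
        assert diams[0] == pytest.approx(36.0 / 2 ** (1 / 3), rel=1e-12)

    def test_murray_relation_and_uniform_terminals(self):
        net = generate_synthetic_tree(bifurcation_levels=3, terminal_diameter_um=22.0,
                                      jitter=0.15, seed=3)
        classify_segments(net)
        term_d = {net.segments[p.terminal_segment].diameter_um for p in net.pathways}
        assert term_d == {22.0}
        # parent^3 = sum(daughter^3) for every bifurcation
        for node in net.nodes.values():
            outs = net.out_segments(node.id)
            ins = net.in_segments(node.id)
            if len(outs) == 2 and ins:
                dp = ins[0].diameter_um
                assert dp**3 == pytest.approx(sum(o.diameter_um**3 for o in outs), rel=1e-12)

    def test_tree_invariant_preserved(self):
        for seed in (0, 5):
            net = generate_synthetic_tree(seed=seed, jitter=0.4)
            assert len(net.segments) == len(net.nodes) - 1
            assert validate_network(net) == []

    @pytest.mark.parametrize("kwargs", [
        {"n_main_branches": 0}, {"bifurcation_levels": 0}, {"jitter": -0.1},
        {"terminal_diameter_um": -5.0},
        {"terminal_diameter_um": 22.0, "root_diameter_um": 100.0},
        {"terminal_diameter_um": None},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            generate_synthetic_tree(seed=0, **kwargs)


class TestClassification:
    def test_single_segment_degenerate_pathway(self):
        net = classify_segments(_single())
        seg = net.segments["s"]
        assert seg.seg_class == "SA"
        assert len(net.pathways) == 1
        pw = net.pathways[0]
        assert pw.first_segment == pw.terminal_segment == "s"

    def test_two_level_pathways(self):
        net = make_toy_network("two_level")
        assert len(net.pathways) == 2
        for pw in net.pathways:
            assert pw.first_segment == "s1"       # shared most-upstream vessel
            assert net.segments[pw.terminal_segment].seg_class == "SA"
        assert net.segments["s1"].seg_class == "LA"

    def test_four_branch_counts(self):
        net = make_toy_network("four_branch")
        assert len(net.pathways) == 4
        assert all(s.seg_class == "SA" for s in net.segments.values())

    def test_no_terminals_raises(self):
        net = VascularNetwork()
        net.nodes["a"] = NetworkNode("a", np.zeros(3), "inlet")
        with pytest.raises(ValueError):
            classify_segments(net)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        net = generate_synthetic_tree(seed=11, jitter=0.3)
        write_csv(net, tmp_path / "n.csv", tmp_path / "s.csv")
        back = read_csv(tmp_path / "n.csv", tmp_path / "s.csv")
        assert to_json_dict(back)["nodes"] == to_json_dict(net)["nodes"]
        assert to_json_dict(back)["segments"] == to_json_dict(net)["segments"]

    def test_json_round_trip(self, tmp_path):
        net = generate_synthetic_tree(seed=11, jitter=0.3)
        write_json(net, tmp_path / "net.json")
        back = read_json(tmp_path / "net.json")
        assert to_json_dict(back) == to_json_dict(net)
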