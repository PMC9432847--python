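"""Poiseuille flow, blood rheology, phase separation and the network solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retmicro.fixtures import make_toy_network
from retmicro.hemodynamics import (
    conductance,
    phase_separation,
    poiseuille_flow,
    solve_network_flow,
    viscosity_in_vivo,
    wall_shear,
)
from retmicro.units import mmhg_to_cgs

from oracles import dense_flow_oracle, pries_bifurcation_oracle


class TestPoiseuille:
    def test_capillary_control_state(self):
        # 6 mmHg over an 80 um-long 6 um capillary at 9.05 cP
        q = poiseuille_flow(6.0, 6.0, 0.080, 9.05)
        assert q == pytest.approx(3.51e-9, rel=2e-3)

    def test_zero_drop_and_sign(self):
        assert poiseuille_flow(0.0, 10.0, 0.1, 2.0) == 0.0
        assert poiseuille_flow(-4.0, 10.0, 0.1, 2.0) < 0.0

    def test_fourth_power_law(self):
        q1 = poiseuille_flow(5.0, 10.0, 0.1, 2.0)
        q2 = poiseuille_flow(5.0, 20.0, 0.1, 2.0)
        assert q2 / q1 == pytest.approx(16.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [(5, 0, 0.1, 2), (5, 10, 0, 2), (5, 10, 0.1, 0)])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            poiseuille_flow(bad[0], bad[1], bad[2], bad[3])


class TestViscosity:
    @pytest.mark.parametrize("d_um,expected", [(6.0, 9.05), (29.5, 2.28), (137.3, 2.39)])
    def test_control_state_viscosities(self, d_um, expected):
        # at discharge hematocrit 0.40 and 1 cP plasma the in-vivo law
        # reproduces the compartment control-state viscosities
        assert viscosity_in_vivo(d_um, 0.40, 1.0) == pytest.approx(expected, abs=0.01)

    def test_low_hematocrit_approaches_plasma(self):
        # the hematocrit-dependent term vanishes; only the wall-layer
        # geometric factor (D/(D-1.1))^2 remains, ~1 for large vessels
        assert viscosity_in_vivo(200.0, 0.0, 1.0) == pytest.approx(1.0, rel=0.02)

    def test_scales_with_plasma_viscosity(self):
        assert (viscosity_in_vivo(30.0, 0.4, 1.3)
                == pytest.approx(1.3 * viscosity_in_vivo(30.0, 0.4, 1.0), rel=1e-12))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            viscosity_in_vivo(1.0, 0.4)
        with pytest.raises(ValueError):
            viscosity_in_vivo(10.0, 1.0)


class TestWallShear:
    def test_capillary_control_state(self):
        tau, omega = wall_shear(3.51e-9, 6.0, 9.05)
        assert tau == pytest.approx(15.0, rel=0.01)
        assert omega == pytest.approx(tau / 0.0905, rel=1e-12)

    def test_zero_flow(self):
        assert wall_shear(0.0, 10.0, 2.0)[0] == 0.0

    def test_consistent_with_pressure_drop(self):
        dp, d_um, l_cm, mu = 7.0, 18.0, 0.12, 2.5
        q = poiseuille_flow(dp, d_um, l_cm, mu)
        tau, _ = wall_shear(q, d_um, mu)
        assert tau == pytest.approx(mmhg_to_cgs(dp) * d_um * 1e-4 / (4 * l_cm), rel=1e-12)


class TestPhaseSeparation:
    def test_symmetric_split(self):
        h1, h2 = phase_separation(0.4, 2e-6, 1e-6, 1e-6, 20.0, 15.0, 15.0)
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert h1 == pytest.approx(0.4, rel=1e-12)

    def test_all_flow_one_daughter(self):
        h1, h2 = phase_separation(0.4, 1e-6, 1e-6, 0.0, 20.0, 15.0, 15.0)
        assert h1 == pytest.approx(0.4)
        assert h2 == 0.0

    def test_matches_direct_law_evaluation(self):
        hd, qp, d_p, d1, d2 = 0.45, 3e-6, 25.0, 18.0, 14.0
        for frac in (0.2, 0.35, 0.5, 0.65, 0.8):
            q1 = frac * qp
            h1, h2 = phase_separation(hd, qp, q1, qp - q1, d_p, d1, d2)
            fqe = pries_bifurcation_oracle(hd, frac, d_p, d1, d2)
            assert h1 == pytest.approx(fqe * hd * qp / q1, rel=1e-10)
            assert h2 == pytest.approx((1 - fqe) * hd * qp / (qp - q1), rel=1e-10)

    @given(
        hd=st.floats(0.1, 0.6),
        frac=st.floats(0.05, 0.95),
        d1=st.floats(8.0, 30.0),
        d2=st.floats(8.0, 30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_red_cell_flux_conserved(self, hd, frac, d1, d2):
        qp = 2.5e-6
        h1, h2 = phase_separation(hd, qp, frac * qp, (1 - frac) * qp, 32.0, d1, d2)
        assert 0.0 <= h1 <= 1.0 and 0.0 <= h2 <= 1.0
        assert (frac * qp * h1 + (1 - frac) * qp * h2
                == pytest.approx(qp * hd, rel=1e-10))

    def test_zero_parent_flow_raises(self):
        with pytest.raises(ValueError):
            phase_separation(0.4, 0.0, 0.0, 0.0, 20.0, 15.0, 15.0)


class TestNetworkSolve:
    def test_single_segment_reduces_to_poiseuille(self, single_vessel):
        sol = solve_network_flow(single_vessel, 40.0, 24.0)
        seg = single_vessel.segments["s1"]
        expected = poiseuille_flow(16.0, seg.diameter_um, seg.length_cm,
                                   sol.viscosity_cp["s1"])
        assert sol.flows["s1"] == pytest.approx(expected, rel=1e-12)
        assert sol.hematocrit["s1"] == pytest.approx(0.40)

    def test_symmetric_y_split(self, y_split):
        sol = solve_network_flow(y_split, 40.0, 24.0)
        assert sol.converged
        assert sol.flows["s2"] == pytest.approx(sol.flows["s3"], rel=1e-10)
        assert sol.flows["s2"] == pytest.approx(0.5 * sol.flows["s1"], rel=1e-10)

    def test_asymmetric_matches_dense_oracle(self):
        net = make_toy_network("two_level")
        mu = 2.0
        sol = solve_network_flow(net, 40.0, 24.0, uniform_viscosity_cp=mu)
        g = {sid: conductance(s.diameter_um, s.length_cm, mu)
             for sid, s in net.segments.items()}
        _, flows = dense_flow_oracle(
            list(net.nodes),
            [(s.id, s.from_node, s.to_node) for s in net.segments.values()],
            {"n0": mmhg_to_cgs(40.0), "n2": mmhg_to_cgs(24.0), "n3": mmhg_to_cgs(24.0)},
            g,
        )
        for sid in net.segments:
            assert sol.flows[sid] == pytest.approx(flows[sid], rel=1e-12)

    def test_mass_and_rbc_flux_conservation(self, default_net, default_flow):
        sol = default_flow
        assert sol.converged
        for node in default_net.nodes.values():
            if node.kind != "junction":
                continue
            q_in = sum(sol.flows[s.id] for s in default_net.in_segments(node.id))
            q_out = sum(sol.flows[s.id] for s in default_net.out_segments(node.id))
            assert abs(q_in - q_out) <= 1e-10 * max(q_in, q_out)
        inlet = default_net.inlet_node()
        rbc_in = sum(sol.flows[s.id] * sol.hematocrit[s.id]
                     for s in default_net.out_segments(inlet))
        rbc_out = sum(sol.flows[p.terminal_segment] * sol.hematocrit[p.terminal_segment]
                      for p in default_net.pathways)
        assert abs(rbc_in - rbc_out) <= 1e-8 * rbc_in

    def test_pressures_decrease_downstream(self, default_net, default_flow):
        for seg in default_net.segments.values():
            assert (default_flow.node_pressures[seg.from_node]
                    > default_flow.node_pressures[seg.to_node])

    def test_total_flow_monotone_in_driving_pressure(self, y_split):
        q = [solve_network_flow(y_split, 24.0 + dp, 24.0).flows["s1"]
             for dp in (8.0, 16.0, 24.0)]
        assert q[0] < q[1] < q[2]
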