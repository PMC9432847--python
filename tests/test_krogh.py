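"""Krogh-cylinder radial profiles and axial capillary marching."""

import numpy as np
import pytest
from scipy.optimize import brentq

from retmicro.compartments import Compartment, CompartmentChain
from retmicro.krogh import (
    KroghConsumptionModel,
    KroghGeometry,
    capillary_inflow_po2,
    krogh_radial_profile,
    march_axial,
    oxygen_flux_balance_error,
)
from retmicro.oxygen import OxygenParams, oxygen_content


GEOM = KroghGeometry(3e-4, 22e-4)


def _chain(l_c=0.06, q_c=3.51e-9, hd=0.4, d=19e-4):
    cap = Compartment("C", 300.0, 6.0, l_c, 9.05, 15.0, 5.0, q_c)
    sv = Compartment("SV", 1.0, 29.5, 0.03, 2.28, 15.6, 0.3, 1e-6)
    lv = Compartment("LV", 0.1, 137.3, 0.2, 2.39, 14.7, 2.7, 1e-5)
    return CompartmentChain(0, "s1", cap, sv, lv, hd, 1e-6, 137.3, 22.0,
                            tissue_width_cm=d)


class TestRadialProfile:
    def test_no_demand_is_flat(self):
        r, po2, cons = krogh_radial_profile(60.0, GEOM, OxygenParams(m0=0.0))
        assert np.allclose(po2, 60.0)
        assert cons == 0.0

    def test_zero_wall_po2(self):
        r, po2, cons = krogh_radial_profile(0.0, GEOM, OxygenParams(m0=2.0))
        assert np.all(po2 == 0.0)
        assert cons == 0.0

    def test_zero_order_limit_matches_classic_closed_form(self):
        # with P0 << P_b the kinetics saturate and the classic Krogh annulus
        # solution applies: P = P_b + M0 (r^2 - r_v^2)/(4K) - M0 r_t^2 ln(r/r_v)/(2K)
        params = OxygenParams(m0=2.0, p0=0.01)
        p_b = 80.0
        r, po2, cons = krogh_radial_profile(p_b, GEOM, params)
        k, m0 = params.d_diff_alpha, params.m0_cgs
        closed = (p_b + m0 * (r**2 - GEOM.r_v_cm**2) / (4 * k)
                  - m0 * GEOM.r_t_cm**2 / (2 * k) * np.log(r / GEOM.r_v_cm))
        assert np.max(np.abs(po2 - closed)) <= 0.1
        assert cons == pytest.approx(
            m0 * np.pi * (GEOM.r_t_cm**2 - GEOM.r_v_cm**2), rel=1e-3)

    def test_profile_decreases_outward(self):
        _, po2, _ = krogh_radial_profile(40.0, GEOM, OxygenParams(m0=2.0))
        assert np.all(np.diff(po2) <= 1e-12)

    def test_interpolated_model_matches_direct_solve(self):
        params = OxygenParams(m0=2.0)
        model = KroghConsumptionModel(GEOM, params)
        for p_b in (3.0, 17.0, 55.0, 90.0):
            direct = krogh_radial_profile(p_b, GEOM, params)[2]
            assert model.consumption_per_length(p_b) == pytest.approx(direct, rel=5e-3)


class TestAxialMarch:
    def test_no_consumption_preserves_po2(self):
        profs = march_axial(_chain(), 65.0, OxygenParams(m0=0.0))
        assert profs["C"].downstream_po2 == pytest.approx(65.0, abs=1e-9)
        assert profs["SV"].p_b[0] == pytest.approx(65.0, abs=1e-9)
        assert profs["LV"].p_b[-1] == pytest.approx(65.0, abs=1e-9)

    def test_constant_consumption_saturation_drop(self):
        # with a constant efflux per length and the dissolved term disabled,
        # flux balance gives dS = -c L / (Q H_D C0) exactly
        class ConstModel:
            def consumption_per_length(self, p_b):
                return 2e-9 if p_b > 0 else 0.0

        params = OxygenParams(m0=2.0)
        ch = _chain()
        profs = march_axial(ch, 70.0, params, consumption_model=ConstModel(),
                            include_dissolved=False, n_steps=400)
        c = profs["C"]
        from retmicro.oxygen import hill_saturation

        ds = hill_saturation(c.p_b[-1], params.p50, params.n_hill) - \
            hill_saturation(c.p_b[0], params.p50, params.n_hill)
        expected = -2e-9 * ch.capillary.length_cm / (
            ch.capillary.q_per_segment * ch.hematocrit * params.c0)
        assert ds == pytest.approx(expected, rel=1e-6)

    def test_flux_balance_without_clamping(self):
        params = OxygenParams(m0=2.0)
        ch = _chain()
        profs = march_axial(ch, 70.0, params)
        assert profs["C"].clamped_from is None
        assert oxygen_flux_balance_error(profs["C"], ch, params) <= 0.005

    def test_zero_clamp_rule(self):
        # low inflow + high demand: po2 hits zero inside the capillary and
        # every downstream sample stays exactly zero
        params = OxygenParams(m0=4.0)
        profs = march_axial(_chain(), 5.0, params)
        c = profs["C"]
        assert c.clamped_from is not None
        clamped = c.s >= c.clamped_from
        assert np.all(c.p_b[clamped] == 0.0)
        assert c.downstream_po2 == 0.0
        # venules inherit the zero
        assert np.all(profs["LV"].p_b == 0.0)

    def test_monotone_in_demand(self):
        ups, downs = [], []
        for m0 in (0.5, 1.0, 2.0, 4.0):
            profs = march_axial(_chain(), 70.0, OxygenParams(m0=m0))
            ups.append(profs["C"].upstream_po2)
            downs.append(profs["C"].downstream_po2)
        assert all(a >= b for a, b in zip(downs, downs[1:]))
        assert downs[0] > downs[-1]

    def test_venules_exchange_nothing(self):
        profs = march_axial(_chain(), 60.0, OxygenParams(m0=2.0))
        for kind in ("SV", "LV"):
            assert np.all(np.diff(profs[kind].p_b) == 0.0)
            assert np.all(profs[kind].consumption_per_length == 0.0)


class TestCapillaryInflow:
    def setup_method(self):
        self.params = OxygenParams()

    def test_single_arteriole_identity(self):
        assert capillary_inflow_po2([1e-6], [0.4], [63.0], self.params) == \
            pytest.approx(63.0, abs=1e-7)

    def test_two_identical_arterioles(self):
        assert capillary_inflow_po2([1e-6, 1e-6], [0.4, 0.4], [55.0, 55.0],
                                    self.params) == pytest.approx(55.0, abs=1e-7)

    def test_mixed_inflow_matches_bisection_oracle(self):
        q = [1.0e-6, 2.5e-6]
        hd = [0.35, 0.45]
        po2 = [70.0, 40.0]
        got = capillary_inflow_po2(q, hd, po2, self.params)
        content = sum(
            qi * oxygen_content(hi, pi, self.params) for qi, hi, pi in zip(q, hd, po2)
        ) / sum(q)
        hd_mix = sum(qi * hi for qi, hi in zip(q, hd)) / sum(q)
        oracle = brentq(
            lambda p: oxygen_content(hd_mix, p, self.params) - content, 0.0, 200.0,
            xtol=1e-12)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_zero_flow_raises(self):
        with pytest.raises(ValueError):
            capillary_inflow_po2([0.0], [0.4], [60.0], self.params)
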