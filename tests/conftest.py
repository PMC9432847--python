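"""Shared fixtures: small networks solved once per session."""

from __future__ import annotations

import numpy as np
import pytest

from retmicro import SimConfig, run_pipeline, solve_network_flow
from retmicro.fixtures import default_network, make_toy_network


def small_run_config() -> SimConfig:
    """Problem sizes used for whole-pipeline tests: coarser tissue sampling
    and vessel elements than the production defaults, chosen to keep a
    three-level demand sweep to a couple of minutes on one core."""
    return SimConfig(
        tissue_spacing_cm=0.012,
        tissue_margin_cm=0.03,
        tissue_thickness_cm=0.024,
        max_element_len_cm=40e-4,
    )


@pytest.fixture(scope="session")
def default_net():
    return default_network(seed=42)


@pytest.fixture(scope="session")
def default_flow(default_net):
    return solve_network_flow(default_net, 40.0, 24.0)


@pytest.fixture(scope="session")
def demand_sweep_runs(default_net):
    """Full pipeline on the default seeded network at M0 = 1, 2, 4."""
    cfg = small_run_config()
    net = default_net.copy()
    runs = []
    flow = chains = None
    for m0 in (1.0, 2.0, 4.0):
        res = run_pipeline(cfg, net, m0=m0, flow=flow, chains=chains)
        flow, chains = res.flow, res.chains
        runs.append(res)
    return runs


@pytest.fixture()
def y_split():
    return make_toy_network("y_split")


@pytest.fixture()
def single_vessel():
    return make_toy_network("single")
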