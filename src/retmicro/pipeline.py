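"""Single-process orchestration of the hybrid-model pipeline.

Stage order (executed exactly once per oxygen-demand level; no regulation
feedback):

1. classify the arteriolar tree into pathways (LA/SA),
2. solve network hemodynamics (pressures, flows, hematocrit, viscosity),
3. build the C/SV/LV compartment chains and the shared tissue annulus width,
4. Green's-function oxygen transport on the arterioles,
5. hand terminal-arteriole outflow po2 to the capillary compartments and
   march Krogh-cylinder extraction down each chain,
6. conduct metabolic wall signals from the large-venule outlets upstream
   through the whole network.

The flow solution and compartment geometry are independent of oxygen demand,
so demand sweeps reuse them across M0 values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compartments import CompartmentChain, build_all_chains, solve_tissue_width
from .config import SimConfig
from .greens import GreensSolution, solve_greens
from .hemodynamics import FlowSolution, solve_network_flow
from .krogh import (
    CompartmentOxygenProfile,
    KroghConsumptionModel,
    KroghGeometry,
    capillary_inflow_po2,
    march_axial,
)
from .network import VascularNetwork, classify_segments
from .signals import SignalProfile, propagate_network
from .units import UM_TO_CM

log = logging.getLogger("retmicro")


@dataclass
class RunResult:
    config: SimConfig
    m0: float
    network: VascularNetwork
    flow: FlowSolution
    chains: list[CompartmentChain]
    tissue_width_cm: float
    oxygen: GreensSolution
    chain_profiles: list[dict[str, CompartmentOxygenProfile]]
    signals: dict[str, SignalProfile]
    summary: dict


def _summary(result_m0: float, net: VascularNetwork, chains, chain_profiles,
             signals, oxygen, cfg: SimConfig) -> dict:
    cap_up = np.array([p["C"].upstream_po2 for p in chain_profiles])
    cap_dn = np.array([p["C"].downstream_po2 for p in chain_profiles])
    ven = np.array([p["LV"].upstream_po2 for p in chain_profiles])
    # pointwise conducted signal at the upstream end of each capillary
    s_cap_up = np.array([signals[f"{c.pathway_index}:C"].s_up for c in chains])
    s_term = np.array([signals[c.terminal_segment].s_meta for c in chains])
    s_all_art = np.array([signals[s.id].s_meta for s in net.segments.values()])
    return {
        "m0": result_m0,
        "capillary_upstream_po2_mean": float(cap_up.mean()),
        "capillary_upstream_po2_sd": float(cap_up.std(ddof=0)),
        "capillary_downstream_po2_mean": float(cap_dn.mean()),
        "capillary_downstream_po2_sd": float(cap_dn.std(ddof=0)),
        "venular_po2_mean": float(ven.mean()),
        "smeta_capillary_upstream_mean": float(s_cap_up.mean()),
        "smeta_capillary_upstream_sd": float(s_cap_up.std(ddof=0)),
        "smeta_terminal_arteriole_mean": float(s_term.mean()),
        "smeta_terminal_arteriole_sd": float(s_term.std(ddof=0)),
        "smeta_arteriole_mean": float(s_all_art.mean()),
        "tissue_po2_mean": float(oxygen.tissue.po2.mean()),
        "tissue_po2_sd": float(oxygen.tissue.po2.std(ddof=0)),
        "oxygen_mass_balance_error": oxygen.mass_balance_error(),
        "greens_converged": oxygen.converged,
        "greens_iterations": oxygen.iterations,
    }


def run_pipeline(
    config: SimConfig,
    net: VascularNetwork,
    m0: float | None = None,
    out_dir: str | Path | None = None,
    flow: FlowSolution | None = None,
    chains: list[CompartmentChain] | None = None,
) -> RunResult:
    """Run all stages for one oxygen-demand level; optionally write outputs.

    ``flow``/``chains`` may be passed in to reuse demand-independent stages
    (as :func:`demand_sweep` does).
    """
    config.validate()
    m0 = config.m0 if m0 is None else m0
    if not net.pathways:
        classify_segments(net)
    net.inlet_pressure = config.p_a
    net.terminal_pressure = config.terminal_pressure

    if flow is None:
        log.info("stage flow: solving network hemodynamics")
        flow = solve_network_flow(
            net, config.p_a, config.terminal_pressure,
            hd_in=config.hd_in, plasma_viscosity_cp=config.plasma_viscosity_cp,
            tol=config.flow_tol, max_iter=config.flow_max_iter,
        )
        if not flow.converged:
            raise RuntimeError("stage flow: iterative rheology did not converge")
        log.info("stage flow: converged in %d iterations", flow.iterations)

    if chains is None:
        log.info("stage compartments: building C/SV/LV chains")
        chains = build_all_chains(net, flow, config.control_params())
        d = solve_tissue_width(chains, config.control_params())
        log.info("stage compartments: tissue width d = %.2f um", d / UM_TO_CM)
    d = chains[0].tissue_width_cm

    params = config.oxygen_params(m0=m0)
    log.info("stage oxygen: Green's function solve at M0 = %g", m0)
    oxygen = solve_greens(
        net, flow, params,
        domain=config.tissue_domain(),
        tol=config.oxygen_tol_mmhg,
        max_iter=config.oxygen_max_iter,
        max_element_len_cm=config.max_element_len_cm,
    )
    if not oxygen.converged:
        raise RuntimeError(
            f"stage oxygen: Green's function iteration did not converge "
            f"(residual {oxygen.residual:.3g} mmHg)"
        )
    log.info("stage oxygen: %d iterations, mass balance error %.3g",
             oxygen.iterations, oxygen.mass_balance_error())

    r_v = 0.5 * config.d_c_um * UM_TO_CM
    geom = KroghGeometry(r_v, r_v + d)
    krogh_model = KroghConsumptionModel(geom, params)
    chain_profiles = []
    for ch in chains:
        term = ch.terminal_segment
        p_in = capillary_inflow_po2(
            [flow.flows[term]], [flow.hematocrit[term]],
            [oxygen.terminal_po2[term]], params,
        )
        chain_profiles.append(
            march_axial(ch, p_in, params, consumption_model=krogh_model,
                        include_dissolved=config.include_dissolved)
        )

    log.info("stage signal: conducting metabolic wall signals upstream")
    signals = propagate_network(
        net, chains, oxygen, chain_profiles,
        p0=config.p0, l0_cm=config.l0_cm, combination=config.signal_combination,
    )

    summary = _summary(m0, net, chains, chain_profiles, signals, oxygen, config)
    result = RunResult(config, m0, net, flow, chains, d, oxygen,
                       chain_profiles, signals, summary)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def demand_sweep(
    config: SimConfig,
    net: VascularNetwork,
    m0_values=(1.0, 2.0, 4.0),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the pipeline across oxygen-demand levels; one summary row per M0.

    The hemodynamic solve and compartment geometry are demand-independent and
    shared across the sweep.
    """
    results = []
    flow = None
    chains = None
    for m0 in m0_values:
        if float(m0) <= 0:
            raise ValueError("M0 values must be positive")
        sub = Path(out_dir) / f"m0_{m0:g}" if out_dir is not None else None
        res = run_pipeline(config, net, m0=float(m0), out_dir=sub,
                           flow=flow, chains=chains)
        flow, chains = res.flow, res.chains
        results.append(res.summary)
    table = pd.DataFrame(results)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "sweep_summary.csv", index=False,
                     float_format="%.10g")
    return table


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_outputs(result: RunResult, out_dir: str | Path,
                  write_vtk: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, flow = result.network, result.flow
    ff = "%.10g"

    pd.DataFrame(
        [
            {
                "segment": sid, "class": net.segments[sid].seg_class,
                "Q_cm3_s": flow.flows[sid], "dP_mmHg": flow.pressure_drop[sid],
                "H_D": flow.hematocrit[sid], "mu_cP": flow.viscosity_cp[sid],
                "tau_dyn_cm2": flow.wall_shear_stress[sid],
            }
            for sid in net.segments
        ]
    ).to_csv(out / "flow.csv", index=False, float_format=ff)

    t = result.oxygen.tissue
    pd.DataFrame(
        {"x": t.points[:, 0], "y": t.points[:, 1], "z": t.points[:, 2],
         "po2_mmHg": t.po2}
    ).to_csv(out / "tissue_po2.csv", index=False, float_format=ff)
    if write_vtk:
        write_tissue_vtk(t.points, t.po2, out / "tissue_po2.vtk")

    pd.DataFrame(
        [
            {
                "pathway": ch.pathway_index,
                "terminal_segment": ch.terminal_segment,
                "upstream_po2_mmHg": p["C"].upstream_po2,
                "downstream_po2_mmHg": p["C"].downstream_po2,
                "clamp_position_cm": (np.nan if p["C"].clamped_from is None
                                      else p["C"].clamped_from),
            }
            for ch, p in zip(result.chains, result.chain_profiles)
        ]
    ).to_csv(out / "capillary_po2.csv", index=False, float_format=ff)

    pd.DataFrame(
        [
            {
                "pathway": ch.pathway_index, "kind": c.kind, "n": c.n,
                "D_um": c.diameter_um, "L_cm": c.length_cm,
                "mu_cP": c.viscosity_cp, "tau_dyn_cm2": c.wall_shear,
                "dP_mmHg": c.pressure_drop, "Q_cm3_s": c.q_per_segment,
            }
            for ch in result.chains for c in ch.compartments
        ]
    ).to_csv(out / "compartments.csv", index=False, float_format=ff)

    rows = []
    for sid, sig in result.signals.items():
        q = flow.flows.get(sid, np.nan)
        rows.append(
            {"vessel": sid, "class": sig.kind, "S_meta": sig.s_meta,
             "S_up": sig.s_up, "mean_po2_mmHg": sig.mean_po2, "Q_cm3_s": q}
        )
    pd.DataFrame(rows).to_csv(out / "smeta.csv", index=False, float_format=ff)

    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))


def write_tissue_vtk(points: np.ndarray, po2: np.ndarray, path: str | Path) -> None:
    """Write the tissue po2 point cloud as legacy ASCII VTK polydata."""
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        "retmicro tissue po2",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in points]
    lines += [f"POINT_DATA {n}", "SCALARS po2 float 1", "LOOKUP_TABLE default"]
    lines += [f"{v:.6g}" for v in po2]
    Path(path).write_text("\n".join(lines) + "\n")


def tissue_po2_histogram(oxygen: GreensSolution, bins: int = 20) -> pd.DataFrame:
    """Histogram of tissue po2 (percent of sample points per bin)."""
    counts, edges = np.histogram(oxygen.tissue.po2, bins=bins)
    return pd.DataFrame(
        {"po2_low": edges[:-1], "po2_high": edges[1:],
         "percent": 100.0 * counts / counts.sum()}
    )
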