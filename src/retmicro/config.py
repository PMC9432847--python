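"""Simulation configuration: every global scalar in one place, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .compartments import DEFAULT_SHEAR_RATE_TABLE, ControlStateParams
from .greens import TissueDomain
from .oxygen import OxygenParams


@dataclass
class SimConfig:
    """All scalar parameters of a hybrid-model run (interface units).

    Pressures in mmHg, diameters in um, L0 in cm, oxygen demand M0 in
    cm^3 O2/100 cm^3/min, D_diff*alpha in cm^3 O2/cm/s/mmHg.
    """

    # boundary conditions / control state
    p_a: float = 40.0
    iop: float = 15.0
    terminal_pressure: float = 24.0
    hd_in: float = 0.40
    plasma_viscosity_cp: float = 1.0
    # oxygen transport
    m0: float = 1.0
    p0: float = 10.0
    p50: float = 26.0
    n_hill: float = 2.7
    d_diff_alpha: float = 6.0e-10
    c0: float = 0.5
    alpha_b: float = 3.1e-5
    inflow_po2: float = 84.4
    # metabolic signal
    l0_cm: float = 1.0
    signal_combination: str = "sum"
    include_dissolved: bool = True
    # compartment control state
    d_c_um: float = 6.0
    tau_c: float = 15.0
    capillary_density: float = 50_000.0
    a_vol: float = 0.0025
    d_sv_anchor_um: float = 69.0
    d_lv_anchor_um: float = 140.0
    shear_rate_table: list = field(
        default_factory=lambda: [list(r) for r in DEFAULT_SHEAR_RATE_TABLE]
    )
    # tissue sampling for the Green's function solve
    tissue_spacing_cm: float = 0.004
    tissue_margin_cm: float = 0.02
    tissue_thickness_cm: float = 0.02
    max_element_len_cm: float = 25e-4
    # numerics
    flow_tol: float = 1e-6
    flow_max_iter: int = 100
    oxygen_tol_mmhg: float = 1e-3
    oxygen_max_iter: int = 200
    seed: int = 42

    def validate(self) -> None:
        if self.p_a <= self.iop:
            raise ValueError("P_a must exceed IOP")
        if not (0.0 <= self.hd_in < 1.0):
            raise ValueError("inlet hematocrit must lie in [0, 1)")
        if self.m0 < 0:
            raise ValueError("oxygen demand must be non-negative")
        self.oxygen_params().validate()
        self.control_params().validate()

    # -- views used by the stage modules ------------------------------------
    def oxygen_params(self, m0: float | None = None) -> OxygenParams:
        return OxygenParams(
            d_diff_alpha=self.d_diff_alpha,
            m0=self.m0 if m0 is None else m0,
            p0=self.p0, p50=self.p50, n_hill=self.n_hill,
            c0=self.c0, alpha_b=self.alpha_b, inflow_po2=self.inflow_po2,
        )

    def control_params(self) -> ControlStateParams:
        return ControlStateParams(
            p_a=self.p_a, iop=self.iop,
            arteriolar_drop=self.p_a - self.terminal_pressure,
            d_c_um=self.d_c_um, tau_c=self.tau_c,
            capillary_density=self.capillary_density, a_vol=self.a_vol,
            d_sv_anchor_um=self.d_sv_anchor_um,
            d_lv_anchor_um=self.d_lv_anchor_um,
            plasma_viscosity_cp=self.plasma_viscosity_cp,
            shear_rate_table=tuple(tuple(r) for r in self.shear_rate_table),
        )

    def tissue_domain(self) -> TissueDomain:
        return TissueDomain(
            spacing=self.tissue_spacing_cm,
            margin=self.tissue_margin_cm,
            thickness=self.tissue_thickness_cm,
        )

    # -- persistence ---------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
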