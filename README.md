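# retmicro

A hybrid model of the human retinal microcirculation: a heterogeneous,
tree-structured arteriolar network is solved for pressure-driven blood flow
and Green's-function oxygen transport, and every terminal arteriole feeds a
series chain of capillary / small-venule / large-venule compartments with
Krogh-cylinder oxygen extraction.  From the resulting blood and tissue
oxygen fields the package computes the conducted *metabolic wall signal* in
every vessel — the upstream-travelling vasoregulatory signal that ultimately
drives arteriolar tone.

The package is aimed at computational physiologists studying retinal
hemodynamics and oxygenation (e.g. in glaucoma research), where the question
is how heterogeneous network structure shapes the spatial distribution of
perfusion, PO₂ and metabolic signalling.

## Model summary

**Hemodynamics.** Each vessel obeys Poiseuille's law
`Q = π ΔP D⁴ / (128 μ L)` with mass conservation at every junction.  The
apparent viscosity `μ(D, H_D)` follows the empirical in-vivo
diameter–hematocrit law of Pries et al. (Fåhræus–Lindqvist effect), and red
cells partition at bifurcations by the empirical phase-separation law.  The
network solve alternates a sparse nodal pressure solve with hematocrit
propagation and viscosity updates.  Boundary conditions: 40 mmHg at the
inlet (central retinal artery), 24 mmHg at every terminal arteriole — a
16 mmHg arteriolar pressure drop.

**Oxygen transport (arterioles).** Steady tissue diffusion–consumption,
`K ∇²P = M(P)` with `K = D_diff·α = 6×10⁻¹⁰ cm³O₂/cm/s/mmHg` and
Michaelis–Menten kinetics `M(P) = M₀ P/(P₀+P)` (`P₀ = 10 mmHg`), is solved
by a Green's-function method: vessel elements are line sources of unknown
strength, tissue sample points are linearized sinks, and PO₂ is the
superposition of free-space kernels `1/(4πK r)`.  Intravascular transport
couples in through `df/ds = −q(s)` with
`f = Q (H_D C₀ S(P_b) + α_b P_b)` and the Hill saturation
`S(P) = Pⁿ/(Pⁿ+P50ⁿ)` (`P50 = 26 mmHg`, `n = 2.7`).

**Compartments.** Per pathway, symmetry assumptions set the venular
geometry from the arteriolar one (`n_SA = n_SV = 1`, `n_LA = n_LV`,
`L_SA = L_SV`, `L_LA = L_LV`, `D_SV = D_SA (ω_SA/ω_SV)^{1/3}`, …), capillary
flow comes from an assumed wall shear stress
(`Q_C = π τ_C D_C³ / (32 μ_C)`), and the capillary pressure drop is the
residual of the total perfusion pressure `P_a − IOP`.  A fixed capillary
density (50,000/cm²) determines the Krogh tissue annulus width `d`, and
blood PO₂ is marched down each capillary against the Krogh-cylinder
consumption; venules exchange no oxygen.

**Metabolic signal.** Each point of each vessel generates
`S_loc = P₀/(P₀+PO₂)`; the conducted signal decays exponentially upstream
with length constant `L₀ = 1 cm`, starting from zero at the large-venule
outlet, and each vessel reports its length-averaged response `S_meta`.

## Worked example

Generate the default seeded synthetic arteriolar tree (4 main branches,
16 terminal arterioles of 22 µm) and sweep oxygen demand:

```bash
retmicro generate-network --kind default --seed 42 --out net.json
retmicro sweep --network net.json --out-dir out --m0 1,2,4 --config cfg.yaml
```

with `cfg.yaml` coarsening the tissue sampling to suit this network's
~1 cm extent:

```yaml
tissue_spacing_cm: 0.012
tissue_margin_cm: 0.03
tissue_thickness_cm: 0.024
max_element_len_cm: 0.004
```

The sweep prints (abridged):

```
 m0  capillary_upstream_po2_mean  capillary_downstream_po2_mean  smeta_capillary_upstream_mean  smeta_terminal_arteriole_sd
1.0                    69.306208                      35.223301                       0.045314                     0.002283
2.0                    67.318179                      24.920675                       0.057594                     0.002791
4.0                    62.108536                      11.640330                       0.088789                     0.005348
```

Reading the numbers: as oxygen demand M₀ rises from 1 to 4 cm³O₂/100cm³/min,
PO₂ at the upstream end of the capillaries stays comparatively high
(69 → 62 mmHg — most extraction happens downstream) while the
capillary-outflow PO₂ collapses (35 → 12 mmHg), so oxygen extraction per
capillary grows.  The mean conducted metabolic signal rises with demand and,
importantly, its spread across pathways (last column) roughly doubles —
different regions of the same network experience very different metabolic
states at high demand.  Per-run directories additionally contain `flow.csv`,
`tissue_po2.csv` (plus optional legacy-VTK export), `capillary_po2.csv`,
`compartments.csv`, `smeta.csv` and `summary.json`.

The same pipeline is available as a library:

```python
from retmicro import SimConfig, demand_sweep
from retmicro.fixtures import default_network

cfg = SimConfig(tissue_spacing_cm=0.012, tissue_margin_cm=0.03,
                tissue_thickness_cm=0.024, max_element_len_cm=0.004)
table = demand_sweep(cfg, default_network(seed=42), (1.0, 2.0, 4.0))
```

## Further reading

`docs/methods.md` documents the numerical schemes, parameter choices, the
synthetic-network generator and known limitations.
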