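# Methods

This note records the model equations as implemented, the numerical schemes,
the parameter defaults with their rationale, what the synthetic network
generator does and does not emulate, and known limitations.

## 1. Scope and units

The package models the steady state of the retinal microcirculation: a
heterogeneous arteriolar tree resolved vessel-by-vessel, coupled in series —
per terminal arteriole — to lumped capillary (C), small-venule (SV) and
large-venule (LV) compartments.  Flow regulation (diameter adaptation in
response to the computed signals) is deliberately out of scope: the pipeline
runs each stage exactly once, ending with the conducted metabolic signal.

All internal arithmetic is CGS (`src/retmicro/units.py`); interfaces use
mmHg, µm, cP and the conventional demand unit cm³O₂/100 cm³/min
(1 mmHg = 1333.22 dyn/cm²; M₀ → CGS factor 1/6000).

## 2. Hemodynamics

Poiseuille conductances with the Pries et al. *in-vivo* apparent-viscosity
law (relative viscosity as a function of luminal diameter in µm and
discharge hematocrit, times plasma viscosity).  Fixed-point outer loop:

1. sparse linear solve of nodal mass conservation (inlet and all terminal
   nodes Dirichlet);
2. one topological downstream pass of discharge hematocrit using the
   empirical phase-separation law at diverging bifurcations (logit form;
   daughter-diameter asymmetry term −13.29·[(D₁²−D₂²)/(D₁²+D₂²)]·(1−H)/D,
   slope 1+6.98(1−H)/D, cutoff X₀ = 0.964(1−H)/D; hematocrits clamped to
   [0,1] with red-cell-flux rebalance);
3. viscosity update, under-relaxed by 0.5;

until the maximum relative flow change is below 1e−6 (max 100 iterations).
After convergence one extra hematocrit pass is made so the reported
hematocrits partition the final flows; junction red-cell-flux closure is
then at solver round-off (~1e−12 relative).  Inlet discharge hematocrit
0.40 and plasma viscosity 1.0 cP are the control-state defaults; this pair
reproduces the reference compartment viscosities 9.05 / 2.28 / 2.39 cP at
6 / 29.5 / 137.3 µm to ±0.01 cP (asserted in the test suite).

Junctions with more than two daughters (the inlet node feeding the main
branches) distribute hematocrit uniformly — exact for the inlet, where no
parent vessel exists.

## 3. Green's-function oxygen transport (arterioles)

Governing tissue equation `K ∇²P = M(P)`, `K = D_diff·α = 6×10⁻¹⁰
cm³O₂/cm/s/mmHg`, Michaelis–Menten `M = M₀P/(P₀+P)`, `P₀ = 10 mmHg`.

**Discretization.** Vessel segments are cut into axial line elements
(≤ 25 µm by default) carrying uniform source strength; the potential of a
finite uniform line is used exactly (`asinh` form), with the radial offset
floored at the source radius so that evaluation points inside a vessel see
its wall value; an element's self-term is its own line potential at its
wall radius.  Tissue sample points represent volume cells; cell–cell
interactions use the point kernel floored at the volume-equivalent sphere
radius, and the self-term is the volume-averaged potential of a uniform
sphere (1.2/a scaling).  The default tissue sampling is a regular slab
(40 µm spacing, 200 µm thickness, 200 µm margins) around the network —
configurable, and intended to be coarsened for centimeter-scale networks
(the solver refuses > 8000 points, where the dense kernel matrices stop
being practical).

**Free-space kernel and closure.** The superposition uses the free-space
kernel `1/(4πK r)` plus an additive constant, with the closure constraint
that total vessel efflux equals total tissue consumption (Σq = Σφ).  For a
balanced source/sink system the far field then carries no net flux, and the
no-consumption limit correctly returns q ≡ 0 with tissue PO₂ equal to the
inflow value.  No bounded-domain boundary correction is applied; the
sampled tissue slab *is* the consuming region and diffusion formally
extends beyond it.  The verification oracle (an axisymmetric finite-
difference solution with consumption confined to the sampled annulus and
diffusion in a 4× larger surrounding region) discretizes the same continuum
problem; agreement is within 1.5 % on the single-vessel instance, and the
5 % bound is asserted in the tests.

**Intravascular coupling.** Along each vessel `df/ds = −q(s)` with
`f = Q(H_D C₀ S(P_b) + α_b P_b)`; at junctions blood PO₂ is continuous,
which together with red-cell-flux conservation conserves total oxygen flux
exactly.  The wall condition equates the superposed potential at each
element's wall with its blood PO₂ (intravascular transport resistance
neglected).

**Iteration.** A plain Picard alternation of (strength solve | marching |
tissue update) is unstable — the tissue-sink feedback and the wall/
convection feedback each overshoot, producing period-2 cycles.  The solver
therefore (i) linearizes the convective response *inside* the strength
solve using an upstream-influence matrix (the sensitivity of every
element's mid-point flux to every upstream element's efflux, with flow-
fraction scaling across junctions), and (ii) solves the tissue
superposition implicitly with the Michaelis–Menten sink linearized about
the current tissue PO₂ (dense solve below 800 points, GMRES with dense
mat-vec above).  Sweeps start undamped; if the residual stalls the
relaxation factor is halved.  Convergence: max change in tissue and blood
PO₂ below 1e−3 mmHg (default), max 200 sweeps.  Typical: 25–70 sweeps.
Tissue PO₂ is clamped at zero (anoxic regions are admissible; the
Michaelis–Menten sink vanishes there).

**Known artifact.** On coarse tissue grids (≳100 µm spacing) a small
fraction of near-vessel sample points can *rise* slightly (≲ 2 mmHg) as
demand increases, because growing element strengths are balanced against
coarse sink lumps; the continuum solution is monotone, and the pointwise
monotonicity test is run on a fine-resolved instance while coarse-grid
sweeps are checked distributionally.

## 4. Compartment chains and the control state

Per classified pathway (terminal segment = SA; the most upstream vessel
supplies D_LA, L_LA and Q_LA):

* `Q_C = π τ_C D_C³ / (32 μ_C)` with τ_C = 15 dyn/cm², D_C = 6 µm and μ_C
  from the viscosity law at the pathway hematocrit;
* counts `n_SV = 1`, `n_LV = Q_SA/Q_LA`, `n_C = Q_SA/Q_C` (fractional
  counts allowed — compartments are continuum descriptions);
* lengths `L_SV = L_SA`, `L_LV = L_LA`; venular diameters
  `D_SV = D_SA (ω_SA/ω_SV)^{1/3}`, `D_LV = D_LA (ω_LA/ω_LV)^{1/3}`;
* venular pressure drops by Poiseuille, computed first; the capillary drop
  is the residual `ΔP_C = (P_a − IOP) − ΔP_arterioles − ΔP_SV − ΔP_LV`
  (P_a = 40, IOP = 15; a non-positive residual raises an
  infeasible-control-state error rather than being clamped); the capillary
  length then follows from Poiseuille.

**Wall shear-rate table.** Venular ω values are interpolated at reference
diameters 69 µm (SV) and 140 µm (LV).  The published tabulation behind
these interpolations is not reproduced here; the package ships a synthetic
monotone table whose venular rows (684 s⁻¹ at 69 µm, 615 s⁻¹ at 140 µm)
are fixed by the control-state compartment shear stresses and viscosities
(τ = ω·μ gives 15.6 and 14.7 dyn/cm²), and whose arteriolar row at 22 µm
(1650 s⁻¹) makes a 22 µm terminal arteriole map to the reference 29.5 µm
mean small-venule diameter.  Diameters above the tabulated range take the
edge value (shear rates are nearly constant at large calibers); below the
range is an error.  The table is a config field (`shear_rate_table`) and
should be overridden when better data are available.

**Tissue annulus width.** With capillary density N = 50,000/cm² and an
arteriolar region volume A_VOL = 0.0025 cm³, the width d solves

    N = Σᵢ n_C,i L_C,i / (A_VOL + Σᵢ [n_C,i L_C,i π(r_C+d)² +
        n_SV,i L_SV,i π r_SV,i² + n_LV,i L_LV,i π r_LV,i²])

by bracketed root finding (the right side is strictly decreasing in d).
On the default synthetic network this yields d ≈ 20 µm.  Note N is
attainable only when the network carries enough pathways relative to
A_VOL; single-vessel demos need a proportionally lower density target.

## 5. Krogh extraction and axial marching

Radial two-point BVP `K (1/r)(r P′)′ = M(P)`, `P(r_v) = P_b`,
`P′(r_t) = 0`, solved by collocation (`scipy.integrate.solve_bvp`,
tolerance 1e−8) with the kinetics evaluated on the positive part of the
iterate; consumption per vessel length is `∫ M(P) 2πr dr`.  In the
zero-order limit (P ≫ P₀) the solution matches the classic Krogh annulus
closed form to < 1e−3 mmHg.  Because every capillary shares (D_C, d), the
consumption–vs–wall-PO₂ curve is precomputed once per demand level on a
PO₂ grid and monotonically interpolated (PCHIP); the axial march then
integrates `dP_b/ds = −q(P_b) / (Q dC/dP_b)` by fixed-step RK4 (200 steps
per capillary).  If PO₂ reaches zero it is clamped there for the rest of
the compartment and the clamp position recorded.  Venules exchange no
oxygen (tissue width zero): their PO₂ is constant.

The convective content keeps the dissolved term `α_b P_b` by default
(`include_dissolved`), consistent with the arteriolar flux expression; the
hemoglobin-bound-only variant is available as a switch.  α_b = 3.1×10⁻⁵
cm³O₂/cm³/mmHg and C₀ = 0.5 cm³O₂/cm³ are standard blood values.

Capillary inflow PO₂ is recovered from the flow-weighted oxygen content of
the feeding terminal arterioles (numerical inversion of the content
relation); with one terminal arteriole per pathway this is the identity.

## 6. Conducted metabolic signal

`S_loc = P₀/(P₀+PO₂)` pointwise; along a vessel, with x the upstream
distance from the outflow node,

    S(x) = S_out e^{−x/L₀} + ∫₀ˣ S_loc(y) e^{−(x−y)/L₀} dy,
    S_meta = (1/L)∫₀ᴸ S(x) dx,   S_up = S(L),    L₀ = 1 cm.

The sampled S_loc profile is treated as piecewise linear and both
integrals are evaluated exactly interval-by-interval (exponential
integrator), so the quadrature error is that of the sampling alone; the
closed forms for constant profiles are reproduced to machine precision.

Conduction order: LV (S_out = 0) → SV → C → terminal arteriole → upstream
through the tree in reverse-topological order.  At converging junctions
the parent's S_out is the **sum** of the daughters' upstream-end signals
(additive conduction, the default, consistent with conducted-response
models in which junction currents superpose); a flow-weighted average is
available via `signal_combination: flow_weighted` since the correct
combination rule in branched networks is not settled.  Arteriolar S_loc
uses the blood PO₂ at the Green's-function element midpoints.

## 7. Synthetic networks

The image-derived retinal arteriolar geometries behind the original human
extrapolation are not publicly deposited, so the generator emulates their
gross statistics: four main branches leaving the inlet (default angles at
the quadrant diagonals, configurable since the fovea-referenced branch
angles are not tabulated), recursive symmetric bifurcation, Murray-law
calibers (`D_pᵏ = ΣD_dᵏ`, k = 3), uniform terminal-arteriole diameters,
and log-normal length jitter (σ = 0.2 by default) at a fixed
length-to-diameter ratio of 30.  The default terminal diameter is 22 µm —
a murine ~6 µm terminal arteriole carried through the 3.6× mouse→human
diameter scaling; the mouse→human conversion itself is available as
`scale_mouse_to_human` (diameters ×3.6, lengths and coordinates ×5.9).

What the generator does **not** emulate: asymmetric branching (daughter
flows differ only through length jitter, so hematocrit heterogeneity is
mild), tortuosity/curvature (segments are straight), real branch-angle
statistics, and the observed broad distribution of pathway depths.
Consequently, passing demand-sweep tests demonstrates the qualitative
whole-network patterns (monotone PO₂ decline, rising signal mean and
spread) but not quantitative agreement with any specific imaged retina.

Hand-built toy networks (`single`, `y_split`, `two_level`, `four_branch`)
carry analytically known flow splits and are used throughout the tests; a
128-terminal "human-scale" emulation exercises structural and hemodynamic
(not oxygen) stages.

## 8. Problem sizes and determinism

Whole-pipeline tests and the worked example use 120 µm tissue spacing,
240 µm slab thickness and 40 µm vessel elements on the 16-terminal default
network — a three-level demand sweep then takes on the order of a minute
on one core, with the Green's stage dominating.  The production defaults
(40 µm spacing, 25 µm elements) resolve small (few-junction) networks
finely and are meant to be coarsened for larger trees.  Every random
choice flows from an explicit integer seed (NumPy `default_rng`); repeated
runs are byte-identical, which the tests assert on the CSV/JSON outputs.

## 9. Limitations

* Venules are lumped per pathway: no intra-venular PO₂ or signal
  variation downstream of a terminal arteriole.
* Single superficial vascular layer; no intermediate/deep capillary
  plexus geometry.
* Free-space Green's kernel without bounded-domain corrections (error
  quantified against the finite-difference oracle on the instance tested).
* No flow regulation: signals are computed, not acted upon.
* The phase-separation and viscosity laws are empirical fits from
  non-retinal microvascular beds, as is standard practice.
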