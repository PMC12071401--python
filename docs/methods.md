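# Methods

`crumbsim` simulates bread baking in a cylindrical mold as a three-phase
continuum: a starch–protein solid network, liquid water bound in that
matrix, and a pore gas of water vapor and CO₂.  The model couples heat
transfer, multiphase moisture transport and large viscous deformation, with
moisture phase change (MPC) as the link between all three.

## Model

**Conserved fields.** Apparent (per-bread-volume) densities ρ̄ₛ, ρ̄ₗ, ρ̄ᵥ,
ρ̄_CO₂ and temperature T on an axisymmetric grid.  Volume fractions follow
from the intrinsic densities (ρₛ = 1500, ρₗ = 1000 kg/m³); porosity is the
gas fraction f_vg = 1 − f_vs − f_vl.

**Moisture phase change.** Vapor in the pores relaxes toward the sorption
equilibrium C_v → a_w C_sat(T) at a rate k_MPC, with the Oswin-type
isotherm 100 W = A (a_w/(1−a_w))^B (A = 15.64 − 0.1 T_C,
B = 0.38 + 1.69·10⁻³ T_C) and a Magnus saturation law
P_sat = 610.78 exp(17.2694 (T−273.15)/(T−35.86)) Pa, pinned by
P_sat(100 °C) ≈ 1 atm.  The rate constant blends the two pore states,
k_MPC = α k_open + (1−α) k_closed with k_closed = 10 s⁻¹ (equilibrium,
closed pores) and the fitted k_open = 0.8 s⁻¹ (nonequilibrium, open pores).
The liquid source is written m˙ₗ = k_MPC f_vg M_H₂O (C_v − a_w C_sat):
positive for condensation (liquid gain, latent heat release).  The printed
source equation carries the opposite sign, which is inconsistent with its
own liquid/vapor bookkeeping and with the reported condensation-front
heating; the sign adopted here satisfies the global water budget and both
front phenomenologies.  The literal reading remains available
(`sign_convention="printed"`).

**Closed-pore transport (ECD).** While pores are closed, water still moves
by evaporation–condensation–diffusion: vapor evaporates on the hot pore
wall, diffuses across the pore, condenses on the cold wall.  The net liquid
flux is j_ECD = −(1−α) f_vg D_v (a_w/RT) dP_sat/dT ∇T and the latent heat
it carries appears as an equivalent conductivity
λ_EDC = f_vg D_v a_w L_v/(RT) dP_sat/dT, so λ_EDC ∇T = −j_ECD L_v
identically (a unit-tested identity).  The total conductivity is the
parallel mixture plus the closed-pore gated EDC term,
λ_eff = Σ f_i λ_i + (1−α) λ_EDC f_vg, exactly as printed (note this
carries f_vg twice — once inside λ_EDC, once outside; the mass flux uses
the single-f_vg form).  The ECD pathway is gated by (1−α): the printed flux
equations show a bare α although the mechanism is a closed-pore one and the
conductivity blend gates it with (1−α); the internal-consistency tests pin
the (1−α) reading.

**Pore state functions.** Pore opening α(T), crusting β(T) and the dough
viscosity μ(T) are quintic smoothsteps (log-space for μ) saturating exactly
at their band edges: α rises 0→1 over T_open ± ΔT_open/2 (fitted 76 ± 5 °C),
β falls 1→0.1 across T_c = 100 °C (band width 5 °C, a design choice: the
source only states the limits), μ rises 10⁴→4.5·10⁶ Pa·s over
T_tra ± ΔT_tra/2 (fitted 80 ± 30 °C).  Permeability is
κ_g = κ₀ α β f_vg^1.34 with κ₀ = 8.77·10⁻¹¹ m².

**CO₂ generation.** The release correlation (linear below 40 °C, clamped at
its ~20 °C root; Gaussian decay above as the yeast dies) is interpreted as
a molar rate, mol CO₂ per kg dry solid per second, giving the mass source
m˙_CO₂ = ρ̄ₛ k_CO₂ f_vg M_CO₂.  The source study prints no units; the mass
reading (kg/(kg·s)) would imply hundreds of grams of CO₂ per kilogram of
flour per hour — far beyond any fermentation — and, in simulation, drives
the dough to the mold rim while making CO₂ dominate the closed-pore gas,
contradicting the reported vapor-dominated composition.  The molar reading
(~0.36 mol/kg/h peak) is the only self-consistent magnitude.

**Mechanics.** The dough is a creeping, weakly compressible Newtonian fluid
(inertia is ~10 orders below the viscous terms at μ ≥ 10⁴ Pa·s and
centimetre scale).  Inside the mold the admissible motion is vertical
column stretching (no-slip bottom, frictionless side with zero normal
velocity), so each cell obeys the implicit quasi-static balance
μ_eff (s−1)/Δt = P_g(s) − P_ref with P_g(s) the ideal-gas pore pressure
after the incompressible matrix donates the volume change to the gas, and
P_ref the ambient plus (optionally) the overburden weight.  Solved by
per-cell bisection, this is unconditionally stable — the local
pressure–strain relaxation time μ f_vg/P_g ≈ 10 ms is far below any
transport step — and reduces to div v = (P_g − P_ref)/μ_eff in the
solidified limit.  Two closures are provided: `pressure_driven` (default,
above) and `prescribed_divergence` (volumetric rate imposed from the
ideal-gas volume imbalance); the source study solves the coupling
monolithically in commercial FEM and states no explicit equation of state,
so the two closures bracket the plausible readings.

*Open-pore backfill.* The species set contains no inert air, so nothing in
the printed model can restore pressure in a surface-connected pore whose
own gas has been flushed or condensed away; such cells would implode under
up to a bar of spurious suction.  Physically, oven air wicks into any
partially interconnected network at ambient pressure.  This is represented
as a pressure floor max(P_g, P_amb) for every cell with α > 0 in the
mechanical balance; over-pressure is still relieved only by viscous
expansion and Darcy venting.

**Gas flow.** Darcy velocity u = −(κ_g/μ_g)∇P_g by default (dominant
balance of the pore-gas momentum equation at κ ~ 10⁻¹¹ m², u ~ mm/s); a
Brinkman option retains the gas shear term.  Closed regions are stagnant
(κ_g = 0).

**Boundaries.** Free top surface: natural convection (h_c ≈ 10 W/m²K),
gray radiation ε(Φ − σT⁴) with ε = 0.9 and effective radiation density
Φ = 1000 W/m², evaporative cooling, and α-gated species exchange (liquid
evaporation (1−α) h_m M (a_w C_sat − C_oven,v) while the surface is closed,
convective vapor/CO₂ exchange plus a Darcy outlet once open).  Mass
coefficients follow the heat–mass analogy h_m = h_c/(ρ c_p Le^{2/3}).
Mold bottom and side: contact conduction q = h_e (T_w − T), h_e = 100
W/m²K, no mass transfer.

**Oven model.** The measured oven traces are not tabulated, so a synthetic
generator stands in: air temperature = setpoint (453.15 K) plus a seeded
triangular relay oscillation (intermittent heating); the mold wall is
either a first-order lag trace or, by default, a lumped glass-wall node per
mold face whose oven-side supply (convection h_out ≈ 12 W/m²K plus cavity
radiation) balances the h_e draw by the dough.  The coupled node matters:
a prescribed hot wall would deliver several times more heat than the oven
can resupply to a thin glass mold; with the balance, the wall plateaus near
390–420 K against a 100 °C dough, consistent with a borosilicate mold
(areal heat capacity ≈ 7500 J/m²K, warm-up constant ≈ 300 s).

## Numerics

Finite volumes, cell-centred, on a column-Lagrangian axisymmetric grid:
fixed annular rings in r, material cells in z that stretch with the dough
(mesh motion conserves every species mass to machine precision; solid mass
is conserved identically).  Operator splitting per step: (1) mechanics +
mesh motion, (2) CO₂ source, (3) local MPC relaxation (exact exponential
integration; stiff at k = 10 s⁻¹), (4) explicit conservative liquid fluxes
(Fickian + ECD, positivity-limited), (5) implicit vapor/CO₂ pore diffusion,
(6) implicit Darcy pressure solve with implicit upwind species advection
(an M-matrix: positivity-preserving and exactly conservative even for
through-fluxes exceeding a cell's inventory, as in steady venting through
thin crust cells), (7) implicit heat conduction with Robin boundaries
(radiation and evaporative cooling explicit).  Interface coefficients are
harmonic means, which makes α-gated coefficients vanish correctly at
open/closed interfaces; advection is upwinded (monotone at the fronts).
Adaptive Δt bounds the per-step volume strain (2%) and temperature change;
steps are rejected and halved on corruption.  Default meshes: 1-D axial
20 cells; 2-D coarse 5×16 to 7×24; optional geometric boundary-layer
grading to 0.1 mm.  A full 1800 s bake takes ~15 s (1-D) to ~30 s (2-D
level 2) on one CPU.

Degenerate inputs: dried cells clamp W at 10⁻⁴ for the sorption isotherm;
the strain rate tapers to zero as either the gas or the matrix fraction
approaches exhaustion; columns freeze at the mold rim; both partial
pressures zero is a rejected gas state.

## Synthetic data and what the tests show

The only synthetic ingredient is the oven program; everything else is the
stated scenario (radius 50 mm, height 20 mm, T₀ = 28 °C, W₀ = 0.82,
ρ_eff,0 = 1069 kg/m³, 1800 s).  The generator reproduces the *described*
features of the measured traces (setpoint, intermittent oscillation, lagged
mold wall) but not their actual waveforms, which were never published.
Consequently the tests demonstrate internal correctness (budgets,
identities, limits, directional parameter responses) and
order-of-magnitude agreement of the headline diagnostics — not a trace-level
replication of the experiment.

## Known limitations

- **No inert air species.**  The gas phase is vapor + CO₂ only, as in the
  printed model; the ambient backfill floor is the minimal closure that
  keeps open crust cells from imploding.  Diagnosed pore pressures in
  flushed open regions can sit below ambient even though the mechanics
  treats them as ambient-filled.
- **Closed-pore vapor fraction is bounded.**  With the pore gas initialised
  at ambient (vapor at sorption equilibrium, remainder CO₂) and gauge
  pressures of order 1 kPa, the vapor molar fraction of a closed cell
  cannot exceed a_w P_sat(81 °C)/P_amb ≈ 0.48 while its CO₂ remains; high
  closed-region vapor fractions arise here only in transition cells whose
  CO₂ has partially drained.  A reported 80% within the first 100 s of a
  bake starting at 28 °C is unreachable under the printed sorption and
  saturation laws regardless of parameter choices.
- **Expansion magnitude inherits the CO₂-source ambiguity.**  Under the
  molar reading the simulated rise is smaller than the reported one; the
  mass reading overshoots to the mold rim.  No printed unit choice
  reproduces both the deformation record and the closed-pore gas
  composition.
- **Crumb re-wetting overshoots.**  The condensation front raises the local
  dry-basis moisture above the reported peak because the near-surface crumb
  under the crust stays a few kelvin cooler than the interior and traps
  part of the vapor stream.
- Constant thermophysical properties, Newtonian temperature-sigmoid
  rheology, no browning/color kinetics, no 3-D effects, dough confined to
  the mold radius.
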