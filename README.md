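# crumbsim

Coupled heat/mass-transfer and large-deformation simulation of bread baking.

Bread is a three-phase porous medium: a starch–protein solid network,
liquid water bound in it, and pores filled with water vapor and CO₂.
During baking, moisture phase change (MPC) couples everything: evaporation
and condensation move water and latent heat through the crumb, vapor and
CO₂ pressurise the closed pores and inflate the dough, and the pore walls
rupture around 71–81 °C, after which gas vents, the dough solidifies and a
crust forms.  `crumbsim` implements this coupled model as a finite-volume
simulator for a cylindrical dough in a mold inside a domestic oven, for
food-process modellers who want to probe how MPC controls baking rather
than fit a lumped empirical curve.

## Model core

Per-phase mass conservation on apparent densities ρ̄ᵢ with a deforming
(column-Lagrangian) mesh:

- solid:   ∂ρ̄ₛ/∂t + ∇·(ρ̄ₛ**v**) = 0
- liquid:  ∂ρ̄ₗ/∂t + ∇·(ρ̄ₗ**v** + **j**ₗ) = ṁₗ, with
  **j**ₗ = −ρ̄ₛ Dₗ∇W − (1−α) f_vg D_v (a_w/RT)(dP_sat/dT)∇T
  (Fickian diffusion + closed-pore evaporation–condensation–diffusion)
- vapor / CO₂: convection by the Darcy velocity
  **u** = −(κ_g/μ_g)∇P_g, open-pore diffusion, source ∓ṁₗ and the CO₂
  generation term ρ̄ₛ k_CO₂ f_vg M_CO₂
- energy: (ρc_p)_eff ∂T/∂t + gas enthalpy advection =
  ∇·(λ_eff∇T) + ṁₗ L_v, with
  λ_eff = Σ f_i λ_i + (1−α) λ_EDC f_vg and
  λ_EDC = f_vg D_v a_w L_v/(RT) dP_sat/dT
- phase change: ṁₗ = k_MPC f_vg M_H₂O (C_v − a_w C_sat),
  k_MPC = α k_open + (1−α) k_closed (equilibrium in closed pores,
  k_closed = 10 s⁻¹; nonequilibrium in open pores, fitted
  k_open = 0.8 s⁻¹)
- mechanics: creeping weakly compressible viscous flow; each cell obeys
  μ_eff ∇·**v** = P_g − P_ref, with the dough viscosity rising
  sigmoidally from 10⁴ to 4.5×10⁶ Pa·s as it solidifies.

Pore opening α(T), crusting β(T) and viscosity μ(T) are smoothstep state
functions with the fitted transitions T_open = 76 ± 5 °C and
T_tra = 80 ± 30 °C; permeability is κ_g = κ₀ α β f_vg^1.34.  See
`docs/methods.md` for assumptions, parameter provenance and limitations.

## Worked example

```python
from crumbsim.scenario import run_paper_scenario

rep = run_paper_scenario(mode="axial1d", mesh_level=1)
for key in ("max_axis_height_mm", "liquid_loss_g", "peak_P1_gauge_Pa",
            "peak_P1_time_s", "final_volume_ratio", "max_edc_share"):
    print(key, round(rep["summary"][key], 2))
```

prints (default scenario: 100 mm mold, 20 mm dough at 28 °C, W₀ = 0.82,
ρ₀ = 1069 kg/m³, 180 °C oven, 1800 s):

```
max_axis_height_mm 28.03
liquid_loss_g 4.22
peak_P1_gauge_Pa 1782.79
peak_P1_time_s 790.05
final_volume_ratio 1.4
max_edc_share 0.96
```

Reading: the dough rises from 20 to ~28 mm as closed-pore gas expands,
driven by a gauge pressure that peaks at ~1.8 kPa around 790 s and
collapses when the pores open; ~4 g of water leaves through the top
surface; and in the still-closed crumb the evaporation–condensation
vapor shuttle contributes up to 96% of the effective thermal conductivity
— closed-pore heat transfer is dominated by moisture phase change, not
conduction.

The same scenario runs from the shell:

```sh
crumbsim run --mode axisym2d --mesh-level 1 --out bake_out
crumbsim sweep T_open 343.15 349.15 355.15 --mode axial1d
crumbsim props dough_viscosity --grid 40:120:9
```

`crumbsim run` writes tidy diagnostics (`diagnostics.csv`), field
snapshots (legacy VTK in 2-D, CSV in 1-D), the oven program and a
`summary.json`.

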