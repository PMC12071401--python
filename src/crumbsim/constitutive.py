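"""Constitutive closures for the multiphase bread-baking model.

Pure, vectorised algebraic functions: sorption/water activity, saturation
properties, latent heat, diffusivities, CO2 generation, the three sigmoid
state functions (pore opening ``alpha``, crusting ``beta``, dough viscosity
``mu``), the moisture-phase-change (MPC) source, the closed-pore
evaporation-condensation-diffusion (ECD) flux and its equivalent thermal
conductivity, effective conductivity, permeability and ideal-gas mixture
properties.

Temperatures are kelvin everywhere at the API surface; correlations that are
written in Celsius (water activity, CO2 generation) convert internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np

__all__ = [
    "MaterialParams",
    "water_activity",
    "saturation_pressure",
    "saturation_pressure_slope",
    "saturation_concentration",
    "latent_heat",
    "liquid_diffusivity",
    "gas_effective_diffusivity",
    "co2_generation_rate",
    "smoothstep",
    "pore_open_fraction",
    "crust_function",
    "dough_viscosity",
    "mpc_rate",
    "phase_change_source",
    "ecd_flux",
    "lambda_edc",
    "effective_conductivity",
    "permeability",
    "gas_density",
]

T_ZERO_C = 273.15
STEFAN_BOLTZMANN = 5.670374419e-8  # W/(m^2 K^4)

#: provenance tag for every MaterialParams field: value printed in the source
#: study ("paper"), calibrated there ("fitted"), or a standard literature value
#: filling a gap ("literature").
PROVENANCE = {
    "rho_s": "paper", "rho_l": "paper", "cp_g": "paper", "cp_l": "paper",
    "cp_s": "literature", "Lv_ref": "paper", "T0": "paper",
    "mu_l_dough": "paper", "mu_s_dough": "paper", "mu_g": "paper",
    "kappa0": "paper", "T_open": "fitted", "dT_open": "fitted",
    "T_tra": "fitted", "dT_tra": "fitted", "T_c": "paper",
    "dT_crust": "literature", "k_mpc_open": "fitted", "k_mpc_closed": "paper",
    "emissivity": "paper", "lambda_s": "literature", "lambda_l": "literature",
    "lambda_g": "literature", "D_v_ref": "literature",
    "D_co2_ref": "literature", "M_h2o": "literature", "M_co2": "literature",
    "R": "paper", "P_amb": "paper", "g": "paper",
    "psat_prefactor": "literature", "psat_coeff": "literature",
}


@dataclass
class MaterialParams:
    """Material constants of the dough/bread system (SI units).

    Defaults are the baseline parameter set of the calibrated baking
    scenario; transition temperatures/widths are the fitted values
    (T_open = 76 C, dT_open = 10 C, T_tra = 80 C, dT_tra = 60 C,
    k_MPC,open = 0.8 1/s).
    """

    rho_s: float = 1500.0          # intrinsic solid density, kg/m^3
    rho_l: float = 1000.0          # liquid water density, kg/m^3
    cp_g: float = 2030.0           # vapor specific heat, J/(kg K)
    cp_l: float = 4180.0           # liquid specific heat, J/(kg K)
    cp_s: float = 1800.0           # dry-solid specific heat, J/(kg K)
    Lv_ref: float = 2.454e6        # latent heat at T0, J/kg
    T0: float = 301.15             # reference/initial temperature, K (28 C)
    mu_l_dough: float = 1.0e4      # fluid-like dough viscosity, Pa s
    mu_s_dough: float = 4.5e6      # solid-like dough viscosity, Pa s
    mu_g: float = 1.8e-5           # gas viscosity, Pa s
    kappa0: float = 8.77e-11       # reference permeability, m^2
    T_open: float = 76.0 + T_ZERO_C   # pore-opening midpoint, K
    dT_open: float = 10.0          # pore-opening band width, K
    T_tra: float = 80.0 + T_ZERO_C    # viscosity transition midpoint, K
    dT_tra: float = 60.0           # viscosity transition band width, K
    T_c: float = 100.0 + T_ZERO_C     # crusting temperature, K
    dT_crust: float = 5.0          # crusting band width, K
    k_mpc_open: float = 0.8        # open-pore MPC rate constant, 1/s
    k_mpc_closed: float = 10.0     # closed-pore MPC rate constant, 1/s
    emissivity: float = 0.9        # bread surface emissivity
    lambda_s: float = 0.20         # solid conductivity, W/(m K)
    lambda_l: float = 0.60         # liquid conductivity, W/(m K)
    lambda_g: float = 0.026        # gas conductivity, W/(m K)
    D_v_ref: float = 2.6e-5        # binary vapor diffusivity, m^2/s
    D_co2_ref: float = 1.6e-5      # binary CO2 diffusivity, m^2/s
    M_h2o: float = 0.018           # kg/mol
    M_co2: float = 0.044           # kg/mol
    R: float = 8.314               # J/(mol K)
    P_amb: float = 101325.0        # Pa
    g: float = 9.8                 # m/s^2
    # Magnus saturation-pressure coefficients (configurable so the literal
    # printed prefactor variant can be selected).
    psat_prefactor: float = 610.78
    psat_coeff: float = 17.2694
    provenance: dict = field(default_factory=lambda: dict(PROVENANCE))

    def __post_init__(self) -> None:
        positive = [
            "rho_s", "rho_l", "cp_g", "cp_l", "cp_s", "Lv_ref",
            "mu_l_dough", "mu_s_dough", "mu_g", "kappa0", "dT_open",
            "dT_tra", "dT_crust", "lambda_s", "lambda_l", "lambda_g",
            "D_v_ref", "D_co2_ref", "M_h2o", "M_co2", "R", "P_amb",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"MaterialParams.{name} must be > 0")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("emissivity must be in (0, 1]")
        if not self.k_mpc_open < self.k_mpc_closed:
            raise ValueError("k_mpc_open must be < k_mpc_closed")

    def replace(self, **kwargs) -> "MaterialParams":
        vals = {f.name: getattr(self, f.name) for f in _dc_fields(self)}
        vals.update(kwargs)
        return MaterialParams(**vals)


# ---------------------------------------------------------------------------
# sorption and saturation properties
# ---------------------------------------------------------------------------

def water_activity(W, T):
    """Water activity a_w from the Oswin-type sorption isotherm.

    The isotherm 100 W = A (a_w/(1-a_w))**B with A = 15.64 - 0.1 Tc and
    B = 0.38 + 1.69e-3 Tc (Tc in Celsius) is inverted in closed form:
    x = (100 W / A)**(1/B), a_w = x/(1+x).

    Parameters
    ----------
    W : dry-basis moisture (kg water / kg dry solid), > 0.
    T : temperature, K, in [273.15, 423.15].
    """
    W = np.asarray(W, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(W <= 0):
        raise ValueError("water_activity: W must be > 0")
    if np.any((T < T_ZERO_C) | (T > 423.15)):
        raise ValueError("water_activity: T outside supported range "
                         "[273.15, 423.15] K")
    Tc = T - T_ZERO_C
    A = 15.64 - 0.1 * Tc
    B = 0.38 + 1.69e-3 * Tc
    x = (100.0 * W / A) ** (1.0 / B)
    return x / (1.0 + x)


def saturation_pressure(T, params: MaterialParams | None = None):
    """Saturation vapor pressure of water, Pa (Magnus form).

    P_sat = c0 * exp(c1 (T - 273.15)/(T - 35.86)); with the default
    coefficients P_sat(373.15 K) is within 1% of one atmosphere.
    """
    p = params or _DEFAULT
    T = np.asarray(T, dtype=float)
    if np.any(T <= T_ZERO_C):
        raise ValueError("saturation_pressure: T must be > 273.15 K")
    return p.psat_prefactor * np.exp(p.psat_coeff * (T - T_ZERO_C) / (T - 35.86))


def saturation_pressure_slope(T, params: MaterialParams | None = None):
    """Analytic dP_sat/dT, Pa/K (chain rule on the Magnus exponent)."""
    p = params or _DEFAULT
    T = np.asarray(T, dtype=float)
    return (saturation_pressure(T, p)
            * p.psat_coeff * (T_ZERO_C - 35.86) / (T - 35.86) ** 2)


def saturation_concentration(T, params: MaterialParams | None = None):
    """Molar saturation concentration C_sat = P_sat/(R T), mol/m^3."""
    p = params or _DEFAULT
    return saturation_pressure(T, p) / (p.R * np.asarray(T, dtype=float))


def latent_heat(T, params: MaterialParams | None = None):
    """Latent heat of vaporisation L_v = Lv_ref + (cp_g - cp_l)(T - T0), J/kg."""
    p = params or _DEFAULT
    return p.Lv_ref + (p.cp_g - p.cp_l) * (np.asarray(T, dtype=float) - p.T0)


# ---------------------------------------------------------------------------
# diffusivities and sources
# ---------------------------------------------------------------------------

def liquid_diffusivity(W, eps_g):
    """Liquid-water diffusivity D_l = 1e-9 eps_g exp(-10 + 10 W), m^2/s."""
    W = np.asarray(W, dtype=float)
    eps_g = np.asarray(eps_g, dtype=float)
    if np.any((eps_g < 0) | (eps_g > 1)):
        raise ValueError("liquid_diffusivity: eps_g must be in [0, 1]")
    return 1e-9 * eps_g * np.exp(-10.0 + 10.0 * W)


def gas_effective_diffusivity(D_ref, eps_g):
    """Bruggeman-type effective gas diffusivity D_ref * eps_g**(4/3)."""
    eps_g = np.asarray(eps_g, dtype=float)
    if np.any((eps_g < 0) | (eps_g > 1)):
        raise ValueError("gas_effective_diffusivity: eps_g must be in [0, 1]")
    return D_ref * eps_g ** (4.0 / 3.0)


def co2_generation_rate(T):
    """Yeast/dissolved CO2 release rate per kg of dry solid per second.

    The correlation's output is interpreted as a molar rate (mol CO2/(kg s));
    the transport source term converts with M_CO2.

    Piecewise in Celsius: linear 5e-6 Tc - 9.98e-5 below 40 C (clamped at
    zero below its ~19.96 C root, where fermentation activity vanishes) and a
    Gaussian decay 1e-4 exp(-((Tc-40)/10)^2) above 40 C as the yeast dies
    off.  The two branches meet at 40 C within 0.2% (1.002e-4 vs 1.000e-4);
    the seam takes the upper-branch value.
    """
    Tc = np.asarray(T, dtype=float) - T_ZERO_C
    low = np.clip(5e-6 * Tc - 9.98e-5, 0.0, None)
    high = 1e-4 * np.exp(-(((Tc - 40.0) / 10.0) ** 2))
    return np.where(Tc < 40.0, low, high)


# ---------------------------------------------------------------------------
# sigmoid state functions
# ---------------------------------------------------------------------------

def smoothstep(x):
    """Quintic smoothstep: 0 for x<=0, 1 for x>=1, C^2 in between."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return np.clip(x * x * x * (x * (6.0 * x - 15.0) + 10.0), 0.0, 1.0)


def pore_open_fraction(T, params: MaterialParams | None = None):
    """Pore-opening function alpha(T) in [0, 1].

    Exactly 0 below T_open - dT_open/2 (closed pores), exactly 1 above
    T_open + dT_open/2 (fully open), quintic smoothstep in between with
    alpha(T_open) = 0.5.
    """
    p = params or _DEFAULT
    T = np.asarray(T, dtype=float)
    return smoothstep((T - (p.T_open - 0.5 * p.dT_open)) / p.dT_open)


def crust_function(T, params: MaterialParams | None = None):
    """Crusting function beta(T): 1 in the crumb, 0.1 in the crust.

    Drops from 1 to 0.1 over a band of width dT_crust centred on T_c
    (default 100 C, 5 K band)."""
    p = params or _DEFAULT
    T = np.asarray(T, dtype=float)
    s = smoothstep((T - (p.T_c - 0.5 * p.dT_crust)) / p.dT_crust)
    return 1.0 - 0.9 * s


def dough_viscosity(T, params: MaterialParams | None = None):
    """Effective dough viscosity, Pa s: log-space sigmoid from fluid-like
    mu_l at T_tra - dT_tra/2 to solid-like mu_s at T_tra + dT_tra/2."""
    p = params or _DEFAULT
    T = np.asarray(T, dtype=float)
    s = smoothstep((T - (p.T_tra - 0.5 * p.dT_tra)) / p.dT_tra)
    return np.exp(np.log(p.mu_l_dough)
                  + s * (np.log(p.mu_s_dough) - np.log(p.mu_l_dough)))


def mpc_rate(alpha, params: MaterialParams | None = None):
    """MPC rate constant k_MPC = alpha k_open + (1 - alpha) k_closed, 1/s."""
    p = params or _DEFAULT
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("mpc_rate: alpha must be in [0, 1]")
    return alpha * p.k_mpc_open + (1.0 - alpha) * p.k_mpc_closed


# ---------------------------------------------------------------------------
# phase change and ECD transport
# ---------------------------------------------------------------------------

def phase_change_source(T, W, C_v, f_vg, alpha,
                        params: MaterialParams | None = None,
                        sign_convention: str = "budget"):
    """Moisture-phase-change liquid source m_l, kg/(m^3 s).

    ``budget`` (default): m_l = k_MPC f_vg M_H2O (C_v - a_w C_sat) --
    positive where vapor is supersaturated (condensation, liquid gain, heat
    release), negative where the pore gas is undersaturated (evaporation).
    This is the reading consistent with the liquid/vapor mass bookkeeping
    and the evaporation/condensation-front phenomenology.  ``printed``
    flips the sign, matching the source equation as literally printed.
    Zero exactly at equilibrium C_v = a_w C_sat.
    """
    p = params or _DEFAULT
    k = mpc_rate(pore_open_fraction(T, p) if alpha is None
                 else np.asarray(alpha, dtype=float), p)
    a_w = water_activity(W, T)
    deficit = np.asarray(C_v, dtype=float) - a_w * saturation_concentration(T, p)
    m_l = k * np.asarray(f_vg, dtype=float) * p.M_h2o * deficit
    if sign_convention == "printed":
        return -m_l
    if sign_convention != "budget":
        raise ValueError("sign_convention must be 'budget' or 'printed'")
    return m_l


def ecd_flux(grad_T, T, W, f_vg, alpha, params: MaterialParams | None = None):
    """Closed-pore ECD liquid-water flux, kg/(m^2 s).

    j_ECD = -(1 - alpha) f_vg D_v (a_w/(R T)) dP_sat/dT * grad T.
    Vapor evaporates from the hot pore wall, diffuses across the pore and
    condenses on the cold wall; the net effect is a liquid flux down the
    temperature gradient, active only while pores are closed.  Vanishes in
    an isothermal field and for fully open pores.
    """
    p = params or _DEFAULT
    a_w = water_activity(W, T)
    coeff = (np.asarray(f_vg, dtype=float) * p.D_v_ref * a_w
             / (p.R * np.asarray(T, dtype=float))
             * saturation_pressure_slope(T, p))
    return -(1.0 - np.asarray(alpha, dtype=float)) * coeff * np.asarray(grad_T, dtype=float)


def lambda_edc(T, W, f_vg, params: MaterialParams | None = None):
    """Equivalent thermal conductivity of the ECD mechanism, W/(m K).

    lambda_EDC = f_vg D_v a_w L_v/(R T) dP_sat/dT: the latent heat carried
    by the closed-pore evaporation-condensation vapor shuttle, expressed as
    a conductivity so that lambda_EDC grad T = -j_ECD L_v.
    """
    p = params or _DEFAULT
    a_w = water_activity(W, T)
    return (np.asarray(f_vg, dtype=float) * p.D_v_ref * a_w * latent_heat(T, p)
            / (p.R * np.asarray(T, dtype=float))
            * saturation_pressure_slope(T, p))


def effective_conductivity(f_vs, f_vl, f_vg, T, W, alpha,
                           params: MaterialParams | None = None,
                           return_share: bool = False):
    """Total effective conductivity lambda_eff, W/(m K).

    Parallel mixture lambda_c = f_vs lambda_s + f_vl lambda_l + f_vg lambda_g
    plus the closed-pore EDC contribution (1 - alpha) lambda_EDC f_vg.
    With ``return_share`` also returns the EDC fraction of the total (the
    diagnostic plotted per region in the source study).
    """
    p = params or _DEFAULT
    f_vs = np.asarray(f_vs, dtype=float)
    f_vl = np.asarray(f_vl, dtype=float)
    f_vg = np.asarray(f_vg, dtype=float)
    if np.any(np.abs(f_vs + f_vl + f_vg - 1.0) > 1e-9):
        raise ValueError("effective_conductivity: volume fractions must sum to 1")
    lam_c = f_vs * p.lambda_s + f_vl * p.lambda_l + f_vg * p.lambda_g
    edc = (1.0 - np.asarray(alpha, dtype=float)) * lambda_edc(T, W, f_vg, p) * f_vg
    lam = lam_c + edc
    if return_share:
        return lam, edc / lam
    return lam


def permeability(f_vg, alpha, beta, params: MaterialParams | None = None):
    """Gas permeability kappa_g = kappa0 alpha beta f_vg**1.34, m^2.

    Zero while pores are closed (alpha = 0); reduced by an order of
    magnitude in the crust (beta = 0.1)."""
    p = params or _DEFAULT
    return (p.kappa0 * np.asarray(alpha, dtype=float)
            * np.asarray(beta, dtype=float)
            * np.asarray(f_vg, dtype=float) ** 1.34)


def gas_density(P_v, P_co2, T, params: MaterialParams | None = None,
                return_molar_mass: bool = False):
    """Ideal-gas mixture density rho_g = (P_v M_v + P_co2 M_co2)/(R T), kg/m^3.

    Optionally also returns the mole-fraction-weighted molar mass."""
    p = params or _DEFAULT
    P_v = np.asarray(P_v, dtype=float)
    P_co2 = np.asarray(P_co2, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(P_v < 0) or np.any(P_co2 < 0):
        raise ValueError("gas_density: partial pressures must be >= 0")
    P_g = P_v + P_co2
    if np.any(P_g <= 0):
        raise ValueError("gas_density: degenerate mixture (P_v + P_co2 = 0)")
    rho = (P_v * p.M_h2o + P_co2 * p.M_co2) / (p.R * T)
    if return_molar_mass:
        return rho, (P_v * p.M_h2o + P_co2 * p.M_co2) / P_g
    return rho


_DEFAULT = MaterialParams()
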