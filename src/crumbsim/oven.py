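"""Oven environment and boundary fluxes.

The bread exchanges heat and mass with its surroundings through two kinds of
faces: the free top surface (natural convection + net radiation + evaporative
cooling, species exchange gated by the surface pore state) and the mold
bottom/side (contact conduction only, no mass transfer).  The oven itself is
represented by an :class:`OvenProgram` -- time series of air temperature,
mold-wall temperature and effective radiation density -- either loaded from
CSV or produced by the synthetic generator that emulates the oscillating
traces of an intermittently heated domestic oven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constitutive import (MaterialParams, STEFAN_BOLTZMANN,
                           latent_heat, saturation_concentration,
                           water_activity)


@dataclass
class OvenProgram:
    """Oven boundary environment.

    Trace arrays are linearly interpolated in time (clamped at the ends);
    transfer coefficients are held constant over a bake.
    """

    t: np.ndarray                 # s
    T_air_trace: np.ndarray       # K
    T_wall_trace: np.ndarray      # K
    Phi_trace: np.ndarray         # effective radiation density, W/m^2
    C_oven_v: float = 0.5         # oven vapor concentration, mol/m^3
    C_oven_co2: float = 0.0       # mol/m^3 (negligible in air)
    h_c: float = 10.0             # natural-convection heat transfer, W/(m^2 K)
    h_m: float = 0.0142           # vapor mass transfer coefficient, m/s
    h_co2: float = 0.0103         # CO2 mass transfer coefficient, m/s
    h_e: float = 100.0            # mold contact conductance, W/(m^2 K)
    # mold-wall thermal model: "trace" imposes T_wall_trace; "coupled" evolves
    # a lumped glass-wall node per mold face, fed by oven-side convection and
    # cavity radiation and drained by the h_e contact with the dough, so the
    # wall cannot deliver more heat than the oven resupplies.
    wall_model: str = "coupled"
    h_out: float = 12.0           # oven-side convection on the mold, W/(m^2 K)
    eps_wall: float = 0.9         # mold outer-surface emissivity
    C_wall: float = 7500.0        # areal heat capacity of the glass, J/(m^2 K)

    def __post_init__(self) -> None:
        for name in ("T_air_trace", "T_wall_trace"):
            if np.any(getattr(self, name) <= 273.15):
                raise ValueError(f"{name} must be > 273.15 K")
        if np.any(self.Phi_trace < 0):
            raise ValueError("Phi must be >= 0")
        for name in ("h_c", "h_m", "h_co2", "h_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wall_model not in ("trace", "coupled"):
            raise ValueError("wall_model must be 'trace' or 'coupled'")

    def T_air(self, t):
        return np.interp(t, self.t, self.T_air_trace)

    def T_wall(self, t):
        return np.interp(t, self.t, self.T_wall_trace)

    def Phi(self, t):
        return np.interp(t, self.t, self.Phi_trace)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "T_air": self.T_air_trace,
                             "T_wall": self.T_wall_trace,
                             "Phi": self.Phi_trace})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "OvenProgram":
        return cls(t=df["t"].to_numpy(float),
                   T_air_trace=df["T_air"].to_numpy(float),
                   T_wall_trace=df["T_wall"].to_numpy(float),
                   Phi_trace=df["Phi"].to_numpy(float), **kwargs)


def transfer_coefficients(h_c: float | None = None,
                          T_oven: float = 453.15,
                          D_v: float = 2.6e-5, D_co2: float = 1.6e-5,
                          P_amb: float = 101325.0) -> tuple[float, float, float]:
    """Heat and mass transfer coefficients for the free surface.

    ``h_c`` defaults to 10 W/(m^2 K), a natural-convection plate value for
    oven-scale Rayleigh numbers (constant override supported).  Mass
    coefficients follow the heat-mass analogy
    h_m = h_c / (rho_air c_p,air Le^(2/3)) with species Lewis numbers
    Le_i = a_air / D_i evaluated at the oven air temperature.
    """
    h_c = 10.0 if h_c is None else h_c
    M_air, cp_air = 0.0289, 1006.0
    rho_air = P_amb * M_air / (8.314 * T_oven)
    lam_air = 0.026 + 6.5e-5 * (T_oven - 300.0)  # linearised air conductivity
    a_air = lam_air / (rho_air * cp_air)
    h_m = h_c / (rho_air * cp_air * (a_air / D_v) ** (2.0 / 3.0))
    h_co2 = h_c / (rho_air * cp_air * (a_air / D_co2) ** (2.0 / 3.0))
    return h_c, h_m, h_co2


def synth_oven_program(setpoint: float = 453.15,
                       amplitude: float = 0.0,
                       period: float = 120.0,
                       seed: int = 0,
                       duration: float = 1800.0,
                       dt: float = 5.0,
                       wall_setpoint: float = 413.15,
                       wall_amplitude: float = 8.0,
                       wall_tau: float = 300.0,
                       T_mold0: float = 301.15,
                       Phi: float = 1000.0,
                       **oven_kwargs) -> OvenProgram:
    """Synthetic oven traces for an intermittently heated domestic oven.

    The air temperature is a triangular relay oscillation of the given
    amplitude about the setpoint (the oven is preheated, so the air starts
    at temperature); the seed only randomises the relay phase, so a given
    seed reproduces the program exactly and amplitude 0 yields a constant
    program.  The mold wall is a first-order lag (time constant
    ``wall_tau``) from its initial temperature toward a wall setpoint plus
    the attenuated air oscillation -- the glass mold warms up much more
    slowly than the air and equilibrates well below the air setpoint
    because its oven-side heat supply is the bottleneck.
    """
    if amplitude < 0 or wall_amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 1.0))
    t = np.arange(0.0, duration + dt, dt)

    def triangle(u):
        u = np.mod(u, 1.0)
        return np.where(u < 0.5, 4.0 * u - 1.0, 3.0 - 4.0 * u)

    T_air = setpoint + amplitude * triangle(t / period + phase)
    # wall: exact exponential update of dTw/dt = (target - Tw)/tau
    target = wall_setpoint + (wall_amplitude * triangle(t / period + phase)
                              if amplitude > 0 else 0.0)
    T_wall = np.empty_like(t)
    T_wall[0] = T_mold0
    decay = np.exp(-dt / wall_tau)
    tgt = np.broadcast_to(target, t.shape)
    for i in range(1, len(t)):
        T_wall[i] = tgt[i] + (T_wall[i - 1] - tgt[i]) * decay
    return OvenProgram(t=t, T_air_trace=T_air, T_wall_trace=T_wall,
                       Phi_trace=np.full_like(t, Phi), **oven_kwargs)


# ---------------------------------------------------------------------------
# boundary fluxes (outward positive)
# ---------------------------------------------------------------------------

def liquid_boundary_flux(T_s, W_s, alpha_s, oven: OvenProgram, t: float,
                         params: MaterialParams):
    """Surface evaporation of liquid water, kg/(m^2 s), outward positive.

    j_l,b = (1 - alpha) h_m M_H2O (a_w C_sat - C_oven,v): natural-convection
    drying of the still-closed surface, gated off once the surface pores
    open (the vapor then leaves through the gas phase instead)."""
    a_w = water_activity(np.maximum(W_s, 1e-4), np.clip(T_s, 273.16, 423.15))
    C_sat = saturation_concentration(np.clip(T_s, 273.16, 423.15), params)
    return ((1.0 - np.asarray(alpha_s)) * oven.h_m * params.M_h2o
            * (a_w * C_sat - oven.C_oven_v))


def vapor_boundary_flux(C_v_s, alpha_s, oven: OvenProgram, params: MaterialParams):
    """Convective vapor exchange j_v,b = alpha h_m M_H2O (C_v - C_oven,v)."""
    return (np.asarray(alpha_s) * oven.h_m * params.M_h2o
            * (np.asarray(C_v_s) - oven.C_oven_v))


def co2_boundary_flux(C_co2_s, alpha_s, oven: OvenProgram, params: MaterialParams):
    """Convective CO2 exchange j_CO2,b = alpha h_CO2 M_CO2 (C_CO2 - C_oven)."""
    return (np.asarray(alpha_s) * oven.h_co2 * params.M_co2
            * (np.asarray(C_co2_s) - oven.C_oven_co2))


def heat_boundary_flux(T_s, tag: str, oven: OvenProgram, t: float,
                       params: MaterialParams, j_l_b=0.0):
    """Inward heat flux q, W/m^2, at a boundary face.

    top_air: convection + net gray radiation eps*(Phi - sigma T^4) minus the
    evaporative cooling j_l,b L_v.  bottom_mold / side_mold: contact
    conduction h_e (T_wall - T)."""
    T_s = np.asarray(T_s, dtype=float)
    if tag == "top_air":
        q = (oven.h_c * (oven.T_air(t) - T_s)
             + params.emissivity * (oven.Phi(t) - STEFAN_BOLTZMANN * T_s ** 4)
             - np.asarray(j_l_b) * latent_heat(T_s, params))
        return q
    if tag in ("bottom_mold", "side_mold"):
        return oven.h_e * (oven.T_wall(t) - T_s)
    raise ValueError(f"unknown boundary tag {tag!r}")
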