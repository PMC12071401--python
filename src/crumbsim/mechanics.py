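"""Dough momentum and ALE mesh motion.

The dough is a creeping, weakly compressible, very viscous Newtonian fluid
(mu >= 1e4 Pa s): at centimetre scales the inertial terms are ~10 orders of
magnitude below the viscous ones, so the quasi-static balance is solved.
Inside the mold the side wall is frictionless with zero normal velocity and
the bottom is no-slip, so the kinematically admissible motion is vertical
column stretching; the free top surface rides with the dough.

Default ``pressure_driven`` closure: the gauge pressure of the pore gas
(minus the overburden weight when gravity is on) drives a local volumetric
strain rate div v = (P_g - P_amb - sigma_w)/mu_eff -- the dominant-balance
reduction of the momentum equation with the gas-pressure body force
F = -grad P_g.  While pores are closed the gas cannot vent, so gas
generation inflates the cell until the viscous resistance balances the
gauge pressure; once pores open and vent, P_g -> P_amb and expansion stops.
``prescribed_divergence`` instead relaxes each cell's gas volume toward its
ideal-gas value at ambient pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import MaterialParams
from .fields import DerivedFields, FieldState, Grid

_MODES = ("pressure_driven", "prescribed_divergence")


@dataclass
class MechanicsConfig:
    inertia: bool = False
    mode: str = "pressure_driven"
    gravity: bool = True
    backfill_open: bool = True        # open pores cannot drop below ambient
    backfill_alpha: float = 0.0       # backfill acts wherever alpha exceeds this
    max_strain_rate: float = 0.05     # |div v| cap, 1/s
    relax_time: float = 20.0          # prescribed_divergence relaxation, s
    mold_height: float = 0.100        # m, dough stays inside the mold

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mechanics mode must be one of {_MODES}")


def overburden_stress(state: FieldState, der: DerivedFields, grid: Grid,
                      params: MaterialParams) -> np.ndarray:
    """Weight of material above each cell centre per unit area, Pa."""
    rho_eff = state.rho_s_bar + state.rho_l_bar + der.f_vg * der.rho_g
    col_w = rho_eff * grid.dz * params.g
    # weight above cell k: half of own cell + all cells above
    above = np.cumsum(col_w[:, ::-1], axis=1)[:, ::-1] - 0.5 * col_w
    return above


def solve_mechanics(state: FieldState, der: DerivedFields, grid: Grid,
                    params: MaterialParams,
                    config: MechanicsConfig | None = None,
                    dt: float = 0.1):
    """Quasi-static deformation solve over an interval dt.

    Per cell the stretch s = 1 + e dt satisfies the implicit balance

        mu_eff (s - 1)/dt = P_g(s) - P_ref,    P_ref = P_amb (+ overburden)

    where P_g(s) = n R T / (V_g0 + (s - 1) V0) is the pore-gas pressure
    after the incompressible matrix has donated all the volume change to
    the gas.  The implicit form is unconditionally stable: the local
    pressure-strain relaxation time mu f_vg / P_g (~0.01 s for fluid-like
    dough) is far below any practical transport step.  In the soft limit
    the cell lands on P_g = P_ref exactly; in the stiff (solidified) limit
    e -> (P_g - P_ref)/mu_eff, the linear creeping-flow law.

    Returns ``(v_nodes, e, p)``: vertical node velocities (nr, nz+1) with
    v = 0 at the no-slip bottom, cell volumetric strain rates e = div v,
    and the mechanical pressure p = P_amb + mu_eff e (viscous normal
    stress about ambient).
    """
    cfg = config or MechanicsConfig()
    if np.any(der.mu_eff <= 0):
        raise ValueError("mu_eff must be positive")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    P_ref = np.full_like(der.P_g, params.P_amb)
    if cfg.gravity:
        P_ref = P_ref + overburden_stress(state, der, grid, params)
    f0 = der.f_vg
    nRT = der.P_g * f0                      # per unit cell volume
    emax = cfg.max_strain_rate
    if cfg.mode == "prescribed_divergence":
        e = f0 * (der.P_g / P_ref - 1.0) / cfg.relax_time
        e = np.clip(e, -emax, emax)
    else:
        # bisection bounds: strain-rate clip plus gas/matrix exhaustion
        s_lo = np.maximum(1.0 - emax * dt, (1.0 - f0) / 0.98)
        s_hi = np.minimum(1.0 + emax * dt, (1.0 - f0) / 0.02)
        s_hi = np.maximum(s_hi, s_lo + 1e-12)
        # any pore interconnection lets oven air wick in at ambient, so a
        # partially or fully open network cannot sustain sub-ambient mean
        # pressure (the model carries no inert-air species; the backfill is
        # represented as a pressure floor).  Over-pressure is still relieved
        # only by viscous expansion and Darcy venting.  Fully closed cells
        # (alpha = 0) keep their own gas pressure.
        floor = (params.P_amb * (der.alpha > cfg.backfill_alpha)
                 if cfg.backfill_open else np.zeros_like(f0))

        def resid(s):
            Vg = np.maximum(f0 + (s - 1.0), 1e-9)
            return der.mu_eff * (s - 1.0) / dt + P_ref \
                - np.maximum(nRT / Vg, floor)

        lo, hi = s_lo.copy(), s_hi.copy()
        r_lo, r_hi = resid(lo), resid(hi)
        s = np.where(r_lo >= 0, lo, np.where(r_hi <= 0, hi, 0.5 * (lo + hi)))
        bracket = (r_lo < 0) & (r_hi > 0)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            r_mid = resid(mid)
            take_lo = r_mid > 0
            hi = np.where(bracket & take_lo, mid, hi)
            lo = np.where(bracket & ~take_lo, mid, lo)
        s = np.where(bracket, 0.5 * (lo + hi), s)
        e = (s - 1.0) / dt
    # freeze columns that have reached the mold rim
    at_rim = grid.column_heights >= cfg.mold_height
    if np.any(at_rim):
        e[at_rim] = np.minimum(e[at_rim], 0.0)
    v_nodes = np.zeros((grid.nr, grid.nz + 1))
    v_nodes[:, 1:] = np.cumsum(e * grid.dz, axis=1)
    p = params.P_amb + der.mu_eff * e
    return v_nodes, e, p


def move_mesh(grid: Grid, state: FieldState, e: np.ndarray, dt: float) -> Grid:
    """Advance the mesh one step and rescale densities conservatively.

    Each cell's thickness is stretched by s = 1 + e dt and all apparent
    densities are divided by s, so the mass rho_bar * V of every species in
    every cell is exactly invariant under pure mesh motion (the ALE form of
    the conservation laws with a material mesh)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = 1.0 + np.asarray(e) * dt
    if np.any(s <= 0.05):
        raise FloatingPointError("mesh tangling: cell stretched below 5% "
                                 "of its size in one step")
    new = grid.copy()
    dz = grid.dz * s
    new.z_edges[:, 1:] = np.cumsum(dz, axis=1)
    new.z_edges[:, 0] = grid.z_edges[:, 0]
    for name in ("rho_s_bar", "rho_l_bar", "rho_v_bar", "rho_co2_bar"):
        getattr(state, name)[...] /= s
    return new
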