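"""State containers on the deforming axisymmetric grid.

The grid is structured in (r, z): fixed annular rings in r (the mold forbids
radial motion) and per-column material cells in z that stretch with the
dough, so vertical deformation is Lagrangian and solid mass is conserved by
construction.  ``axial1d`` is the single-column reduction used as the fast
test vehicle; ``axisym2d`` carries several rings so that the axis and
mold-edge columns evolve differently.

All conserved quantities are apparent (per unit bread volume) densities;
every derived field (moisture W, volume fractions, partial pressures, gas
properties, the sigmoid state functions) is assembled here from the
constitutive layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as con
from .constitutive import MaterialParams


@dataclass
class Grid:
    """Structured axisymmetric grid with per-column vertical stretching.

    r_edges : (nr+1,) fixed ring boundaries, m.
    z_edges : (nr, nz+1) per-column cell boundaries, m (z=0 at mold bottom).
    """

    mode: str
    r_edges: np.ndarray
    z_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in ("axial1d", "axisym2d"):
            raise ValueError(f"unknown grid mode {self.mode!r}")
        if np.any(self.r_edges < 0):
            raise ValueError("r_edges must be >= 0")
        if np.any(np.diff(self.z_edges, axis=1) <= 0):
            raise ValueError("cell heights must be positive")

    @property
    def nr(self) -> int:
        return self.z_edges.shape[0]

    @property
    def nz(self) -> int:
        return self.z_edges.shape[1] - 1

    @property
    def ring_areas(self) -> np.ndarray:
        """Horizontal annular areas pi (r_o^2 - r_i^2), (nr,)."""
        return np.pi * np.diff(self.r_edges ** 2)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges, axis=1)

    @property
    def volumes(self) -> np.ndarray:
        """Cell volumes, (nr, nz)."""
        return self.ring_areas[:, None] * self.dz

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:, :-1] + self.z_edges[:, 1:])

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def column_heights(self) -> np.ndarray:
        return self.z_edges[:, -1]

    @property
    def radius(self) -> float:
        return float(self.r_edges[-1])

    def copy(self) -> "Grid":
        return Grid(self.mode, self.r_edges.copy(), self.z_edges.copy())


def make_grid(radius: float = 0.05, height: float = 0.020,
              nr: int = 6, nz: int = 16, mode: str = "axisym2d",
              boundary_layer: float = 0.0) -> Grid:
    """Build the initial cylinder grid.

    ``boundary_layer`` > 0 geometrically grades the first/last vertical
    cells down to that thickness (m) for boundary resolution; 0 keeps the
    column uniform.
    """
    if radius <= 0 or height <= 0:
        raise ValueError("geometry must be positive")
    if mode == "axial1d":
        nr = 1
    r_edges = np.linspace(0.0, radius, nr + 1)
    z = np.linspace(0.0, height, nz + 1)
    if boundary_layer > 0 and nz >= 6:
        # squeeze the end cells toward `boundary_layer` with a smooth map
        u = z / height
        w = u + 0.0  # identity base
        pinch = boundary_layer * nz / height
        if pinch < 1.0:
            a = 1.0 - pinch
            w = u - a / (2 * np.pi) * np.sin(2 * np.pi * u)
        z = w * height
        z[0], z[-1] = 0.0, height
    z_edges = np.tile(z, (nr, 1))
    return Grid(mode, r_edges, z_edges)


@dataclass
class FieldState:
    """Conserved fields on the grid (apparent densities kg/m^3, T in K)."""

    rho_s_bar: np.ndarray
    rho_l_bar: np.ndarray
    rho_v_bar: np.ndarray
    rho_co2_bar: np.ndarray
    T: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(*(getattr(self, k).copy() for k in
                            ("rho_s_bar", "rho_l_bar", "rho_v_bar",
                             "rho_co2_bar", "T")))

    def validate(self) -> None:
        for name in ("rho_s_bar", "rho_l_bar", "rho_v_bar", "rho_co2_bar", "T"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                idx = tuple(int(i) for i in np.argwhere(~np.isfinite(arr))[0])
                raise FloatingPointError(
                    f"state corruption: non-finite {name} at cell {idx}")
            if name != "T" and np.any(arr < -1e-12):
                idx = tuple(int(i) for i in np.argwhere(arr < -1e-12)[0])
                raise FloatingPointError(
                    f"state corruption: negative {name} at cell {idx}")


@dataclass
class DerivedFields:
    """Elementwise derived fields; fraction closure f_vs+f_vl+f_vg = 1 exact."""

    W: np.ndarray
    f_vs: np.ndarray
    f_vl: np.ndarray
    f_vg: np.ndarray
    a_w: np.ndarray
    C_v: np.ndarray          # intrinsic vapor molar concentration, mol/m^3 gas
    C_co2: np.ndarray
    P_v: np.ndarray
    P_co2: np.ndarray
    P_g: np.ndarray
    rho_g: np.ndarray        # intrinsic gas density, kg/m^3
    rhocp_eff: np.ndarray    # volumetric heat capacity, J/(m^3 K)
    lambda_eff: np.ndarray
    edc_share: np.ndarray
    kappa_g: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu_eff: np.ndarray
    k_mpc: np.ndarray
    L_v: np.ndarray
    C_sat: np.ndarray


def derived_fields(state: FieldState, params: MaterialParams) -> DerivedFields:
    """Assemble every constitutive closure over the grid."""
    state.validate()
    p = params
    W = state.rho_l_bar / np.maximum(state.rho_s_bar, 1e-300)
    f_vs = state.rho_s_bar / p.rho_s
    f_vl = state.rho_l_bar / p.rho_l
    f_vg = 1.0 - f_vs - f_vl
    if np.any(f_vg <= 0) or np.any(f_vg >= 1):
        raise ValueError("derived_fields: gas volume fraction outside (0, 1)")
    T = state.T
    C_v = state.rho_v_bar / (p.M_h2o * f_vg)
    C_co2 = state.rho_co2_bar / (p.M_co2 * f_vg)
    P_v = C_v * p.R * T
    P_co2 = C_co2 * p.R * T
    P_g = P_v + P_co2
    rho_g = (P_v * p.M_h2o + P_co2 * p.M_co2) / (p.R * T)
    rhocp = (state.rho_s_bar * p.cp_s + state.rho_l_bar * p.cp_l
             + f_vg * rho_g * p.cp_g)
    alpha = con.pore_open_fraction(T, p)
    beta = con.crust_function(T, p)
    # clamp W for the sorption correlation: dried-out crust cells keep a
    # tiny residual so a_w stays defined
    W_safe = np.maximum(W, 1e-4)
    T_safe = np.clip(T, 273.16, 423.15)
    lam, share = con.effective_conductivity(f_vs, f_vl, f_vg, T_safe, W_safe,
                                            alpha, p, return_share=True)
    return DerivedFields(
        W=W, f_vs=f_vs, f_vl=f_vl, f_vg=f_vg,
        a_w=con.water_activity(W_safe, T_safe),
        C_v=C_v, C_co2=C_co2, P_v=P_v, P_co2=P_co2, P_g=P_g, rho_g=rho_g,
        rhocp_eff=rhocp, lambda_eff=lam, edc_share=share,
        kappa_g=con.permeability(f_vg, alpha, beta, p),
        alpha=alpha, beta=beta,
        mu_eff=con.dough_viscosity(T, p),
        k_mpc=con.mpc_rate(alpha, p),
        L_v=con.latent_heat(T, p),
        C_sat=con.saturation_concentration(T_safe, p),
    )


def initialize(grid: Grid, params: MaterialParams,
               T0: float = 301.15, W0: float = 0.82,
               rho_eff0: float = 1069.0) -> FieldState:
    """Uniform initial state from (T0, W0, rho_eff0).

    rho_s_bar = rho_eff0/(1+W0), rho_l_bar = W0 rho_s_bar; the pore gas is
    initialised at ambient pressure with the vapor at sorption equilibrium
    (P_v = a_w P_sat(T0)) and the balance assigned to CO2 (the model
    carries no inert-air species).
    """
    p = params
    if W0 <= 0:
        raise ValueError("initialize: W0 must be > 0")
    rho_s_bar = rho_eff0 / (1.0 + W0)
    rho_l_bar = W0 * rho_s_bar
    f_vg = 1.0 - rho_s_bar / p.rho_s - rho_l_bar / p.rho_l
    if not 0.0 < f_vg < 1.0:
        raise ValueError(
            f"inconsistent scenario: initial gas fraction {f_vg:.4f} not in (0,1)")
    a_w = float(con.water_activity(W0, T0))
    P_v = a_w * float(con.saturation_pressure(T0, p))
    P_co2 = p.P_amb - P_v
    if P_co2 <= 0:
        raise ValueError("inconsistent scenario: a_w P_sat(T0) >= P_amb")
    shape = (grid.nr, grid.nz)
    rho_v_bar = f_vg * P_v * p.M_h2o / (p.R * T0)
    rho_co2_bar = f_vg * P_co2 * p.M_co2 / (p.R * T0)
    return FieldState(
        rho_s_bar=np.full(shape, rho_s_bar),
        rho_l_bar=np.full(shape, rho_l_bar),
        rho_v_bar=np.full(shape, rho_v_bar),
        rho_co2_bar=np.full(shape, rho_co2_bar),
        T=np.full(shape, float(T0)),
    )


# ---------------------------------------------------------------------------
# Lagrangian probes and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class Probe:
    """Material (Lagrangian) point: fixed column + fractional cell index.

    Because columns stretch materially in z, a fixed (cell, local offset)
    pair is a material point that rides with the dough, like a flexible
    thermocouple."""

    name: str
    col: int
    k: int
    xi: float  # in [0, 1) within cell k

    def z(self, grid: Grid) -> float:
        return float(grid.z_edges[self.col, self.k]
                     + self.xi * grid.dz[self.col, self.k])


def make_probe(name: str, r: float, z: float, grid: Grid) -> Probe:
    """Attach a probe at laboratory coordinates (r, z) of the *initial* grid."""
    col = int(np.clip(np.searchsorted(grid.r_edges, r, side="right") - 1,
                      0, grid.nr - 1))
    zcol = grid.z_edges[col]
    if not zcol[0] <= z <= zcol[-1]:
        raise ValueError(f"probe {name!r} outside domain (z={z})")
    k = int(np.clip(np.searchsorted(zcol, z, side="right") - 1, 0, grid.nz - 1))
    xi = (z - zcol[k]) / (zcol[k + 1] - zcol[k])
    return Probe(name, col, k, float(xi))


def probe_value(field2d: np.ndarray, probe: Probe, grid: Grid) -> float:
    """Linear interpolation of a cell-centred field at the probe point."""
    col, zc = probe.col, grid.z_centers[probe.col]
    z = probe.z(grid)
    return float(np.interp(z, zc, field2d[col]))


DEFAULT_PROBES = (("T1", 0.000, 0.005), ("T2", 0.000, 0.010),
                  ("T3", 0.025, 0.015), ("P1", 0.000, 0.010))


def diagnostics(state: FieldState, grid: Grid, params: MaterialParams,
                probes: list[Probe] | None = None,
                initial_volume: float | None = None,
                t: float = 0.0) -> dict:
    """One diagnostics row: heights, masses, probe values, closed-pore gas
    composition, EDC conductivity share, volume ratio."""
    d = derived_fields(state, params)
    V = grid.volumes
    vol = float(V.sum())
    row = {
        "t": t,
        "axis_height": float(grid.column_heights[0]),
        "side_height": float(grid.column_heights[-1]),
        "liquid_mass": float((state.rho_l_bar * V).sum()),
        "vapor_mass": float((state.rho_v_bar * V).sum()),
        "co2_mass": float((state.rho_co2_bar * V).sum()),
        "solid_mass": float((state.rho_s_bar * V).sum()),
        "volume": vol,
        "volume_ratio": vol / initial_volume if initial_volume else 1.0,
        "T_min": float(state.T.min()),
        "T_max": float(state.T.max()),
    }
    closed = d.alpha < 1.0
    if np.any(closed):
        w = (V * d.f_vg)[closed]
        x_v = (d.P_v / np.maximum(d.P_g, 1e-300))[closed]
        row["closed_vapor_molfrac"] = float((x_v * w).sum() / w.sum())
        row["closed_edc_share_max"] = float(d.edc_share[closed].max())
        row["closed_fraction"] = float(V[closed].sum() / vol)
    else:
        row["closed_vapor_molfrac"] = np.nan
        row["closed_edc_share_max"] = np.nan
        row["closed_fraction"] = 0.0
    # crumb (non-crust) peak dry-basis moisture, sampled where the source
    # study reports it: along the axis and the z = 15 mm material line
    # (cells are material in z, so a fixed index row tracks that line)
    k15 = min(int(round(0.75 * grid.nz)), grid.nz - 1)
    lines = np.zeros_like(d.W, dtype=bool)
    lines[0, :] = True
    lines[:, k15] = True
    crumb = (d.beta > 0.5) & lines
    row["W_crumb_max"] = float(d.W[crumb].max()) if np.any(crumb) else np.nan
    for pr in probes or []:
        if pr.name.startswith("P"):
            row[pr.name + "_gauge"] = probe_value(d.P_g, pr, grid) - params.P_amb
        else:
            row[pr.name] = probe_value(state.T, pr, grid)
    return row
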