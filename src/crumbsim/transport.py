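"""Time integration of the coupled conservation laws.

Finite-volume, cell-centred discretisation on the column-Lagrangian
axisymmetric grid.  Per step (operator splitting):

1. mechanics + mesh motion (quasi-static viscous expansion; pure vertical
   stretch, so advection by the deformation velocity is absorbed into the
   material mesh and solid mass is conserved exactly);
2. CO2 generation source;
3. local moisture phase change (MPC): exponential relaxation of the vapor
   concentration toward the sorption equilibrium a_w C_sat at rate k_MPC,
   with the latent heat applied to the cell (stiff at k = 10 1/s, hence the
   exact local integration);
4. explicit conservative liquid fluxes: Fickian diffusion down grad W plus
   the closed-pore ECD flux down grad T;
5. implicit (backward-Euler) vapor and CO2 pore diffusion, open-pore gated;
6. implicit Darcy venting: one pressure solve per step with upwinded
   species and enthalpy advection; closed cells (kappa = 0) decouple;
7. implicit heat conduction with Robin oven/mold boundaries (radiation and
   evaporative cooling explicit).

Interface diffusivities/conductivities use harmonic means, which makes the
alpha-gated coefficients vanish correctly at open/closed interfaces;
advective fluxes are upwinded (monotone at the evaporation and condensation
fronts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as con
from .constitutive import MaterialParams
from .fields import (DerivedFields, FieldState, Grid, derived_fields,
                     diagnostics, make_probe, DEFAULT_PROBES)
from .mechanics import MechanicsConfig, move_mesh, solve_mechanics
from .oven import (OvenProgram, heat_boundary_flux, liquid_boundary_flux)


@dataclass
class SolverConfig:
    dt_init: float = 0.05
    dt_max: float = 0.5
    dt_min: float = 1e-4
    rel_tol: float = 1e-3            # adaptive-step relative tolerance
    max_retries: int = 12
    t_end: float = 1800.0
    gas_momentum: str = "darcy"      # or "brinkman" (diagnostic velocity)
    mechanics_on: bool = True
    co2_source_on: bool = True
    max_dT_step: float = 3.0         # K per step, adaptivity target
    max_strain_step: float = 0.02    # relative volume change per step
    diag_interval: float = 10.0
    snapshot_times: tuple = (300.0, 600.0, 900.0, 1200.0)

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.rel_tol <= 0:
            raise ValueError("t_end and rel_tol must be > 0")
        if self.gas_momentum not in ("darcy", "brinkman"):
            raise ValueError("gas_momentum must be 'darcy' or 'brinkman'")


@dataclass
class StepReport:
    """Per-step bookkeeping used by budget accounting and adaptivity."""
    water_out: float = 0.0     # kg leaving the domain this step (liquid+vapor)
    co2_out: float = 0.0
    heat_in: float = 0.0       # J through all boundaries
    max_dT: float = 0.0
    max_strain: float = 0.0


# ---------------------------------------------------------------------------
# sparse helpers
# ---------------------------------------------------------------------------

def _harmonic(a, b):
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _face_geometry(grid: Grid):
    """Transmissibility geometry: (A/d) for vertical and radial faces."""
    dz = grid.dz
    A_ring = grid.ring_areas
    # vertical faces between (i,k) and (i,k+1)
    dz_v = 0.5 * (dz[:, :-1] + dz[:, 1:])
    geo_z = A_ring[:, None] / dz_v                    # (nr, nz-1)
    if grid.nr > 1:
        r_int = grid.r_edges[1:-1]
        dzbar = 0.5 * (dz[:-1, :] + dz[1:, :])
        A_r = 2.0 * np.pi * r_int[:, None] * dzbar    # (nr-1, nz)
        dr = np.diff(grid.r_centers)
        geo_r = A_r / dr[:, None]
    else:
        geo_r = np.zeros((0, grid.nz))
    return geo_z, geo_r


def _spsolve(A, b):
    return spla.spsolve(A.tocsr(), b)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Couples mechanics, transport and the oven boundary on one grid."""

    def __init__(self, params: MaterialParams,
                 solver: SolverConfig | None = None,
                 mechanics: MechanicsConfig | None = None,
                 oven: OvenProgram | None = None):
        self.params = params
        self.solver = solver or SolverConfig()
        self.mech = mechanics or MechanicsConfig()
        self.oven = oven
        self.last_pressure = None
        self.last_flux_z = None
        self.T_wall_bot: float | None = None   # coupled mold-wall nodes
        self.T_wall_side: float | None = None

    # -- individual sub-steps ----------------------------------------------

    def mpc_exchange(self, state: FieldState, der: DerivedFields,
                     dt: float) -> None:
        """Local MPC relaxation of C_v toward a_w C_sat (exact in dt)."""
        p = self.params
        target = der.a_w * der.C_sat
        relax = 1.0 - np.exp(-der.k_mpc * dt)
        delta = der.f_vg * p.M_h2o * (target - der.C_v) * relax
        # positive delta = evaporation (vapor gain): cap by available liquid
        delta = np.minimum(delta, 0.9 * state.rho_l_bar)
        delta = np.maximum(delta, -0.9 * state.rho_v_bar)
        state.rho_v_bar += delta
        state.rho_l_bar -= delta
        state.T -= delta * der.L_v / der.rhocp_eff

    def co2_generation(self, state: FieldState, der: DerivedFields,
                       dt: float) -> None:
        """CO2 release m_CO2 = rho_s_bar k_CO2(T) f_vg M_CO2, kg/(m^3 s).

        The generation correlation k_CO2(T) is read as mol CO2 per kg dry
        solid per second: that magnitude (peak ~0.36 mol/kg/h near 40 C)
        matches vigorous proofing, whereas a mass reading would imply an
        impossible ~400 g CO2/kg/h and a closed-pore gas overwhelmingly
        dominated by CO2."""
        rate = con.co2_generation_rate(state.T) * self.params.M_co2
        state.rho_co2_bar += state.rho_s_bar * rate * der.f_vg * dt

    def liquid_fluxes(self, state: FieldState, der: DerivedFields,
                      grid: Grid, dt: float) -> None:
        """Explicit conservative Fickian + ECD liquid transport."""
        p = self.params
        geo_z, geo_r = _face_geometry(grid)
        W = der.W
        T = state.T
        # cell transport coefficients
        D_fick = state.rho_s_bar * con.liquid_diffusivity(
            np.minimum(W, 3.0), np.clip(der.f_vg, 0.0, 1.0))
        T_safe = np.clip(T, 273.16, 423.15)
        ecd_coef = ((1.0 - der.alpha) * der.f_vg * p.D_v_ref * der.a_w
                    / (p.R * T_safe) * con.saturation_pressure_slope(T_safe, p))

        def face_flux(axis):
            if axis == 0 and grid.nr == 1:
                return None
            sl_a = (slice(None), slice(None, -1)) if axis == 1 else (slice(None, -1), slice(None))
            sl_b = (slice(None), slice(1, None)) if axis == 1 else (slice(1, None), slice(None))
            geo = geo_z if axis == 1 else geo_r
            f_fick = _harmonic(D_fick[sl_a], D_fick[sl_b]) * geo * (W[sl_a] - W[sl_b])
            f_ecd = _harmonic(ecd_coef[sl_a], ecd_coef[sl_b]) * geo * (T[sl_a] - T[sl_b])
            return f_fick + f_ecd  # kg/s, positive from a -> b

        V = grid.volumes
        dm = np.zeros_like(W)
        out = np.zeros_like(W)
        fluxes = {}
        for axis in (1, 0):
            f = face_flux(axis)
            if f is None:
                continue
            fluxes[axis] = f
            if axis == 1:
                out[:, :-1] += np.maximum(f, 0.0)
                out[:, 1:] += np.maximum(-f, 0.0)
            else:
                out[:-1, :] += np.maximum(f, 0.0)
                out[1:, :] += np.maximum(-f, 0.0)
        # positivity limiter: a cell may export at most half its liquid per step
        avail = 0.5 * state.rho_l_bar * V / dt
        scale = np.ones_like(W)
        hot = out > avail
        scale[hot] = avail[hot] / out[hot]
        for axis, f in fluxes.items():
            if axis == 1:
                s_face = np.where(f > 0, scale[:, :-1], scale[:, 1:])
                f *= s_face
                dm[:, :-1] -= f * dt
                dm[:, 1:] += f * dt
            else:
                s_face = np.where(f > 0, scale[:-1, :], scale[1:, :])
                f *= s_face
                dm[:-1, :] -= f * dt
                dm[1:, :] += f * dt
        state.rho_l_bar += dm / V

    def surface_evaporation(self, state: FieldState, der: DerivedFields,
                            grid: Grid, t: float, dt: float,
                            report: StepReport) -> np.ndarray:
        """Closed-surface liquid evaporation; returns per-column j_l,b W-cooling
        already folded into the top heat flux later."""
        p = self.params
        top = (slice(None), -1)
        j = liquid_boundary_flux(state.T[top], np.maximum(der.W[top], 1e-4),
                                 der.alpha[top], self.oven, t, p)
        j = np.maximum(j, 0.0)
        A_top = grid.ring_areas
        avail = 0.9 * state.rho_l_bar[top] * grid.dz[top] / dt
        j = np.minimum(j, avail)
        state.rho_l_bar[top] -= j * dt / grid.dz[top]
        report.water_out += float((j * A_top).sum() * dt)
        return j

    def species_diffusion(self, state: FieldState, der: DerivedFields,
                          grid: Grid, t: float, dt: float,
                          report: StepReport) -> None:
        """Implicit open-pore diffusion of vapor and CO2 (intrinsic C)."""
        p = self.params
        V = grid.volumes
        eps = np.clip(der.f_vg, 0.0, 1.0)
        for which in ("v", "co2"):
            if which == "v":
                D_ref, M, C = p.D_v_ref, p.M_h2o, der.C_v
                h = self.oven.h_m if self.oven else 0.0
                C_env = self.oven.C_oven_v if self.oven else 0.0
                rho_attr = "rho_v_bar"
            else:
                D_ref, M, C = p.D_co2_ref, p.M_co2, der.C_co2
                h = self.oven.h_co2 if self.oven else 0.0
                C_env = self.oven.C_oven_co2 if self.oven else 0.0
                rho_attr = "rho_co2_bar"
            coeff = der.alpha * con.gas_effective_diffusivity(D_ref, eps)
            if not np.any(coeff > 0) and (h == 0 or not np.any(der.alpha[:, -1] > 0)):
                continue
            nr, nz = grid.nr, grid.nz
            n = nr * nz
            geo_z, geo_r = _face_geometry(grid)
            idx = np.arange(n).reshape(nr, nz)
            rows, cols, vals = [], [], []
            tz = _harmonic(coeff[:, :-1], coeff[:, 1:]) * geo_z
            ia, ib = idx[:, :-1].ravel(), idx[:, 1:].ravel()
            rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
            vals += [tz.ravel(), tz.ravel(), -tz.ravel(), -tz.ravel()]
            if nr > 1:
                tr = _harmonic(coeff[:-1, :], coeff[1:, :]) * geo_r
                ia, ib = idx[:-1, :].ravel(), idx[1:, :].ravel()
                rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
                vals += [tr.ravel(), tr.ravel(), -tr.ravel(), -tr.ravel()]
            cap = (eps * V).ravel() / dt
            A = sp.coo_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(n, n)).tolil()
            A.setdiag(A.diagonal() + cap)
            b = cap * C.ravel()
            if self.oven is not None and h > 0:
                # top-face Robin exchange, alpha-gated
                top_cells = idx[:, -1]
                hA = der.alpha[:, -1] * h * grid.ring_areas
                for ii, ha in zip(top_cells, hA):
                    A[ii, ii] += ha
                b[top_cells] += hA * C_env
            C_new = _spsolve(A.tocsr(), b).reshape(nr, nz)
            if self.oven is not None and h > 0:
                out = (der.alpha[:, -1] * h * grid.ring_areas
                       * (C_new[:, -1] - C_env)).sum() * M * dt
                if which == "v":
                    report.water_out += float(out)
                else:
                    report.co2_out += float(out)
            setattr(state, rho_attr, C_new * M * eps)

    def darcy_vent(self, state: FieldState, der: DerivedFields, grid: Grid,
                   t: float, dt: float, report: StepReport) -> np.ndarray:
        """Implicit gas-pressure solve and upwinded species/enthalpy advection.

        Returns the per-cell enthalpy-advection heat source (W) consumed by
        the subsequent temperature solve."""
        p = self.params
        nr, nz = grid.nr, grid.nz
        n = nr * nz
        V = grid.volumes
        heat_src = np.zeros((nr, nz))
        kap = der.kappa_g
        top_open = der.alpha[:, -1] > 0
        if not np.any(kap > 0) and not np.any(top_open):
            self.last_pressure = der.P_g.copy()
            return heat_src
        geo_z, geo_r = _face_geometry(grid)
        idx = np.arange(n).reshape(nr, nz)
        T_safe = state.T
        n_mol = der.P_g / (p.R * T_safe)     # intrinsic molar density
        mob = kap / p.mu_g
        rows, cols, vals = [], [], []
        tz = _harmonic(mob[:, :-1], mob[:, 1:]) * geo_z \
            * 0.5 * (n_mol[:, :-1] + n_mol[:, 1:])
        if nr > 1:
            tr = _harmonic(mob[:-1, :], mob[1:, :]) * geo_r \
                * 0.5 * (n_mol[:-1, :] + n_mol[1:, :])
        ia, ib = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
        vals += [tz.ravel(), tz.ravel(), -tz.ravel(), -tz.ravel()]
        if nr > 1:
            ia, ib = idx[:-1, :].ravel(), idx[1:, :].ravel()
            rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
            vals += [tr.ravel(), tr.ravel(), -tr.ravel(), -tr.ravel()]
        cap = (np.clip(der.f_vg, 1e-6, 1.0) * V / (p.R * T_safe)).ravel() / dt
        A = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)).tolil()
        A.setdiag(A.diagonal() + cap)
        b = cap * der.P_g.ravel()
        # top outlet: half-cell transmissibility to ambient where surface open
        t_out = np.zeros(nr)
        if np.any(top_open):
            t_out = (der.alpha[:, -1] * mob[:, -1] * grid.ring_areas
                     / (0.5 * grid.dz[:, -1]) * n_mol[:, -1])
            top_cells = idx[:, -1]
            for ii, to in zip(top_cells, t_out):
                A[ii, ii] += to
            b[top_cells] += t_out * p.P_amb
        P = _spsolve(A.tocsr(), b).reshape(nr, nz)
        self.last_pressure = P
        # species advection with the solved molar fluxes: implicit upwind
        # (backward Euler) -- an M-matrix, so positivity-preserving and
        # exactly conservative even for through-fluxes exceeding a cell's
        # inventory per step (steady venting through the thin crust cells)
        Fz = tz * (P[:, :-1] - P[:, 1:])  # mol/s, positive lower -> upper
        Fr = tr * (P[:-1, :] - P[1:, :]) if nr > 1 else None
        F_out = np.zeros(nr)
        if np.any(top_open):
            F_out = np.maximum(t_out * (P[:, -1] - p.P_amb), 0.0)  # mol/s out
        self.last_flux_z = Fz
        n_cell = np.maximum(n_mol * np.clip(der.f_vg, 1e-9, 1.0) * V, 1e-300)

        n_flat = n_cell.ravel()
        a_rows, a_cols, a_vals = [], [], []

        def couple(F, ia, ib):
            """Upwind exchange for face flux F (mol/s) positive ia->ib,
            entries in donor-cell mole-fraction-per-second units."""
            F = F.ravel()
            rate_a = np.maximum(F, 0.0) / n_flat[ia]   # donor = a
            rate_b = np.maximum(-F, 0.0) / n_flat[ib]  # donor = b
            a_rows.extend([ia, ib, ib, ia])
            a_cols.extend([ia, ia, ib, ib])
            a_vals.extend([rate_a, -rate_a, rate_b, -rate_b])

        couple(Fz, idx[:, :-1].ravel(), idx[:, 1:].ravel())
        if Fr is not None:
            couple(Fr, idx[:-1, :].ravel(), idx[1:, :].ravel())
        a_rows.append(idx[:, -1])
        a_cols.append(idx[:, -1])
        a_vals.append(F_out / n_flat[idx[:, -1]])
        Aadv = sp.coo_matrix((np.concatenate(a_vals),
                              (np.concatenate(a_rows), np.concatenate(a_cols))),
                             shape=(n, n))
        Asys = (sp.identity(n) + dt * Aadv).tocsr()
        N_v = der.C_v * np.clip(der.f_vg, 0.0, 1.0) * V     # mol per cell
        N_c = der.C_co2 * np.clip(der.f_vg, 0.0, 1.0) * V
        N_v_new = _spsolve(Asys, N_v.ravel()).reshape(nr, nz)
        N_c_new = _spsolve(Asys, N_c.ravel()).reshape(nr, nz)
        out_v = float((F_out * dt * N_v_new[:, -1] / n_cell[:, -1]).sum())
        out_c = float((F_out * dt * N_c_new[:, -1] / n_cell[:, -1]).sum())
        report.water_out += out_v * p.M_h2o
        report.co2_out += out_c * p.M_co2
        # enthalpy advection (explicit, with upwind donor temperature)
        x_v = der.C_v / np.maximum(n_mol, 1e-300)
        x_c = der.C_co2 / np.maximum(n_mol, 1e-300)
        Mbar = x_v * p.M_h2o + x_c * p.M_co2

        def adv_heat(F, sl_a, sl_b):
            Fa = np.maximum(F, 0.0)
            Fb = np.maximum(-F, 0.0)
            e_a = Fa * Mbar[sl_a] * p.cp_g * state.T[sl_a]
            e_b = Fb * Mbar[sl_b] * p.cp_g * state.T[sl_b]
            heat_src[sl_a] += e_b - e_a
            heat_src[sl_b] += e_a - e_b

        adv_heat(Fz, (slice(None), slice(None, -1)), (slice(None), slice(1, None)))
        if Fr is not None:
            adv_heat(Fr, (slice(None, -1), slice(None)), (slice(1, None), slice(None)))
        heat_src[:, -1] -= F_out * Mbar[:, -1] * p.cp_g * state.T[:, -1]
        state.rho_v_bar = N_v_new * p.M_h2o / V
        state.rho_co2_bar = N_c_new * p.M_co2 / V
        np.clip(state.rho_v_bar, 0.0, None, out=state.rho_v_bar)
        np.clip(state.rho_co2_bar, 0.0, None, out=state.rho_co2_bar)
        return heat_src

    def heat_step(self, state: FieldState, der: DerivedFields, grid: Grid,
                  t: float, dt: float, j_l_b: np.ndarray,
                  adv_src: np.ndarray, report: StepReport) -> None:
        """Implicit conduction with Robin oven/mold boundaries."""
        p = self.params
        nr, nz = grid.nr, grid.nz
        n = nr * nz
        V = grid.volumes
        geo_z, geo_r = _face_geometry(grid)
        idx = np.arange(n).reshape(nr, nz)
        lam = der.lambda_eff
        rows, cols, vals = [], [], []
        tz = _harmonic(lam[:, :-1], lam[:, 1:]) * geo_z
        ia, ib = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
        vals += [tz.ravel(), tz.ravel(), -tz.ravel(), -tz.ravel()]
        if nr > 1:
            tr = _harmonic(lam[:-1, :], lam[1:, :]) * geo_r
            ia, ib = idx[:-1, :].ravel(), idx[1:, :].ravel()
            rows += [ia, ib, ia, ib]; cols += [ia, ib, ib, ia]
            vals += [tr.ravel(), tr.ravel(), -tr.ravel(), -tr.ravel()]
        cap = (der.rhocp_eff * V).ravel() / dt
        A = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n)).tolil()
        A.setdiag(A.diagonal() + cap)
        b = cap * state.T.ravel() + adv_src.ravel()
        if self.oven is not None:
            ov = self.oven
            if ov.wall_model == "coupled":
                if self.T_wall_bot is None:
                    self.T_wall_bot = float(ov.T_wall(0.0))
                    self.T_wall_side = float(ov.T_wall(0.0))
                Tw_bot, Tw_side = self.T_wall_bot, self.T_wall_side
            else:
                Tw_bot = Tw_side = float(ov.T_wall(t))
            A_top = grid.ring_areas
            top_cells = idx[:, -1]
            # top: implicit convection; radiation + evaporative cooling explicit
            hA = ov.h_c * A_top
            for ii, ha in zip(top_cells, hA):
                A[ii, ii] += ha
            b[top_cells] += hA * ov.T_air(t)
            T_top = state.T[:, -1]
            q_rad = p.emissivity * (ov.Phi(t)
                                    - con.STEFAN_BOLTZMANN * T_top ** 4)
            q_evap = j_l_b * con.latent_heat(T_top, p)
            b[top_cells] += (q_rad - q_evap) * A_top
            report.heat_in += float(((q_rad - q_evap) * A_top).sum() * dt)
            # bottom mold: implicit Robin through half-cell + contact in series
            bot_cells = idx[:, 0]
            lam_half = lam[:, 0] / (0.5 * grid.dz[:, 0])
            h_eff = 1.0 / (1.0 / ov.h_e + 1.0 / np.maximum(lam_half, 1e-30))
            hA_b = h_eff * A_top
            for ii, ha in zip(bot_cells, hA_b):
                A[ii, ii] += ha
            b[bot_cells] += hA_b * Tw_bot
            # side mold: every outer-column cell, area 2 pi R dz
            side_cells = idx[-1, :]
            A_side = 2.0 * np.pi * grid.radius * grid.dz[-1, :]
            dr_half = 0.5 * (grid.r_edges[-1] - grid.r_edges[-2]) if nr > 1 \
                else 0.5 * grid.radius
            h_eff_s = 1.0 / (1.0 / ov.h_e + dr_half / lam[-1, :])
            hA_s = h_eff_s * A_side
            for ii, ha in zip(side_cells, hA_s):
                A[ii, ii] += ha
            b[side_cells] += hA_s * Tw_side
        T_new = _spsolve(A.tocsr(), b).reshape(nr, nz)
        if self.oven is not None:
            ov = self.oven
            q_bot = float((hA_b * (Tw_bot - T_new[:, 0])).sum())      # W
            q_side = float((hA_s * (Tw_side - T_new[-1, :])).sum())
            report.heat_in += float(
                (ov.h_c * grid.ring_areas * (ov.T_air(t) - T_new[:, -1])).sum()
                * dt + (q_bot + q_side) * dt)
            if ov.wall_model == "coupled":
                # lumped glass-wall nodes: oven-side convection + cavity
                # radiation in, contact conduction to the dough out
                T_cav = float(ov.T_air(t))
                A_bot = float(A_top.sum())
                A_sd = max(float(A_side.sum()), 1e-12)
                for name, Tw, q_del, Aw in (("T_wall_bot", Tw_bot, q_bot, A_bot),
                                            ("T_wall_side", Tw_side, q_side, A_sd)):
                    q_sup = (ov.h_out * (T_cav - Tw)
                             + ov.eps_wall * con.STEFAN_BOLTZMANN
                             * (T_cav ** 4 - Tw ** 4))
                    setattr(self, name,
                            Tw + dt * (q_sup - q_del / Aw) / ov.C_wall)
        report.max_dT = float(np.max(np.abs(T_new - state.T)))
        state.T = T_new

    # -- full step ----------------------------------------------------------

    def step(self, state: FieldState, grid: Grid, t: float,
             dt: float) -> tuple[FieldState, Grid, StepReport]:
        """Advance all conserved fields by dt.  Returns new (state, grid)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        report = StepReport()
        der = derived_fields(state, self.params)
        if self.solver.mechanics_on:
            v, e, _p = solve_mechanics(state, der, grid, self.params,
                                       self.mech, dt)
            grid = move_mesh(grid, state, e, dt)
            report.max_strain = float(np.max(np.abs(e)) * dt)
            der = derived_fields(state, self.params)
        if self.solver.co2_source_on:
            self.co2_generation(state, der, dt)
        self.mpc_exchange(state, der, dt)
        der = derived_fields(state, self.params)
        self.liquid_fluxes(state, der, grid, dt)
        j_l_b = np.zeros(grid.nr)
        if self.oven is not None:
            j_l_b = self.surface_evaporation(state, der, grid, t, dt, report)
        der = derived_fields(state, self.params)
        self.species_diffusion(state, der, grid, t, dt, report)
        der = derived_fields(state, self.params)
        adv_src = self.darcy_vent(state, der, grid, t, dt, report)
        der = derived_fields(state, self.params)
        self.heat_step(state, der, grid, t, dt, j_l_b, adv_src, report)
        state.validate()
        return state, grid, report

    def pick_dt(self, state: FieldState, grid: Grid, dt_prev: float) -> float:
        """Heuristic adaptive step: bound per-step volume strain."""
        cfg = self.solver
        der = derived_fields(state, self.params)
        dt = min(dt_prev * 1.3, cfg.dt_max)
        if cfg.mechanics_on:
            _v, e, _p = solve_mechanics(state, der, grid, self.params,
                                        self.mech, dt)
            emax = float(np.max(np.abs(e)))
            if emax > 0:
                dt = min(dt, cfg.max_strain_step / emax)
        return max(dt, cfg.dt_min)


def gas_velocity(state: FieldState, grid: Grid, params: MaterialParams,
                 mode: str = "darcy", P: np.ndarray | None = None):
    """Vertical gas velocity on interior z-faces, m/s (positive upward).

    darcy: u = -(kappa/mu_g) dP/dz.  brinkman: per-column steady solve
    retaining the gas shear term mu_g d2u/dz2 (a small correction at
    kappa ~ 1e-11 m^2); falls back to u = 0 where the matrix is closed
    everywhere."""
    der = derived_fields(state, params)
    if P is None:
        P = der.P_g
    dz_f = 0.5 * (grid.dz[:, :-1] + grid.dz[:, 1:])
    kap_f = _harmonic(der.kappa_g[:, :-1], der.kappa_g[:, 1:])
    dPdz = (P[:, 1:] - P[:, :-1]) / dz_f
    u_darcy = -kap_f / params.mu_g * dPdz
    if mode == "darcy":
        return u_darcy
    if mode != "brinkman":
        raise ValueError("mode must be 'darcy' or 'brinkman'")
    u = np.zeros_like(u_darcy)
    for i in range(grid.nr):
        kf = kap_f[i]
        if not np.any(kf > 0):
            continue  # stagnant column: u = 0
        main = params.mu_g / np.maximum(kf, 1e-300)
        shear = params.mu_g / dz_f[i] ** 2
        A = (sp.diags(main + 2 * shear)
             - sp.diags(shear[:-1], 1) - sp.diags(shear[1:], -1)).tolil()
        rhs = -dPdz[i].copy()
        for jj in np.where(kf <= 0)[0]:
            A[jj, :] = 0.0
            A[jj, jj] = 1.0
            rhs[jj] = 0.0
        u[i] = spla.spsolve(A.tocsr(), rhs)
    return u


def run(state: FieldState, grid: Grid, sim: Simulator,
        probes=None, initial_volume: float | None = None,
        progress: bool = False):
    """Integrate to ``sim.solver.t_end`` with adaptive stepping.

    Returns ``(diag_rows, snapshots, budget)`` where diag_rows is a list of
    diagnostics dicts at the configured cadence, snapshots maps time ->
    (state copy, grid copy), and budget carries cumulative boundary fluxes
    and the water/solid conservation residuals."""
    cfg = sim.solver
    p = sim.params
    V0 = initial_volume if initial_volume is not None else float(grid.volumes.sum())
    if probes is None:
        probes = [make_probe(nm, r, z, grid) for nm, r, z in DEFAULT_PROBES]
    t = 0.0
    dt = cfg.dt_init
    rows = [diagnostics(state, grid, p, probes, V0, t)]
    water0 = rows[0]["liquid_mass"] + rows[0]["vapor_mass"]
    solid0 = rows[0]["solid_mass"]
    water_out_cum = 0.0
    co2_out_cum = 0.0
    next_diag = cfg.diag_interval
    snaps = {}
    snap_times = sorted(cfg.snapshot_times)
    si = 0
    while t < cfg.t_end - 1e-9:
        dt = min(sim.pick_dt(state, grid, dt), cfg.t_end - t)
        wall_save = (sim.T_wall_bot, sim.T_wall_side)
        for attempt in range(cfg.max_retries):
            trial_state = state.copy()
            trial_grid = grid.copy()
            sim.T_wall_bot, sim.T_wall_side = wall_save
            try:
                trial_state, trial_grid, rep = sim.step(trial_state, trial_grid,
                                                        t, dt)
            except FloatingPointError:
                dt = max(dt * 0.5, cfg.dt_min)
                continue
            if rep.max_dT > 4.0 * sim.solver.max_dT_step and dt > cfg.dt_min:
                dt = max(dt * 0.5, cfg.dt_min)
                continue
            break
        else:
            raise RuntimeError(f"step failed at t={t:.1f}s after retries")
        state, grid = trial_state, trial_grid
        water_out_cum += rep.water_out
        co2_out_cum += rep.co2_out
        t += dt
        if rep.max_dT > sim.solver.max_dT_step:
            dt = max(dt * 0.7, cfg.dt_min)
        while si < len(snap_times) and t >= snap_times[si] - 1e-9:
            snaps[snap_times[si]] = (state.copy(), grid.copy())
            si += 1
        if t >= next_diag - 1e-9 or t >= cfg.t_end - 1e-9:
            row = diagnostics(state, grid, p, probes, V0, t)
            water_now = row["liquid_mass"] + row["vapor_mass"]
            row["water_budget_residual"] = (
                (water_now - water0 + water_out_cum) / water0)
            row["water_out_cum"] = water_out_cum
            rows.append(row)
            next_diag += cfg.diag_interval
            if progress:
                print(f"t={t:7.1f}s dt={dt:6.3f} Tmin={row['T_min']-273.15:6.1f}C "
                      f"H={row['axis_height']*1000:5.1f}mm "
                      f"Ml={row['liquid_mass']*1000:6.1f}g", flush=True)
    budget = {
        "water_out_cum": water_out_cum,
        "co2_out_cum": co2_out_cum,
        "water_residual": rows[-1].get("water_budget_residual", 0.0),
        "solid_residual": (rows[-1]["solid_mass"] - solid0) / solid0,
    }
    return rows, snaps, budget
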