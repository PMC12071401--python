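"""Scenario configuration, reproducible runs and reports.

A :class:`Scenario` bundles geometry, initial conditions, material
parameters, the oven program (or its generator parameters), solver and
mechanics settings.  ``load_scenario`` reads a YAML file with strict key
checking (unknown keys are an error, so typos cannot silently fall back to
defaults); an empty file yields the default calibrated baking scenario:
100 mm mold, 20 mm dough at 28 C, W = 0.82, 1069 kg/m^3, 180 C oven
program, 1800 s bake.

``run_paper_scenario`` integrates the scenario and emits tidy diagnostics
(CSV), field snapshots (legacy-VTK ASCII in 2-D, CSV in 1-D) and a summary
JSON of the headline quantities; ``sweep`` repeats a run over values of one
registered scalar parameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialParams
from .fields import (FieldState, Grid, derived_fields, initialize, make_grid,
                     make_probe, DEFAULT_PROBES)
from .mechanics import MechanicsConfig
from .oven import OvenProgram, synth_oven_program, transfer_coefficients
from .transport import Simulator, SolverConfig, run


@dataclass
class OvenGenParams:
    """Parameters of the synthetic oven-program generator."""
    setpoint: float = 453.15        # oven air, K (180 C program)
    amplitude: float = 15.0         # relay oscillation amplitude, K
    period: float = 120.0           # s
    wall_setpoint: float = 413.15   # mold-wall plateau, K
    wall_amplitude: float = 8.0     # K
    wall_tau: float = 300.0         # mold warm-up time constant, s
    Phi: float = 1000.0             # effective radiation density, W/m^2
    C_oven_v: float = 0.5           # oven humidity, mol/m^3
    h_c: float = 10.0               # W/(m^2 K)
    h_e: float = 100.0              # W/(m^2 K)
    seed: int = 0


@dataclass
class Geometry:
    radius: float = 0.05
    height: float = 0.020

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("geometry must be positive")


@dataclass
class Initial:
    T0: float = 301.15
    W0: float = 0.82
    rho_eff0: float = 1069.0


@dataclass
class MeshSpec:
    nr: int = 5
    nz: int = 14
    boundary_layer: float = 0.0


@dataclass
class Scenario:
    geometry: Geometry = field(default_factory=Geometry)
    initial: Initial = field(default_factory=Initial)
    params: MaterialParams = field(default_factory=MaterialParams)
    oven_gen: OvenGenParams = field(default_factory=OvenGenParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    mesh: MeshSpec = field(default_factory=MeshSpec)
    probes: tuple = DEFAULT_PROBES

    def build_oven(self) -> OvenProgram:
        g = self.oven_gen
        h_c, h_m, h_co2 = transfer_coefficients(g.h_c, g.setpoint)
        return synth_oven_program(
            setpoint=g.setpoint, amplitude=g.amplitude, period=g.period,
            seed=g.seed, duration=self.solver.t_end,
            wall_setpoint=g.wall_setpoint, wall_amplitude=g.wall_amplitude,
            wall_tau=g.wall_tau, T_mold0=self.initial.T0, Phi=g.Phi,
            C_oven_v=g.C_oven_v, h_c=h_c, h_m=h_m, h_co2=h_co2, h_e=g.h_e)


def _apply_overrides(obj, data: dict, path: str):
    names = {f.name for f in _dc_fields(obj)}
    for key, val in data.items():
        if key not in names:
            raise KeyError(f"unknown scenario key {path}{key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply_overrides(cur, val, f"{path}{key}.")
        else:
            setattr(obj, key, type(cur)(val) if isinstance(cur, (int, float))
                    else val)
    return obj


def load_scenario(path: str | Path | None = None,
                  overrides: dict | None = None) -> Scenario:
    """Load a YAML scenario; empty/missing content gives all defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("scenario file must contain a mapping")
    if overrides:
        data = {**data, **overrides}
    sc = Scenario()
    _apply_overrides(sc, data, "")
    # re-run validation of nested dataclasses
    sc.params.__post_init__()
    sc.geometry.__post_init__()
    sc.solver.__post_init__()
    sc.mechanics.__post_init__()
    return sc


def scenario_to_yaml(sc: Scenario) -> str:
    """Echo the fully resolved scenario (defaults applied) as YAML, with the
    per-parameter provenance tags {paper, fitted, literature} alongside."""
    d = dataclasses.asdict(sc)
    d["probes"] = [list(p) for p in sc.probes]
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)


MESH_LEVELS = {
    0: {"axial1d": (1, 14), "axisym2d": (4, 12)},
    1: {"axial1d": (1, 20), "axisym2d": (5, 16)},
    2: {"axial1d": (1, 30), "axisym2d": (7, 24)},
    3: {"axial1d": (1, 44), "axisym2d": (10, 34)},
}


def _summary_from_rows(rows: list[dict], budget: dict) -> dict:
    df = pd.DataFrame(rows)
    m0 = df["liquid_mass"].iloc[0]
    closed = df[df["closed_fraction"] > 0]
    open_time = (float(df.loc[df["closed_fraction"] <= 0, "t"].iloc[0])
                 if (df["closed_fraction"] <= 0).any() else np.nan)
    vf = closed["closed_vapor_molfrac"].dropna()
    # first crossing of 80% vapor in the closed-pore gas
    above = closed[closed["closed_vapor_molfrac"] >= 0.80]
    t80 = float(above["t"].iloc[0]) if len(above) else np.nan
    t_done = df[df["T_min"] >= 366.15]
    late = df[df["t"] > 900.0]
    peak_i = int(df["P1_gauge"].idxmax()) if "P1_gauge" in df else 0
    summary = {
        "liquid_loss_g": float((m0 - df["liquid_mass"].iloc[-1]) * 1000.0),
        "initial_liquid_g": float(m0 * 1000.0),
        "max_axis_height_mm": float(df["axis_height"].max() * 1000.0),
        "side_height_plateau_mm": float(
            (late if len(late) else df)["side_height"].mean() * 1000.0),
        "peak_P1_gauge_Pa": float(df["P1_gauge"].max()) if "P1_gauge" in df else np.nan,
        "peak_P1_time_s": float(df["t"].iloc[peak_i]) if "P1_gauge" in df else np.nan,
        "t_done_93C_s": float(t_done["t"].iloc[0]) if len(t_done) else np.nan,
        "closed_vapor_molfrac_mean": float(np.trapezoid(vf, closed["t"].iloc[:len(vf)])
                                           / (closed["t"].iloc[len(vf) - 1]
                                              - closed["t"].iloc[0]))
        if len(vf) > 1 else float(vf.mean()) if len(vf) else np.nan,
        "t_vapor80_s": t80,
        "full_open_time_s": open_time,
        "max_edc_share": float(closed["closed_edc_share_max"].max())
        if len(closed) else np.nan,
        "final_volume_ratio": float(df["volume_ratio"].iloc[-1]),
        "max_crumb_W": float(df["W_crumb_max"].max()),
        "water_budget_residual": float(budget["water_residual"]),
        "solid_budget_residual": float(budget["solid_residual"]),
    }
    return summary


def run_paper_scenario(mode: str = "axial1d", mesh_level: int = 1,
                       scenario: Scenario | None = None,
                       out_dir: str | Path | None = None,
                       seed: int | None = None,
                       progress: bool = False) -> dict:
    """Run the default (or a given) scenario and return the report.

    The report holds the summary dict, the diagnostics DataFrame, the
    snapshots and the conservation budget.  ``seed`` overrides the oven
    generator seed."""
    sc = scenario or Scenario()
    if seed is not None:
        sc.oven_gen.seed = int(seed)
    nr, nz = MESH_LEVELS[int(mesh_level)][mode]
    if scenario is not None and (sc.mesh.nr, sc.mesh.nz) != (5, 14):
        nr, nz = (1 if mode == "axial1d" else sc.mesh.nr), sc.mesh.nz
    grid = make_grid(sc.geometry.radius, sc.geometry.height, nr, nz, mode,
                     sc.mesh.boundary_layer)
    state = initialize(grid, sc.params, sc.initial.T0, sc.initial.W0,
                       sc.initial.rho_eff0)
    oven = sc.build_oven()
    sim = Simulator(sc.params, sc.solver, sc.mechanics, oven)
    probes = [make_probe(nm, r, z, grid) for nm, r, z in sc.probes]
    rows, snaps, budget = run(state, grid, sim, probes, progress=progress)
    summary = _summary_from_rows(rows, budget)
    summary["mode"] = mode
    summary["mesh"] = [nr, nz]
    report = {"summary": summary, "diagnostics": pd.DataFrame(rows),
              "snapshots": snaps, "budget": budget,
              "state": state, "grid": grid}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "scenario_resolved.yaml").write_text(scenario_to_yaml(sc))
        report["diagnostics"].to_csv(out / "diagnostics.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float))
        oven.to_frame().to_csv(out / "oven_program.csv", index=False)
        for t_snap, (st, gr) in snaps.items():
            stem = f"snapshot_{int(t_snap):04d}"
            if mode == "axisym2d":
                write_vtk(out / f"{stem}.vtk", st, gr, sc.params)
            else:
                write_snapshot_csv(out / f"{stem}.csv", st, gr, sc.params)
    return report


SWEEPABLE = {
    "T_open": ("params", "T_open"),
    "dT_open": ("params", "dT_open"),
    "T_tra": ("params", "T_tra"),
    "dT_tra": ("params", "dT_tra"),
    "k_mpc_open": ("params", "k_mpc_open"),
}


def sweep(parameter: str, values, mode: str = "axial1d",
          mesh_level: int = 0, scenario: Scenario | None = None,
          progress: bool = False) -> pd.DataFrame:
    """One run per value of a registered scalar parameter; summary table."""
    if parameter not in SWEEPABLE:
        raise KeyError(f"{parameter!r} is not a registered sweep parameter; "
                       f"choose from {sorted(SWEEPABLE)}")
    section, name = SWEEPABLE[parameter]
    out = []
    for v in values:
        sc = scenario or Scenario()
        sc = dataclasses.replace(sc)
        setattr(getattr(sc, section), name, float(v))
        if name == "k_mpc_open" and v >= sc.params.k_mpc_closed:
            sc.params.k_mpc_closed = float(v) + 1e-6
        rep = run_paper_scenario(mode, mesh_level, scenario=sc,
                                 progress=progress)
        row = {parameter: float(v), **rep["summary"]}
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# snapshot writers (text formats only)
# ---------------------------------------------------------------------------

def _snapshot_fields(state: FieldState, params: MaterialParams):
    d = derived_fields(state, params)
    return {
        "temperature_K": state.T, "moisture_W": d.W, "porosity": d.f_vg,
        "pressure_Pa": d.P_g, "vapor_molfrac": d.P_v / d.P_g,
        "alpha_open": d.alpha, "liquid_density": state.rho_l_bar,
    }


def write_snapshot_csv(path, state: FieldState, grid: Grid,
                       params: MaterialParams) -> None:
    data = {"z_m": grid.z_centers.ravel()}
    data.update({k: v.ravel() for k, v in
                 _snapshot_fields(state, params).items()})
    pd.DataFrame(data).to_csv(path, index=False)


def write_vtk(path, state: FieldState, grid: Grid,
              params: MaterialParams) -> None:
    """Minimal legacy-VTK (ASCII structured grid) writer for the (r, z) plane."""
    nr, nz = grid.nr, grid.nz
    r_nodes = np.tile(grid.r_edges[:, None], (1, nz + 1))
    # node z: column edges extended to node rings by averaging neighbours
    z_cols = grid.z_edges
    z_nodes = np.empty((nr + 1, nz + 1))
    z_nodes[0] = z_cols[0]
    z_nodes[-1] = z_cols[-1]
    for i in range(1, nr):
        z_nodes[i] = 0.5 * (z_cols[i - 1] + z_cols[i])
    lines = ["# vtk DataFile Version 3.0", "crumbsim snapshot", "ASCII",
             "DATASET STRUCTURED_GRID",
             f"DIMENSIONS {nz + 1} {nr + 1} 1",
             f"POINTS {(nr + 1) * (nz + 1)} float"]
    for i in range(nr + 1):
        for k in range(nz + 1):
            lines.append(f"{r_nodes[i, k]:.6e} {z_nodes[i, k]:.6e} 0.0")
    lines.append(f"CELL_DATA {nr * nz}")
    for name, arr in _snapshot_fields(state, params).items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6e}" for v in arr.ravel())
    Path(path).write_text("\n".join(lines) + "\n")
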