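"""Configuration loading, validation, presets, and result serialization.

The config dialect is a flat YAML document with explicit unit suffixes on
every key (``_cm``, ``_mm``, ``_C``, ``_s``, ...) so a value can never be
misread; everything is converted to SI meters/seconds/degC internally.
Unknown keys are rejected with their full path.  The packaged defaults
reproduce the liver tissue table, the probe material table, and the damage
constants of the underlying model bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import SimulationGrid, AxisymmetricGrid
from .morphometry import compute_metrics
from .probes import LoadCurve, make_layout
from .solver import SolverConfig, simulate
from .tissue import DamageParams, ProbeMaterialParams, TissueParams, frozen_fraction
from .vtk_io import write_vtk

__all__ = [
    "ConfigError",
    "RunConfiguration",
    "RunManifest",
    "DEFAULT_CONFIG",
    "PRESETS",
    "load_config",
    "resolve_config",
    "preset",
    "simulate_from_config",
    "write_outputs",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


DEFAULT_CONFIG: dict = {
    "tissue": {
        "k_liquid_W_mC": 0.5,
        "k_frozen_W_mC": 2.0,
        "c_liquid_J_kgC": 3600.0,
        "c_frozen_J_kgC": 1800.0,
        "rho_liquid_kg_m3": 1000.0,
        "rho_frozen_kg_m3": 998.0,
        "latent_heat_MJ_m3": 250.0,
        "T_upper_C": -1.0,
        "T_lower_C": -8.0,
        "perfusion_rate_per_s": 0.0005,
        "rho_blood_kg_m3": 1000.0,
        "c_blood_J_kgC": 3600.0,
        "T_blood_C": 37.0,
        "metabolic_W_m3": 4200.0,
    },
    "damage": {
        "threshold_C": -20.0,
        "time_s": 60.0,
        "necrosis_C": -50.0,
        "enthalpy_kJ_kg": 250.0,
    },
    "probe_materials": {
        "nitinol": {"k_W_mC": 21.9, "rho_kg_m3": 4506.0, "c_J_kgC": 522.0},
        "insulation": {"k_W_mC": 0.18, "rho_kg_m3": 930.0, "c_J_kgC": 1900.0},
    },
    "layout": {"pattern": "single", "spacing_cm": 1.0},
    "probe": {"depth_cm": 2.0, "active_length_cm": 2.0, "radius_mm": 0.85},
    "loadcurve": {
        "start_C": 25.0,
        "plateau_C": -150.0,
        "ramp_s": 60.0,
        "freeze_s": 900.0,
        "thaw_C": 20.0,
        "thaw_s": 240.0,
    },
    "grid": {
        "mode": "cartesian",
        "spacing_mm": 1.0,
        "extent_x_cm": 8.0,
        "extent_y_cm": 8.0,
        "extent_z_cm": 8.0,
        "extent_r_cm": 2.5,
    },
    "solver": {
        "dt_s": 0.5,
        "end_time_s": 900.0,
        "initial_C": 37.0,
        "frozen_shutdown": True,
        "apply_damage_enthalpy": False,
        "damage_property_mixing": False,
        "linear_tol": 1.0e-10,
        "picard_tol": 1.0e-3,
        "output_cadence_s": 100.0,
        "trace_interval_s": 1.0,
        "method": "implicit",
    },
    # the four-channel bench layout: at the main probe, 5 mm out, at an
    # auxiliary probe position, and a distal reference
    "monitors_cm": [[0.1, 0.0, -1.0], [0.5, 0.0, -1.0], [1.0, 0.0, -1.0], [2.0, 0.0, -1.0]],
}

#: Scenario presets: bench phantoms start at room temperature (25 degC),
#: the liver scenario at body-core temperature (37 degC).  All use a 2 cm
#: insertion and, for multi-probe patterns, 1 cm spacing and 900 s freezing.
PRESETS: dict = {
    "phantom-single": {
        "layout": {"pattern": "single"},
        "grid": {"mode": "axisymmetric", "spacing_mm": 1.0,
                 "extent_r_cm": 2.5, "extent_z_cm": 4.5},
        "solver": {"initial_C": 25.0, "end_time_s": 900.0},
    },
    "phantom-five": {
        "layout": {"pattern": "five", "spacing_cm": 1.0},
        "grid": {"mode": "cartesian", "spacing_mm": 2.0,
                 "extent_x_cm": 6.5, "extent_y_cm": 6.5, "extent_z_cm": 4.0},
        "solver": {"initial_C": 25.0, "end_time_s": 900.0, "dt_s": 2.0},
    },
    "phantom-seven": {
        "layout": {"pattern": "seven", "spacing_cm": 1.0},
        "grid": {"mode": "cartesian", "spacing_mm": 2.0,
                 "extent_x_cm": 6.5, "extent_y_cm": 6.5, "extent_z_cm": 4.0},
        "solver": {"initial_C": 25.0, "end_time_s": 900.0, "dt_s": 2.0},
    },
    "phantom-nine": {
        "layout": {"pattern": "nine", "spacing_cm": 1.0},
        "grid": {"mode": "cartesian", "spacing_mm": 2.0,
                 "extent_x_cm": 6.5, "extent_y_cm": 6.5, "extent_z_cm": 4.0},
        "solver": {"initial_C": 25.0, "end_time_s": 900.0, "dt_s": 2.0},
    },
    "liver-nine": {
        "layout": {"pattern": "nine", "spacing_cm": 1.0},
        "grid": {"mode": "cartesian", "spacing_mm": 2.0,
                 "extent_x_cm": 6.5, "extent_y_cm": 6.5, "extent_z_cm": 4.0},
        "solver": {"initial_C": 37.0, "end_time_s": 900.0, "dt_s": 2.0},
    },
}


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = {k: v for k, v in base.items()}
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _deep_merge(base[key], val, here)
        else:
            out[key] = val
    return out


def _require_number(cfg: dict, section: str, key: str) -> float:
    val = cfg[section][key]
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        raise ConfigError(f"{section}.{key} must be a number, got {val!r}")
    return float(val)


@dataclass
class RunConfiguration:
    """A fully resolved, validated simulation setup (all SI internally)."""

    raw: dict
    tissue: TissueParams
    damage: DamageParams
    load_curve: LoadCurve
    layout: object
    grid: object
    solver: SolverConfig
    monitors: tuple
    probe_materials: dict

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


def resolve_config(user: dict | None = None, base_preset: str | None = None) -> RunConfiguration:
    """Merge user keys over (preset over) defaults, validate, and build objects."""
    cfg = DEFAULT_CONFIG
    user = dict(user or {})
    name = user.pop("preset", base_preset)
    if name is not None:
        if name not in PRESETS:
            raise ConfigError(
                f"unknown preset '{name}'; available: {sorted(PRESETS)}"
            )
        cfg = _deep_merge(cfg, PRESETS[name])
    cfg = _deep_merge(cfg, user)

    t = cfg["tissue"]
    try:
        tissue = TissueParams(
            k_u=_require_number(cfg, "tissue", "k_liquid_W_mC"),
            k_f=_require_number(cfg, "tissue", "k_frozen_W_mC"),
            c_u=_require_number(cfg, "tissue", "c_liquid_J_kgC"),
            c_f=_require_number(cfg, "tissue", "c_frozen_J_kgC"),
            rho_u=_require_number(cfg, "tissue", "rho_liquid_kg_m3"),
            rho_f=_require_number(cfg, "tissue", "rho_frozen_kg_m3"),
            Q_lf=_require_number(cfg, "tissue", "latent_heat_MJ_m3") * 1e6,
            T_mu=_require_number(cfg, "tissue", "T_upper_C"),
            T_ml=_require_number(cfg, "tissue", "T_lower_C"),
            w_b=_require_number(cfg, "tissue", "perfusion_rate_per_s"),
            rho_b=_require_number(cfg, "tissue", "rho_blood_kg_m3"),
            c_b=_require_number(cfg, "tissue", "c_blood_J_kgC"),
            T_b=_require_number(cfg, "tissue", "T_blood_C"),
            Q_m=_require_number(cfg, "tissue", "metabolic_W_m3"),
        )
    except ValueError as exc:
        raise ConfigError(f"tissue: {exc}") from exc

    try:
        damage = DamageParams(
            T_dc=_require_number(cfg, "damage", "threshold_C"),
            t_dc=_require_number(cfg, "damage", "time_s"),
            T_nc=_require_number(cfg, "damage", "necrosis_C"),
            L_dc=_require_number(cfg, "damage", "enthalpy_kJ_kg") * 1e3,
            apply_damage_enthalpy=bool(cfg["solver"]["apply_damage_enthalpy"]),
        )
    except ValueError as exc:
        raise ConfigError(f"damage: {exc}") from exc

    try:
        lc = LoadCurve(
            start_temperature=_require_number(cfg, "loadcurve", "start_C"),
            plateau_temperature=_require_number(cfg, "loadcurve", "plateau_C"),
            ramp_duration=_require_number(cfg, "loadcurve", "ramp_s"),
            freeze_duration=_require_number(cfg, "loadcurve", "freeze_s"),
            thaw_target_temperature=_require_number(cfg, "loadcurve", "thaw_C"),
            thaw_duration=_require_number(cfg, "loadcurve", "thaw_s"),
        )
    except ValueError as exc:
        raise ConfigError(f"loadcurve: {exc}") from exc

    spacing = _require_number(cfg, "grid", "spacing_mm") * 1e-3
    mode = cfg["grid"]["mode"]
    depth = _require_number(cfg, "probe", "depth_cm") * 1e-2
    radius = _require_number(cfg, "probe", "radius_mm") * 1e-3
    active = _require_number(cfg, "probe", "active_length_cm") * 1e-2
    probe_spacing = _require_number(cfg, "layout", "spacing_cm") * 1e-2
    try:
        layout = make_layout(
            cfg["layout"]["pattern"], spacing=probe_spacing, depth=depth,
            active_length=active, radius=radius,
        )
    except ValueError as exc:
        raise ConfigError(f"layout: {exc}") from exc

    try:
        if mode == "axisymmetric":
            nr = int(round(_require_number(cfg, "grid", "extent_r_cm") * 1e-2 / spacing))
            nz = int(round(_require_number(cfg, "grid", "extent_z_cm") * 1e-2 / spacing))
            grid = AxisymmetricGrid(spacing=spacing, shape=(nr, nz), z_top=0.0)
        elif mode == "cartesian":
            grid = SimulationGrid.centered(
                (
                    _require_number(cfg, "grid", "extent_x_cm") * 1e-2,
                    _require_number(cfg, "grid", "extent_y_cm") * 1e-2,
                    _require_number(cfg, "grid", "extent_z_cm") * 1e-2,
                ),
                spacing,
            )
        else:
            raise ConfigError(f"grid.mode must be 'cartesian' or 'axisymmetric', got '{mode}'")
    except ValueError as exc:
        raise ConfigError(f"grid: {exc}") from exc
    if mode == "axisymmetric" and cfg["layout"]["pattern"] != "single":
        raise ConfigError("grid.mode axisymmetric requires layout.pattern 'single'")

    try:
        solver_cfg = SolverConfig(
            dt=_require_number(cfg, "solver", "dt_s"),
            end_time=_require_number(cfg, "solver", "end_time_s"),
            initial_temperature=_require_number(cfg, "solver", "initial_C"),
            frozen_shutdown=bool(cfg["solver"]["frozen_shutdown"]),
            apply_damage_enthalpy=bool(cfg["solver"]["apply_damage_enthalpy"]),
            damage_property_mixing=bool(cfg["solver"]["damage_property_mixing"]),
            linear_tol=_require_number(cfg, "solver", "linear_tol"),
            picard_tol=_require_number(cfg, "solver", "picard_tol"),
            output_cadence=_require_number(cfg, "solver", "output_cadence_s"),
            trace_interval=_require_number(cfg, "solver", "trace_interval_s"),
            method=str(cfg["solver"]["method"]),
        )
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    monitors = tuple(
        tuple(float(c) * 1e-2 for c in point) for point in cfg["monitors_cm"]
    )
    pm = cfg["probe_materials"]
    probe_materials = {
        name: ProbeMaterialParams(
            k=vals["k_W_mC"], rho=vals["rho_kg_m3"], c=vals["c_J_kgC"]
        )
        for name, vals in pm.items()
    }
    return RunConfiguration(
        raw=cfg, tissue=tissue, damage=damage, load_curve=lc, layout=layout,
        grid=grid, solver=solver_cfg, monitors=monitors,
        probe_materials=probe_materials,
    )


def load_config(path) -> RunConfiguration:
    """Load and validate a YAML config file (may name a ``preset`` to extend)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return resolve_config(data)


def preset(name: str) -> RunConfiguration:
    """Resolved configuration of a named scenario preset."""
    return resolve_config({}, base_preset=name)


def simulate_from_config(rc: RunConfiguration):
    """Run the simulation a RunConfiguration describes."""
    return simulate(
        rc.solver, rc.grid, rc.layout, rc.tissue, rc.damage,
        load_curve=rc.load_curve, monitors=rc.monitors,
    )


@dataclass
class RunManifest:
    """Reproducibility record: the resolved config re-runs the simulation bit-identically."""

    config: dict
    version: str
    timestamp: str
    config_digest: str
    outputs: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "timestamp": self.timestamp,
                "config_digest": self.config_digest,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def write_outputs(result, rc: RunConfiguration, out_dir, run_id: str = "run") -> RunManifest:
    """Serialize a finished run: VTK snapshots, CSV traces and metrics, JSON manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    files = []
    grid = result.grid
    if grid.ndim == 3:
        origin = tuple(np.asarray(grid.origin) + grid.spacing / 2.0)
    else:
        r, z = grid.axis_coords()
        origin = (float(r[0]), float(z[0]))
    for i, (t, snap) in enumerate(zip(result.snapshot_times, result.snapshots)):
        fname = out / f"{run_id}_t{i:04d}.vtk"
        write_vtk(
            fname,
            {
                "T_C": snap.T,
                "theta_d": snap.theta_d,
                "frozen_fraction": frozen_fraction(snap.T, result.tissue),
            },
            grid.spacing,
            origin,
            comment=f"{run_id} t={t:.3f}s",
        )
        files.append(fname.name)

    traces_path = out / f"{run_id}_traces.csv"
    result.traces.to_csv(traces_path, index=False, float_format="%.6g")
    files.append(traces_path.name)

    axis = (0.0, 0.0, -1.0)
    rows = [m.to_dict() for m in compute_metrics(result.final.T, grid, probe_axis=axis)]
    metrics_path = out / f"{run_id}_metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False, float_format="%.6g")
    files.append(metrics_path.name)

    manifest = RunManifest(
        config=rc.raw,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config_digest=rc.digest(),
        outputs=sorted(files),
    )
    (out / f"{run_id}_manifest.json").write_text(manifest.to_json())
    return manifest
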