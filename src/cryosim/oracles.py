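"""Closed-form references that verify the solver without external data.

Three independent checks of the same physics the solver discretizes:

* the two-phase Neumann (Stefan) similarity solution for a planar freezing
  front advancing into initially warm tissue from a cold wall;
* the exact relaxation of a conduction-free, perfused tissue cell toward its
  perfusion/metabolism steady state;
* a grid-refinement harness demonstrating mesh convergence of a monitor-point
  temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf, erfc

from .grids import Grid1D, AxisymmetricGrid
from .probes import LoadCurve, make_layout
from .solver import SolverConfig, simulate
from .tissue import TissueParams

__all__ = [
    "StefanSetup",
    "neumann_lambda",
    "stefan_front_position",
    "lumped_perfusion_temperature",
    "run_grid_convergence",
]


@dataclass(frozen=True)
class StefanSetup:
    """Planar two-phase freezing problem: cold wall, warm half-space.

    The wall at x=0 is held at ``wall_temperature``; tissue initially at
    ``initial_temperature`` freezes at the sharp front temperature
    ``freeze_temperature`` (the mushy interval is idealized to zero width).
    Frozen/unfrozen properties are taken from ``tissue``; perfusion and
    metabolism are ignored (the similarity solution has no volumetric terms).
    """

    wall_temperature: float
    initial_temperature: float
    freeze_temperature: float
    tissue: TissueParams
    domain_length: float = 0.1

    def __post_init__(self) -> None:
        if not self.wall_temperature < self.freeze_temperature < self.initial_temperature:
            raise ValueError(
                "require wall_temperature < freeze_temperature < initial_temperature"
            )


def _stefan_residual(lam: float, s: StefanSetup) -> float:
    """Interface energy-balance residual of the similarity ansatz x = 2 lam sqrt(kappa_s t)."""
    p = s.tissue
    k_s, k_l = p.k_f, p.k_u
    kap_s = p.k_f / (p.rho_f * p.c_f)
    kap_l = p.k_u / (p.rho_u * p.c_u)
    dT_s = s.freeze_temperature - s.wall_temperature
    dT_l = s.initial_temperature - s.freeze_temperature
    nu = np.sqrt(kap_s / kap_l)
    conduction_solid = k_s * dT_s * np.exp(-lam**2) / (np.sqrt(np.pi * kap_s) * erf(lam))
    conduction_liquid = (
        k_l * dT_l * np.exp(-(lam * nu) ** 2)
        / (np.sqrt(np.pi * kap_l) * erfc(lam * nu))
    )
    latent = p.Q_lf * lam * np.sqrt(kap_s)
    return conduction_solid - conduction_liquid - latent


def neumann_lambda(setup: StefanSetup) -> float:
    """Root of the two-phase Neumann transcendental equation (bracketed, 1e-10)."""
    lo, hi = 1e-8, 5.0
    f_lo = _stefan_residual(lo, setup)
    f_hi = _stefan_residual(hi, setup)
    if f_lo * f_hi > 0:
        raise ValueError("no bracketed root: unphysical Stefan parameters")
    return float(brentq(_stefan_residual, lo, hi, args=(setup,), xtol=1e-10, rtol=1e-12))


def stefan_front_position(setup: StefanSetup, t: float) -> float:
    """Freezing-front position x(t) = 2 lambda sqrt(kappa_f t), m."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return 0.0
    lam = neumann_lambda(setup)
    kap_s = setup.tissue.k_f / (setup.tissue.rho_f * setup.tissue.c_f)
    return float(2.0 * lam * np.sqrt(kap_s * t))


def lumped_perfusion_temperature(t, tissue: TissueParams, T0: float):
    """Exact conduction-free Pennes relaxation, degC.

    With k = 0 every cell obeys rho c dT/dt = w_b rho_b c_b (T_b - T) + Q_m,
    whose solution relaxes exponentially to the steady state
    T_ss = T_b + Q_m / (w_b rho_b c_b).  For w_b = 0 the temperature drifts
    linearly under the metabolic term alone.
    """
    t = np.asarray(t, dtype=float)
    rc = tissue.rho_u * tissue.c_u
    a = tissue.w_b * tissue.rho_b * tissue.c_b
    if a == 0:
        out = T0 + tissue.Q_m / rc * t
    else:
        T_ss = tissue.T_b + tissue.Q_m / a
        out = T_ss + (T0 - T_ss) * np.exp(-a * t / rc)
    if np.ndim(t) == 0:
        return float(out)
    return out


def run_grid_convergence(
    spacings,
    *,
    tissue: TissueParams = None,
    load_curve: LoadCurve | None = None,
    end_time: float = 300.0,
    initial_temperature: float = 37.0,
    monitor_offset: float = 0.0048,
    domain_r: float = 0.024,
    domain_depth: float = 0.0432,
    probe_depth: float = 0.0216,
    probe_radius: float = 0.0024,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Mesh-independence study on a reduced axisymmetric single-probe domain.

    Runs the same freeze at each grid spacing (descending, m) and reports the
    temperature at a fixed probe-relative monitor (``monitor_offset`` m
    axially beyond the tip, on the axis) at ``end_time``, plus successive
    differences between refinements.

    The probe radius must be representable on every tested grid (the default
    geometry is commensurate with the conventional 2.4/1.2/0.6 mm ladder):
    a probe thinner than a cell would otherwise snap to a single column, so
    its effective radius — and with it the whole thermal problem — would
    change between resolutions, masking mesh convergence behind a geometry
    artifact.
    """
    spacings = list(spacings)
    if any(b >= a for a, b in zip(spacings, spacings[1:])):
        raise ValueError("spacings must be strictly descending")
    if any(h > probe_radius + 1e-12 for h in spacings):
        raise ValueError(
            "every spacing must be <= probe_radius so the rasterized probe "
            "geometry is identical on all grids"
        )
    if tissue is None:
        tissue = TissueParams()
    if load_curve is None:
        load_curve = LoadCurve()
    monitor_z = -(probe_depth + monitor_offset)
    if monitor_z <= -domain_depth:
        raise ValueError("monitor point lies outside the reduced domain")
    temps = []
    for h in spacings:
        nr = max(3, int(round(domain_r / h)))
        nz = max(3, int(round(domain_depth / h)))
        grid = AxisymmetricGrid(spacing=h, shape=(nr, nz), z_top=0.0)
        layout = make_layout("single", depth=probe_depth, radius=probe_radius)
        cfg = SolverConfig(
            dt=dt, end_time=end_time, initial_temperature=initial_temperature,
            output_cadence=end_time, trace_interval=end_time,
        )
        res = simulate(cfg, grid, layout, tissue,
                       load_curve=load_curve, monitors=((0.0, monitor_z),))
        temps.append(float(res.traces.iloc[-1]["T_p0_C"]))
    df = pd.DataFrame({"spacing_m": spacings, "T_monitor_C": temps})
    df["delta_T_C"] = df["T_monitor_C"].diff().abs()
    return df
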