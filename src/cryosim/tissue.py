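"""Temperature-dependent thermophysical properties of freezing tissue.

The tissue is modelled as a homogeneous medium that passes through three
states as it cools: liquid (unfrozen) above the upper phase-transition
temperature ``T_mu``, a solid-liquid mushy mixture between ``T_ml`` and
``T_mu``, and fully frozen solid below ``T_ml``.  Latent heat of freezing is
represented with the effective heat capacity method: the volumetric heat
capacity is augmented by ``Q_lf / (T_mu - T_ml)`` across the mushy interval,
so that integrating the capacity through the interval releases exactly the
latent heat ``Q_lf`` in addition to the sensible heat.

All property functions are vectorized over temperature arrays and work in
volumetric heat capacity (J/(m^3.degC)) to keep the latent-heat bookkeeping
dimensionally consistent (the latent heat is tabulated per unit volume).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TissueParams",
    "DamageParams",
    "ProbeMaterialParams",
    "LIVER",
    "NITINOL",
    "POLYURETHANE",
    "frozen_fraction",
    "conductivity",
    "density",
    "volumetric_heat_capacity",
    "perfusion_metabolic_source",
]


@dataclass(frozen=True)
class TissueParams:
    """Thermophysical constants of the tissue in its two phases.

    Units: conductivities W/(m.degC), specific heats J/(kg.degC), densities
    kg/m^3, latent heat J/m^3, temperatures degC, perfusion rate 1/s,
    metabolic heat W/m^3.  ``_u`` marks the unfrozen (liquid) phase, ``_f``
    the frozen (solid) phase.
    """

    k_u: float = 0.5
    k_f: float = 2.0
    c_u: float = 3600.0
    c_f: float = 1800.0
    rho_u: float = 1000.0
    rho_f: float = 998.0
    Q_lf: float = 250e6
    T_mu: float = -1.0
    T_ml: float = -8.0
    w_b: float = 0.0005
    rho_b: float = 1000.0
    c_b: float = 3600.0
    T_b: float = 37.0
    Q_m: float = 4200.0

    def __post_init__(self) -> None:
        if not self.T_ml < self.T_mu:
            raise ValueError(
                f"phase-transition interval is inverted: T_ml={self.T_ml} "
                f"must be below T_mu={self.T_mu}"
            )
        for name in ("k_u", "k_f", "c_u", "c_f", "rho_u", "rho_f", "Q_lf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.w_b < 0:
            raise ValueError("w_b must be non-negative")
        if self.Q_m < 0:
            raise ValueError("Q_m must be non-negative")

    @property
    def mushy_width(self) -> float:
        return self.T_mu - self.T_ml

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DamageParams:
    """Threshold/time damage kinetics constants.

    Tissue held below the damage threshold ``T_dc`` accumulates injury at the
    constant rate ``1/t_dc``; the damage fraction saturates at 1.  ``T_nc`` is
    the necrosis temperature below which death is immediate in the threshold
    picture, and ``L_dc`` an optional damage enthalpy released as the damage
    fraction advances (off by default: the latent heat of freezing already
    enters through the effective heat capacity, and enabling both would
    release it twice).
    """

    T_dc: float = -20.0
    t_dc: float = 60.0
    T_nc: float = -50.0
    L_dc: float = 250e3
    apply_damage_enthalpy: bool = False

    def __post_init__(self) -> None:
        if not self.t_dc > 0:
            raise ValueError("t_dc must be strictly positive")
        if self.T_nc > self.T_dc:
            raise ValueError(
                f"necrosis temperature T_nc={self.T_nc} must not exceed "
                f"damage threshold T_dc={self.T_dc}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProbeMaterialParams:
    """Conductivity / density / specific heat of a probe construction material."""

    k: float
    rho: float
    c: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.rho > 0 and self.c > 0):
            raise ValueError("probe material parameters must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


#: Packaged default tissue parameter set (liver-like, used for all scenarios).
LIVER = TissueParams()

#: Shape-memory alloy of the probe shaft.
NITINOL = ProbeMaterialParams(k=21.9, rho=4506.0, c=522.0)

#: Polyurethane insulation sleeve.
POLYURETHANE = ProbeMaterialParams(k=0.18, rho=930.0, c=1900.0)


def _check_finite(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature input contains non-finite values")
    return T


def frozen_fraction(T, p: TissueParams = LIVER):
    """Solid mass fraction at temperature ``T``.

    0 above ``T_mu``, 1 below ``T_ml``, linear ramp across the mushy interval
    (the field convention matching a constant effective-capacity plateau).
    """
    T = _check_finite(T)
    f = (p.T_mu - T) / p.mushy_width
    return np.clip(f, 0.0, 1.0)


def _piecewise(T, p: TissueParams, liquid, mushy, frozen):
    """Three-branch piecewise evaluation; the mushy branch is inclusive at both ends."""
    T = _check_finite(T)
    out = np.full(np.shape(T), mushy, dtype=float)
    out = np.where(T > p.T_mu, liquid, out)
    out = np.where(T < p.T_ml, frozen, out)
    if np.ndim(T) == 0:
        return float(out)
    return out


def conductivity(T, p: TissueParams = LIVER):
    """Thermal conductivity k(T), W/(m.degC): k_u / mean / k_f by phase."""
    return _piecewise(T, p, p.k_u, 0.5 * (p.k_u + p.k_f), p.k_f)


def density(T, p: TissueParams = LIVER):
    """Density rho(T), kg/m^3: rho_u / mean / rho_f by phase."""
    return _piecewise(T, p, p.rho_u, 0.5 * (p.rho_u + p.rho_f), p.rho_f)


def volumetric_heat_capacity(T, p: TissueParams = LIVER):
    """Effective volumetric heat capacity rho(T)*c(T), J/(m^3.degC).

    In the mushy interval the latent heat is smeared as
    ``Q_lf / (T_mu - T_ml)`` on top of the mean sensible capacity, so that

        integral of capacity over [T_ml, T_mu]
            = rho_bar * (c_u + c_f)/2 * (T_mu - T_ml) + Q_lf

    exactly (latent-heat conservation).
    """
    rho_bar = 0.5 * (p.rho_u + p.rho_f)
    mushy = rho_bar * 0.5 * (p.c_u + p.c_f) + p.Q_lf / p.mushy_width
    return _piecewise(T, p, p.rho_u * p.c_u, mushy, p.rho_f * p.c_f)


def volumetric_enthalpy(T, p: TissueParams = LIVER):
    """Volumetric enthalpy H(T) = integral of the effective capacity, J/m^3.

    Zero reference at ``T_ml``.  Piecewise linear with the three capacity
    plateaus; continuous everywhere.  The solver uses the chord slope of this
    function as its effective capacity so that no part of the latent heat can
    be skipped when a time step crosses the mushy interval.
    """
    T = _check_finite(T)
    rho_bar = 0.5 * (p.rho_u + p.rho_f)
    c_mushy = rho_bar * 0.5 * (p.c_u + p.c_f) + p.Q_lf / p.mushy_width
    c_liq = p.rho_u * p.c_u
    c_sol = p.rho_f * p.c_f
    H_mu = c_mushy * p.mushy_width  # enthalpy at T_mu
    out = np.where(
        T > p.T_mu,
        H_mu + c_liq * (T - p.T_mu),
        np.where(T < p.T_ml, c_sol * (T - p.T_ml), c_mushy * (T - p.T_ml)),
    )
    if np.ndim(T) == 0:
        return float(out)
    return out


def perfusion_metabolic_source(T, p: TissueParams = LIVER, frozen_shutdown: bool = True):
    """Blood perfusion plus metabolic volumetric heat source, W/m^3.

    Returns ``w_b*rho_b*c_b*(T_b - T) + Q_m``, optionally scaled by the local
    liquid fraction ``1 - frozen_fraction(T)`` (frozen tissue neither perfuses
    nor metabolizes; ``frozen_shutdown=False`` restores the unscaled Pennes
    source).
    """
    T = _check_finite(T)
    src = p.w_b * p.rho_b * p.c_b * (p.T_b - T) + p.Q_m
    if frozen_shutdown:
        src = src * (1.0 - frozen_fraction(T, p))
    if np.ndim(T) == 0:
        return float(src)
    return src
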