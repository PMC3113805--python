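"""Canopy energy budget, evaporative flow, and canopy albedo.

The canopy absorbs shortwave radiation (Beer–Lambert attenuation through the
leaf area index) plus ambient longwave at air temperature, and sheds energy
as emitted thermal radiation, sensible heat, and latent heat:

    R_abs = A_L * eps * sigma * T_L^4
          + A_H * c_p * g_Ha * (T_L - T_air)
          + A_E * lambda * g_v * (e_s(T_L) - e_a) / p_air

Each effective area A_X is a configurable multiple of the one-sided total
leaf area (two-sided thermal emission and sensible exchange, one evaporating
side by default).  The left side is independent of canopy temperature and
the right side strictly increasing in it, so the balance has a unique root;
it is found by Newton iteration with an analytic derivative and a bisection
fallback on the asserted bracket [T_air - 40, T_air + 40] degC.

The evaporative molar flux E (mol m^-2 s^-1) at that root, times the
evaporating area and the molar volume of liquid water, is the transpiration
stream Qevap in litres per day.  Identifier convention mirrors the physics:
capital ``r_abs``-style names are radiation, lower-case ``r_can``/``r_root``
are radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .allometry import (
    AllometryConfig,
    ConfigError,
    DomainError,
    TreeGeometry,
    _geometry_arrays,
)

__all__ = [
    "STEFAN_BOLTZMANN",
    "CP_MOLAR",
    "LATENT_HEAT_VAPORIZATION",
    "MOLAR_MASS_WATER",
    "DENSITY_WATER",
    "Environment",
    "TraitSet",
    "Conductances",
    "EnergyBalanceResult",
    "EnergyBalanceError",
    "saturation_vapor_pressure",
    "conductances",
    "absorbed_radiation",
    "canopy_albedo",
    "solve_energy_balance",
    "evaporative_flow",
    "evaporative_flow_profile",
    "molar_flux_to_flow",
]

# Physical constants (SI / molar units).
STEFAN_BOLTZMANN = 5.670374419e-8   # W m^-2 K^-4 (CODATA)
CP_MOLAR = 29.3                     # J mol^-1 K^-1, molar heat capacity of air
LATENT_HEAT_VAPORIZATION = 44.0e3   # J mol^-1, treated as constant
MOLAR_MASS_WATER = 0.018015         # kg mol^-1
DENSITY_WATER = 1000.0              # kg m^-3
ZERO_C_IN_K = 273.15

# Boundary-layer conductance coefficients for forced convection over a flat
# leaf, with the 1.4 outdoor-turbulence enhancement (mol m^-2 s^-1 with wind
# in m/s and leaf dimension in m).
_BL_VAPOR = 1.4 * 0.147
_BL_HEAT = 1.4 * 0.135

# Tetens saturation-vapor-pressure coefficients (kPa, degC).
_TETENS_A = 0.6108
_TETENS_B = 17.27
_TETENS_C = 237.3


class EnergyBalanceError(Exception):
    """Energy-balance solver failure; carries the last residual in watts."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _esat(t_c):
    """Tetens saturation vapor pressure (kPa) without domain checks."""
    return _TETENS_A * np.exp(_TETENS_B * t_c / (t_c + _TETENS_C))


def _desat_dt(t_c):
    """Derivative of the Tetens curve (kPa / K)."""
    return _esat(t_c) * _TETENS_B * _TETENS_C / (t_c + _TETENS_C) ** 2


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapor pressure of water (kPa) at ``t_c`` degC, Tetens form.

    Valid for -40 <= T <= 60 degC; strictly increasing.
    """
    arr = np.asarray(t_c, dtype=float)
    if np.any(arr < -40.0) or np.any(arr > 60.0):
        raise DomainError(f"temperature {t_c!r} degC outside the Tetens range [-40, 60]")
    out = _esat(arr)
    return float(out) if np.ndim(t_c) == 0 else out


@dataclass(frozen=True)
class Environment:
    """One site's long-term-mean meteorology."""

    precipitation: float        # m/yr
    air_temperature: float      # degC
    relative_humidity: float    # fraction in (0, 1]
    wind_speed: float           # m/s
    solar_radiation: float      # W/m^2, incoming, normal to ground
    air_pressure: float = 101.325  # kPa
    site_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_humidity <= 1.0:
            raise ConfigError(f"relative_humidity must be in (0, 1], got {self.relative_humidity}")
        if self.wind_speed < 0:
            raise ConfigError(f"wind_speed must be non-negative, got {self.wind_speed}")
        if self.solar_radiation < 0:
            raise ConfigError(f"solar_radiation must be non-negative, got {self.solar_radiation}")
        if not self.air_pressure > 0:
            raise ConfigError(f"air_pressure must be positive, got {self.air_pressure}")
        if self.precipitation < 0:
            raise ConfigError(f"precipitation must be non-negative, got {self.precipitation}")


@dataclass(frozen=True)
class TraitSet:
    """Environment-independent physiological parameters of the average tree.

    Stomatal conductance is linear in stomatal density through the reference
    pair (``reference_stomatal_conductance`` at ``reference_stomatal_density``).
    Effective heat-exchange areas are ``coefficient * total one-sided leaf
    area``; defaults are two-sided thermal and sensible exchange and a single
    evaporating (hypostomatous) side.
    """

    stomatal_density: float = 200.0                 # stomata / mm^2, leaf-side average
    reference_stomatal_density: float = 200.0       # stomata / mm^2
    reference_stomatal_conductance: float = 0.2     # mol m^-2 s^-1
    leaf_characteristic_dimension: float = 0.05     # m
    leaf_shortwave_absorptivity: float = 0.5        # fraction
    canopy_extinction_coefficient: float = 0.5
    thermal_emissivity: float = 0.97                # fraction
    soil_reflectance: float = 0.30                  # fraction
    deep_canopy_reflectance: float = 0.15           # fraction
    effective_area_coefficients: tuple[float, float, float] = (2.0, 2.0, 1.0)  # (c_L, c_H, c_E)

    def __post_init__(self) -> None:
        for name in (
            "leaf_shortwave_absorptivity",
            "thermal_emissivity",
            "soil_reflectance",
            "deep_canopy_reflectance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in (
            "stomatal_density",
            "reference_stomatal_conductance",
            "canopy_extinction_coefficient",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not self.reference_stomatal_density > 0:
            raise ConfigError("reference_stomatal_density must be positive")
        if any(c < 0 for c in self.effective_area_coefficients):
            raise ConfigError("effective_area_coefficients must be non-negative")

    def with_stomatal_density(self, density: float) -> "TraitSet":
        return replace(self, stomatal_density=density)

    def with_leaf_dimension(self, d: float) -> "TraitSet":
        return replace(self, leaf_characteristic_dimension=d)


class Conductances(NamedTuple):
    """Leaf conductances (mol m^-2 s^-1)."""

    g_s: float   # stomatal, to vapor
    g_va: float  # boundary-layer, to vapor
    g_v: float   # total vapor (stomatal and boundary layer in series)
    g_ha: float  # boundary-layer, to heat


@dataclass(frozen=True)
class EnergyBalanceResult:
    """Closed canopy energy budget at the solved canopy temperature."""

    canopy_temperature: float       # degC
    absorbed_radiation: float       # W
    emitted_thermal: float          # W
    sensible_heat: float            # W
    latent_heat: float              # W
    evaporative_molar_flux: float   # mol m^-2 s^-1
    residual: float                 # W


def conductances(traits: TraitSet, env: Environment) -> Conductances:
    """Stomatal, boundary-layer and series conductances for a leaf.

    g_s scales linearly with stomatal density; the boundary-layer terms use
    the forced-convection forms ``1.4 * 0.147 * sqrt(u/d)`` (vapor) and
    ``1.4 * 0.135 * sqrt(u/d)`` (heat).
    """
    d = traits.leaf_characteristic_dimension
    if not d > 0:
        raise DomainError(f"leaf_characteristic_dimension must be positive, got {d}")
    g_s = traits.reference_stomatal_conductance * (
        traits.stomatal_density / traits.reference_stomatal_density
    )
    ratio = math.sqrt(env.wind_speed / d)
    g_va = _BL_VAPOR * ratio
    g_ha = _BL_HEAT * ratio
    g_v = 0.0 if (g_s == 0.0 or g_va == 0.0) else g_s * g_va / (g_s + g_va)
    return Conductances(g_s, g_va, g_v, g_ha)


def canopy_albedo(h: float, traits: TraitSet, cfg: AllometryConfig) -> float:
    """Whole-canopy albedo of a tree of height ``h`` (m).

    Interpolates between bare-soil reflectance (LAI -> 0) and the deep-canopy
    reflectance (LAI -> inf) with Beer–Lambert weight exp(-k * LAI(h)):
    short trees look like soil, tall closed canopies like deep foliage.
    """
    if not h > 0:
        raise DomainError(f"height must be positive, got {h!r}")
    lai = _geometry_arrays(np.asarray([h], dtype=float), cfg)["leaf_area_index"][0]
    k = traits.canopy_extinction_coefficient
    rho_deep = traits.deep_canopy_reflectance
    rho_soil = traits.soil_reflectance
    return float(rho_deep + (rho_soil - rho_deep) * math.exp(-k * lai))


def _absorbed_radiation_terms(a_total, a_proj, lai, env: Environment, traits: TraitSet):
    """Shortwave and ambient-longwave absorption (W), vectorized (internal)."""
    k = traits.canopy_extinction_coefficient
    shortwave = (
        env.solar_radiation
        * traits.leaf_shortwave_absorptivity
        * (1.0 - np.exp(-k * lai))
        * a_proj
    )
    c_l = traits.effective_area_coefficients[0]
    t_air_k = env.air_temperature + ZERO_C_IN_K
    longwave = traits.thermal_emissivity * STEFAN_BOLTZMANN * t_air_k ** 4 * c_l * a_total
    return shortwave, longwave


def absorbed_radiation(geom: TreeGeometry, env: Environment, traits: TraitSet) -> float:
    """Total absorbed radiation R_abs (W) of the canopy.

    Shortwave: ``S * absorptivity * (1 - exp(-k * LAI)) * projected area`` —
    for dense canopies (k * LAI >~ 5) this saturates at
    ``absorptivity * S * projected area``.  Longwave: ambient thermal at air
    temperature absorbed over the thermal effective area (emissivity used as
    absorptivity), which makes the no-sun, saturated-air equilibrium exact.
    """
    sw, lw = _absorbed_radiation_terms(
        np.asarray(geom.total_leaf_area),
        np.asarray(geom.projected_canopy_area),
        np.asarray(geom.leaf_area_index),
        env,
        traits,
    )
    return float(sw + lw)


def _solve_canopy_temperature(
    r_abs,
    a_thermal,
    a_sensible,
    a_evap,
    g_v: float,
    g_ha: float,
    env: Environment,
    traits: TraitSet,
    *,
    max_iter: int = 100,
    step_tol: float = 1e-6,
):
    """Vectorized Newton/bisection root of the energy balance (internal).

    Returns the canopy temperature array (degC).  The residual
    ``r_abs - losses(T)`` is strictly decreasing in T; a sign change over
    [T_air - 40, T_air + 40] is asserted before refinement.
    """
    r_abs = np.asarray(r_abs, dtype=float)
    a_thermal = np.broadcast_to(np.asarray(a_thermal, dtype=float), r_abs.shape).copy()
    a_sensible = np.broadcast_to(np.asarray(a_sensible, dtype=float), r_abs.shape).copy()
    a_evap = np.broadcast_to(np.asarray(a_evap, dtype=float), r_abs.shape).copy()
    t_air = env.air_temperature
    e_air = env.relative_humidity * _esat(t_air)
    p_air = env.air_pressure
    eps = traits.thermal_emissivity

    def residual(t):
        thermal = a_thermal * eps * STEFAN_BOLTZMANN * (t + ZERO_C_IN_K) ** 4
        sensible = a_sensible * CP_MOLAR * g_ha * (t - t_air)
        latent = a_evap * LATENT_HEAT_VAPORIZATION * g_v * (_esat(t) - e_air) / p_air
        return r_abs - (thermal + sensible + latent)

    def dresidual(t):
        d_thermal = 4.0 * a_thermal * eps * STEFAN_BOLTZMANN * (t + ZERO_C_IN_K) ** 3
        d_sensible = a_sensible * CP_MOLAR * g_ha
        d_latent = a_evap * LATENT_HEAT_VAPORIZATION * g_v * _desat_dt(t) / p_air
        return -(d_thermal + d_sensible + d_latent)

    lo = np.full_like(r_abs, t_air - 40.0)
    hi = np.full_like(r_abs, t_air + 40.0)
    f_lo = residual(lo)
    f_hi = residual(hi)
    if np.any(f_lo < 0) or np.any(f_hi > 0):
        worst = float(np.max(np.abs(np.concatenate([f_lo[f_lo < 0], f_hi[f_hi > 0]]))))
        raise EnergyBalanceError(
            "energy-balance residual does not change sign on [T_air - 40, T_air + 40] degC",
            residual=worst,
        )

    t = np.full_like(r_abs, t_air, dtype=float)
    f = residual(t)
    f_tol = 1e-10 * np.maximum(1.0, np.abs(r_abs))
    done = np.abs(f) <= f_tol
    for _ in range(max_iter):
        if done.all():
            break
        # Maintain the bracket from the current residuals (f decreasing in T).
        lo = np.where(~done & (f > 0), t, lo)
        hi = np.where(~done & (f < 0), t, hi)
        df = dresidual(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_newton = t - f / df
        bad = ~np.isfinite(t_newton) | (t_newton <= lo) | (t_newton >= hi)
        t_next = np.where(bad, 0.5 * (lo + hi), t_newton)
        step = np.abs(t_next - t)
        t = np.where(done, t, t_next)
        f = residual(t)
        done = done | (np.abs(f) <= f_tol) | (step <= step_tol)
    if not done.all():
        worst = float(np.max(np.abs(f[~done])))
        raise EnergyBalanceError(
            f"canopy-temperature iteration did not converge in {max_iter} steps",
            residual=worst,
        )
    return t


def _energy_balance_from_areas(a_total, a_proj, lai, env: Environment, traits: TraitSet):
    """Energy balance given leaf/projected areas and LAI arrays (internal)."""
    a_total = np.asarray(a_total, dtype=float)
    c_l, c_h, c_e = traits.effective_area_coefficients
    a_thermal = c_l * a_total
    a_sensible = c_h * a_total
    a_evap = c_e * a_total
    sw, lw = _absorbed_radiation_terms(a_total, a_proj, lai, env, traits)
    r_abs = sw + lw
    cond = conductances(traits, env)
    t_leaf = _solve_canopy_temperature(
        r_abs, a_thermal, a_sensible, a_evap, cond.g_v, cond.g_ha, env, traits
    )
    e_air = env.relative_humidity * _esat(env.air_temperature)
    e_flux = cond.g_v * (_esat(t_leaf) - e_air) / env.air_pressure
    thermal = a_thermal * traits.thermal_emissivity * STEFAN_BOLTZMANN * (t_leaf + ZERO_C_IN_K) ** 4
    sensible = a_sensible * CP_MOLAR * cond.g_ha * (t_leaf - env.air_temperature)
    latent = a_evap * LATENT_HEAT_VAPORIZATION * e_flux
    return {
        "canopy_temperature": t_leaf,
        "absorbed_radiation": r_abs,
        "emitted_thermal": thermal,
        "sensible_heat": sensible,
        "latent_heat": latent,
        "evaporative_molar_flux": e_flux,
        "residual": r_abs - (thermal + sensible + latent),
        "a_evap": a_evap,
    }


def _energy_balance_arrays(h, env: Environment, traits: TraitSet, cfg: AllometryConfig):
    """Energy balance along a height grid; returns dict of arrays (internal)."""
    geom = _geometry_arrays(np.asarray(h, dtype=float), cfg)
    return _energy_balance_from_areas(
        geom["total_leaf_area"],
        geom["projected_canopy_area"],
        geom["leaf_area_index"],
        env,
        traits,
    )


def solve_energy_balance(
    geom: TreeGeometry, env: Environment, traits: TraitSet
) -> EnergyBalanceResult:
    """Solve the canopy energy budget for canopy temperature and fluxes.

    The returned budget closes: ``|residual| <= 1e-6 * max(1 W, R_abs)``.
    Raises :class:`EnergyBalanceError` (carrying the last residual) if the
    iteration fails to converge.
    """
    out = _energy_balance_from_areas(
        np.asarray([geom.total_leaf_area]),
        np.asarray([geom.projected_canopy_area]),
        np.asarray([geom.leaf_area_index]),
        env,
        traits,
    )
    return EnergyBalanceResult(**{k: float(v[0]) for k, v in out.items() if k != "a_evap"})


def molar_flux_to_flow(e_flux, area):
    """Convert a molar evaporation flux (mol m^-2 s^-1 over ``area`` m^2) to L/day."""
    kg_per_s = np.asarray(e_flux) * np.asarray(area) * MOLAR_MASS_WATER
    liters_per_day = kg_per_s / DENSITY_WATER * 1000.0 * 86400.0
    return liters_per_day


def evaporative_flow(geom: TreeGeometry, env: Environment, traits: TraitSet) -> float:
    """Evaporative (transpiration) flow Qevap (L/day) for one tree.

    ``Qevap = A_E * E * M_w / rho_w`` converted to litres per day; zero when
    the energy balance yields no outward vapor flux (condensation conditions
    are clipped to zero flow).
    """
    result = solve_energy_balance(geom, env, traits)
    c_e = traits.effective_area_coefficients[2]
    a_evap = c_e * geom.total_leaf_area
    q = float(molar_flux_to_flow(result.evaporative_molar_flux, a_evap))
    return max(q, 0.0)


def evaporative_flow_profile(h, env: Environment, traits: TraitSet, cfg: AllometryConfig):
    """Vectorized Qevap (L/day) along a height grid (m)."""
    out = _energy_balance_arrays(h, env, traits, cfg)
    q = molar_flux_to_flow(out["evaporative_molar_flux"], out["a_evap"])
    return np.maximum(q, 0.0)
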