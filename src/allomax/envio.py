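"""Meteorology I/O and the synthetic-environment generator.

Site tables are plain CSV, one row per site, with the columns::

    site_id       free text identifier
    precip_m_yr   precipitation rate, m/yr
    tair_c        mean air temperature, degC
    rh_frac       relative humidity, fraction in (0, 1]
    wind_m_s      wind speed, m/s
    solar_w_m2    incoming solar radiation normal to the ground, W/m^2
    pressure_kpa  air pressure, kPa

All meteorology is a long-term annual mean.  Users pairing their own tree
records with stations should keep pairs within about 100 m of elevation and
4 km of radial distance of one another, so the station reflects the
conditions the trees actually experience; no geospatial matching is done
here.

The synthetic generator emulates site climatologies spanning wet/cool to
arid/hot regimes, either as independent uniform draws within ranges or as a
jointly ordered transect (first site wettest/coolest, last driest/hottest),
so the whole pipeline is testable without any external downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import AllomaxError, DomainError
from .microclimate import Environment, _esat
from .solver import MaxHeightResult

__all__ = [
    "SITE_COLUMNS",
    "EnvironmentGridSpec",
    "ValidationError",
    "rh_from_dewpoint",
    "generate_environments",
    "read_sites",
    "write_sites",
    "write_results",
]

SITE_COLUMNS = (
    "site_id",
    "precip_m_yr",
    "tair_c",
    "rh_frac",
    "wind_m_s",
    "solar_w_m2",
    "pressure_kpa",
)


class ValidationError(AllomaxError, ValueError):
    """A site table failed validation; ``issues`` itemizes every problem."""

    def __init__(self, issues: list[str]):
        super().__init__("invalid site table:\n  " + "\n  ".join(issues))
        self.issues = issues


def rh_from_dewpoint(t_dew: float, t_min: float, t_max: float) -> float:
    """Relative humidity from dewpoint and daily temperature extremes.

    RH = e_s(t_dew) / e_s((t_min + t_max) / 2), clipped to (0, 1].  A
    dewpoint above t_max is physically inconsistent; it produces a warning
    and a clipped result rather than an error, since long-term-average
    climatologies occasionally contain such artifacts.
    """
    if t_dew > t_max:
        warnings.warn(
            f"dewpoint {t_dew} degC exceeds maximum temperature {t_max} degC; clipping RH",
            stacklevel=2,
        )
    rh = float(_esat(t_dew) / _esat(0.5 * (t_min + t_max)))
    return min(rh, 1.0)


@dataclass(frozen=True)
class EnvironmentGridSpec:
    """Recipe for a deterministic set of synthetic site climatologies."""

    n_sites: int
    precipitation_range: tuple[float, float] = (0.3, 3.0)   # m/yr
    temperature_range: tuple[float, float] = (4.0, 28.0)    # degC
    rh_range: tuple[float, float] = (0.25, 0.92)            # fraction
    wind_range: tuple[float, float] = (1.5, 4.0)            # m/s
    solar_range: tuple[float, float] = (110.0, 320.0)       # W/m^2 annual mean
    correlation_mode: str = "transect"                      # or "independent"
    seed: int = 0
    pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DomainError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in (
            "precipitation_range",
            "temperature_range",
            "rh_range",
            "wind_range",
            "solar_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise DomainError(f"{name} must be ordered (lo <= hi), got {(lo, hi)}")
        if self.correlation_mode not in ("transect", "independent"):
            raise DomainError(
                f"correlation_mode must be 'transect' or 'independent', "
                f"got {self.correlation_mode!r}"
            )


def _lerp(lo: float, hi: float, t: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * t


def generate_environments(spec: EnvironmentGridSpec) -> list[Environment]:
    """Generate synthetic site climatologies; deterministic for a fixed seed.

    Transect mode orders the sites from wettest/coolest/most-humid/dimmest to
    driest/hottest/least-humid/brightest so both water-limited and
    energy-limited regimes occur along the list; a single site sits at the
    midpoint of every range.  Independent mode draws each variable uniformly
    within its range.
    """
    n = spec.n_sites
    if spec.correlation_mode == "transect":
        t = np.full(1, 0.5) if n == 1 else np.linspace(0.0, 1.0, n)
        precip = _lerp(spec.precipitation_range[1], spec.precipitation_range[0], t)
        tair = _lerp(spec.temperature_range[0], spec.temperature_range[1], t)
        rh = _lerp(spec.rh_range[1], spec.rh_range[0], t)
        wind = _lerp(spec.wind_range[0], spec.wind_range[1], t)
        solar = _lerp(spec.solar_range[0], spec.solar_range[1], t)
    else:
        rng = np.random.default_rng(spec.seed)
        precip = rng.uniform(*spec.precipitation_range, n)
        tair = rng.uniform(*spec.temperature_range, n)
        rh = rng.uniform(*spec.rh_range, n)
        wind = rng.uniform(*spec.wind_range, n)
        solar = rng.uniform(*spec.solar_range, n)
    return [
        Environment(
            precipitation=float(precip[i]),
            air_temperature=float(tair[i]),
            relative_humidity=float(np.clip(rh[i], 1e-9, 1.0)),
            wind_speed=float(wind[i]),
            solar_radiation=float(solar[i]),
            air_pressure=spec.pressure_kpa,
            site_id=f"site{i:03d}",
        )
        for i in range(n)
    ]


def _environments_to_frame(envs: list[Environment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in envs],
            "precip_m_yr": [e.precipitation for e in envs],
            "tair_c": [e.air_temperature for e in envs],
            "rh_frac": [e.relative_humidity for e in envs],
            "wind_m_s": [e.wind_speed for e in envs],
            "solar_w_m2": [e.solar_radiation for e in envs],
            "pressure_kpa": [e.air_pressure for e in envs],
        }
    )


def write_sites(path, envs: list[Environment]) -> None:
    """Write a site table (CSV, documented schema)."""
    # repr() emits the shortest digits that parse back to the same float
    _environments_to_frame(envs).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_sites(path) -> list[Environment]:
    """Read and validate a site CSV.

    Raises :class:`ValidationError` itemizing every missing column,
    non-finite value, and out-of-range relative humidity (with row indices).
    A header-only file yields an empty list with a warning.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    issues: list[str] = []
    for col in SITE_COLUMNS:
        if col not in table.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        raise ValidationError(issues)
    if len(table) == 0:
        warnings.warn(f"site table {path} contains a header but no rows", stacklevel=2)
        return []

    numeric = [c for c in SITE_COLUMNS if c != "site_id"]
    for col in numeric:
        values = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[~np.isfinite(values)]:
            issues.append(f"row {idx}: non-finite {col} = {table.at[idx, col]!r}")
        table[col] = values
    rh = table["rh_frac"]
    for idx in table.index[np.isfinite(rh) & ((rh <= 0) | (rh > 1))]:
        issues.append(f"row {idx}: rh_frac = {rh[idx]!r} outside (0, 1]")
    if issues:
        raise ValidationError(issues)

    return [
        Environment(
            precipitation=float(row.precip_m_yr),
            air_temperature=float(row.tair_c),
            relative_humidity=float(row.rh_frac),
            wind_speed=float(row.wind_m_s),
            solar_radiation=float(row.solar_w_m2),
            air_pressure=float(row.pressure_kpa),
            site_id=str(row.site_id),
        )
        for row in table.itertuples()
    ]


def write_results(path, results: dict[str, MaxHeightResult]) -> None:
    """Write per-site solver results (CSV: site_id, max height, binding constraint)."""
    rows = [
        {
            "site_id": site_id,
            "max_height_m": r.max_height,
            "binding_constraint": r.binding_constraint,
            "bracket_lo_m": r.bracket[0],
            "bracket_hi_m": r.bracket[1],
        }
        for site_id, r in results.items()
    ]
    pd.DataFrame(rows, columns=[
        "site_id", "max_height_m", "binding_constraint", "bracket_lo_m", "bracket_hi_m"
    ]).to_csv(path, index=False)
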