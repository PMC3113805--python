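"""Power-law allometry of the idealized tree.

All tree dimensions and the basal metabolic water demand are tied to overall
size through configurable power laws ``y = c * x^a``.  Heights and radii are
in metres, trunk diameters in centimetres, flows in litres per day; a year is
365.25 days.  Every prefactor and exponent is calibration data, loaded from a
TOML file (see :mod:`allomax.config`), never hard-coded in formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "ScalingLaw",
    "AllometryConfig",
    "TreeGeometry",
    "AllomaxError",
    "DomainError",
    "InversionError",
    "FitError",
    "ConfigError",
    "evaluate_law",
    "diameter_from_height",
    "geometry_from_height",
    "basal_flow",
    "fit_scaling_law",
    "liters_per_day_from_m3_per_year",
]

DAYS_PER_YEAR = 365.25


class AllomaxError(Exception):
    """Base class for package errors."""


class DomainError(AllomaxError, ValueError):
    """An input outside a function's mathematical domain."""


class InversionError(AllomaxError, ValueError):
    """A scaling law that cannot be inverted (zero exponent)."""


class FitError(AllomaxError, ValueError):
    """Insufficient or degenerate data for a power-law fit."""


class ConfigError(AllomaxError, ValueError):
    """Malformed configuration."""


def liters_per_day_from_m3_per_year(q: float | np.ndarray) -> float | np.ndarray:
    """Convert a volume flow from m^3/yr to L/day (the package's flow unit).

    The single place where the year-length convention (365.25 days) enters.
    """
    return q * 1000.0 / DAYS_PER_YEAR


@dataclass(frozen=True)
class ScalingLaw:
    """A power-law relation ``y = prefactor * x**exponent`` with unit tags.

    Parameters
    ----------
    prefactor
        Value of y at x = 1, in ``output_units`` per ``input_units**exponent``.
        Must be positive.
    exponent
        Dimensionless scaling exponent; may be negative or zero.
    """

    prefactor: float
    exponent: float
    input_units: str = ""
    output_units: str = ""

    def __post_init__(self) -> None:
        if not (self.prefactor > 0 and math.isfinite(self.prefactor)):
            raise ConfigError(f"prefactor must be positive and finite, got {self.prefactor!r}")
        if not math.isfinite(self.exponent):
            raise ConfigError(f"exponent must be finite, got {self.exponent!r}")

    def __call__(self, x):
        return evaluate_law(self, x)

    def invert(self, y):
        """Solve ``y = prefactor * x**exponent`` for x."""
        if self.exponent == 0:
            raise InversionError(
                f"law with zero exponent ({self.output_units} vs {self.input_units}) "
                "is constant and cannot be inverted"
            )
        y = np.asarray(y, dtype=float) if np.ndim(y) else float(y)
        if np.any(np.asarray(y) <= 0):
            raise DomainError(f"cannot invert law at non-positive output {y!r}")
        return (y / self.prefactor) ** (1.0 / self.exponent)

    def with_exponent_perturbed(self, percent: float) -> "ScalingLaw":
        """Return a copy with the exponent scaled by ``1 + percent/100``."""
        return ScalingLaw(
            self.prefactor,
            self.exponent * (1.0 + percent / 100.0),
            self.input_units,
            self.output_units,
        )


def evaluate_law(law: ScalingLaw, x):
    """Evaluate ``law.prefactor * x**law.exponent`` for positive x.

    Accepts scalars or arrays; raises :class:`DomainError` (naming the law by
    its units) on any non-positive input.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(
            f"scaling law ({law.output_units or 'y'} from {law.input_units or 'x'}) "
            f"requires positive finite input, got {x!r}"
        )
    out = law.prefactor * arr ** law.exponent
    return float(out) if np.ndim(x) == 0 else out


@dataclass(frozen=True)
class AllometryConfig:
    """The full set of scaling laws describing the idealized tree.

    ``basal_flow_small`` applies below ``crossover_diameter`` (cm) and
    ``basal_flow_large`` above it — a hard switch; a validation warning is
    emitted if the two laws disagree by more than 5% at the junction.
    """

    height_vs_diameter: ScalingLaw  # h (m) from D (cm)
    basal_flow_small: ScalingLaw    # Q0 (L/day) from D (cm)
    basal_flow_large: ScalingLaw    # Q0 (L/day) from D (cm)
    crossover_diameter: float       # cm
    canopy_radius: ScalingLaw       # r_can (m) from h (m)
    canopy_depth: ScalingLaw        # h_can (m) from h (m)
    root_radius: ScalingLaw         # r_root (m) from h (m)
    leaf_count: ScalingLaw          # n_L from D (cm)
    leaf_area_single: float         # m^2, one-sided area of a single leaf

    LAW_NAMES = (
        "height_vs_diameter",
        "basal_flow_small",
        "basal_flow_large",
        "canopy_radius",
        "canopy_depth",
        "root_radius",
        "leaf_count",
    )

    def __post_init__(self) -> None:
        if not self.crossover_diameter > 0:
            raise ConfigError(f"crossover_diameter must be positive, got {self.crossover_diameter}")
        if not self.leaf_area_single > 0:
            raise ConfigError(f"leaf_area_single must be positive, got {self.leaf_area_single}")
        left = evaluate_law(self.basal_flow_small, self.crossover_diameter)
        right = evaluate_law(self.basal_flow_large, self.crossover_diameter)
        if abs(left - right) / right > 0.05:
            warnings.warn(
                f"basal-flow laws disagree by {100 * abs(left - right) / right:.1f}% at the "
                f"crossover diameter {self.crossover_diameter} cm",
                stacklevel=2,
            )

    def replace_law(self, name: str, law: ScalingLaw) -> "AllometryConfig":
        if name not in self.LAW_NAMES:
            raise ConfigError(f"unknown scaling law {name!r}; known: {self.LAW_NAMES}")
        kwargs = {n: getattr(self, n) for n in self.LAW_NAMES}
        kwargs[name] = law
        return AllometryConfig(
            crossover_diameter=self.crossover_diameter,
            leaf_area_single=self.leaf_area_single,
            **kwargs,
        )


@dataclass(frozen=True)
class TreeGeometry:
    """All size-derived dimensions of the idealized tree at one height."""

    height: float            # m
    trunk_diameter: float    # cm
    canopy_radius: float     # m
    canopy_depth: float      # m
    root_radius: float       # m
    leaf_count: float
    total_leaf_area: float       # m^2, one-sided
    projected_canopy_area: float  # m^2
    leaf_area_index: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise DomainError(f"TreeGeometry.{name} must be non-negative")


def diameter_from_height(h, cfg: AllometryConfig):
    """Invert the height–diameter law: trunk diameter (cm) from height (m)."""
    arr = np.asarray(h, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"height must be positive, got {h!r}")
    d = cfg.height_vs_diameter.invert(arr)
    return float(d) if np.ndim(h) == 0 else d


def _geometry_arrays(h: np.ndarray, cfg: AllometryConfig) -> dict[str, np.ndarray]:
    """Vectorized geometry fields over an array of heights (internal)."""
    h = np.asarray(h, dtype=float)
    d = cfg.height_vs_diameter.invert(h)
    r_can = evaluate_law(cfg.canopy_radius, h)
    h_can = evaluate_law(cfg.canopy_depth, h)
    r_root = evaluate_law(cfg.root_radius, h)
    n_leaf = evaluate_law(cfg.leaf_count, d)
    a_total = n_leaf * cfg.leaf_area_single
    a_proj = math.pi * r_can ** 2
    lai = np.where(a_proj > 0, a_total / np.where(a_proj > 0, a_proj, 1.0), 0.0)
    return {
        "height": h,
        "trunk_diameter": d,
        "canopy_radius": r_can,
        "canopy_depth": h_can,
        "root_radius": r_root,
        "leaf_count": n_leaf,
        "total_leaf_area": a_total,
        "projected_canopy_area": a_proj,
        "leaf_area_index": lai,
    }


def geometry_from_height(h: float, cfg: AllometryConfig) -> TreeGeometry:
    """Compute all tree dimensions at height ``h`` (m) from the configured laws."""
    if not h > 0:
        raise DomainError(f"height must be positive, got {h!r}")
    g = _geometry_arrays(np.asarray([h], dtype=float), cfg)
    return TreeGeometry(**{k: float(v[0]) for k, v in g.items()})


def basal_flow(d, cfg: AllometryConfig):
    """Basal metabolic flow Q0 (L/day) from trunk diameter (cm).

    Uses the sapling law below the crossover diameter and the large-tree law
    at and above it (hard switch).
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"diameter must be positive, got {d!r}")
    small = evaluate_law(cfg.basal_flow_small, arr)
    large = evaluate_law(cfg.basal_flow_large, arr)
    q = np.where(arr < cfg.crossover_diameter, small, large)
    return float(q) if np.ndim(d) == 0 else q


def fit_scaling_law(
    points,
    input_units: str = "",
    output_units: str = "",
) -> ScalingLaw:
    """Fit ``y = c * x^a`` by ordinary least squares on (log x, log y).

    Parameters
    ----------
    points
        Iterable of (x, y) pairs, all positive, with at least two distinct x.

    Returns
    -------
    ScalingLaw
        exponent = slope of the log–log fit; prefactor = exp(intercept).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise FitError("need at least two (x, y) pairs")
    if np.any(pts <= 0) or np.any(~np.isfinite(pts)):
        raise FitError("all points must be positive and finite")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise FitError("need at least two distinct x values")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return ScalingLaw(float(np.exp(intercept)), float(slope), input_units, output_units)
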