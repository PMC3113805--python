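"""Environment-optimal trait values.

Inverts the height framework: holding every other parameter fixed, find the
trait value (stomatal density, or characteristic leaf size) that maximizes
the height upper bound while the full flow-constraint chain still holds.  A
coarse grid scan locates the bracketing maximum; golden-section search then
refines within that bracket only (no global unimodality is assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .allometry import AllometryConfig, DomainError
from .hydrology import WaterBudgetParams
from .microclimate import Environment, TraitSet
from .solver import max_height

__all__ = ["TraitOptimum", "optimal_stomatal_density", "optimal_leaf_size"]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class TraitOptimum:
    """Result of a single-trait optimization.

    ``value`` and ``h_max`` are NaN when every scanned trait value is
    infeasible.  ``scan_values``/``scan_heights`` expose the coarse-scan
    table (heights are NaN at infeasible points) for dominance checks and
    diagnostics.
    """

    value: float
    h_max: float
    scan_values: np.ndarray
    scan_heights: np.ndarray

    @property
    def feasible(self) -> bool:
        return not math.isnan(self.value)


def _golden_section_max(
    f: Callable[[float], float], a: float, b: float, xtol: float
) -> tuple[float, float]:
    """Golden-section maximization of ``f`` on [a, b] to width ``xtol``.

    Evaluations are cached; ties are resolved toward the lower endpoint.
    """
    cache: dict[float, float] = {}

    def fc(x: float) -> float:
        if x not in cache:
            cache[x] = f(x)
        return cache[x]

    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    while b - a > xtol:
        if fc(c) >= fc(d):  # >= keeps ties moving toward lower values
            b, d = d, c
            c = b - _INVPHI * (b - a)
        else:
            a, c = c, d
            d = a + _INVPHI * (b - a)
    candidates = [(x, y) for x, y in cache.items() if a <= x <= b] + [(a, fc(a))]
    best_y = max(y for _, y in candidates)
    best_x = min(x for x, y in candidates if y == best_y)
    return best_x, best_y


def _optimize_trait(
    objective: Callable[[float], float],
    bounds: tuple[float, float],
    n_grid: int,
    xtol: float,
) -> TraitOptimum:
    lo, hi = bounds
    if not (lo > 0 and hi >= lo):
        raise DomainError(f"bounds must satisfy 0 < min <= max, got {bounds!r}")
    if hi == lo:
        h = objective(lo)
        scan = np.asarray([lo])
        return TraitOptimum(lo, h, scan, np.asarray([h]))

    xs = np.linspace(lo, hi, n_grid)
    hs = np.asarray([objective(x) for x in xs])
    if np.all(np.isnan(hs)):
        return TraitOptimum(float("nan"), float("nan"), xs, hs)

    i = int(np.nanargmax(hs))  # first maximum -> ties toward lower trait value
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, n_grid - 1)]

    def finite_objective(x: float) -> float:
        h = objective(x)
        return -math.inf if math.isnan(h) else h

    x_star, h_star = _golden_section_max(finite_objective, float(a), float(b), xtol)
    # The refined point must dominate the coarse scan; keep the scan winner
    # on the (plateau) occasions where golden section lands a hair lower.
    if h_star < hs[i]:
        x_star, h_star = float(xs[i]), float(hs[i])
    return TraitOptimum(float(x_star), float(h_star), xs, hs)


def _height_objective(
    env: Environment,
    traits_for: Callable[[float], TraitSet],
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    mode: str,
    tol: float,
    solver_kwargs: dict,
) -> Callable[[float], float]:
    def objective(x: float) -> float:
        result = max_height(env, traits_for(x), params, cfg, mode=mode, tol=tol, **solver_kwargs)
        return result.max_height
    return objective


def optimal_stomatal_density(
    env: Environment,
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    bounds: tuple[float, float],
    *,
    mode: str = "both",
    n_grid: int = 64,
    xtol: float = 0.1,
    height_tol: float = 1e-3,
    **solver_kwargs,
) -> TraitOptimum:
    """Stomatal density (stomata/mm^2) that maximizes the height bound.

    All other traits are held fixed.  The full constraint chain (mode
    ``both``) is the default: the optimum balances enough evaporative pull
    to meet metabolic demand against staying inside the water budget.
    """
    objective = _height_objective(
        env, traits.with_stomatal_density, params, cfg, mode, height_tol, solver_kwargs
    )
    return _optimize_trait(objective, bounds, n_grid, xtol)


def optimal_leaf_size(
    env: Environment,
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    bounds: tuple[float, float],
    *,
    mode: str = "both",
    n_grid: int = 64,
    xtol: float = 1e-4,
    height_tol: float = 1e-3,
    **solver_kwargs,
) -> TraitOptimum:
    """Characteristic leaf dimension (m) that maximizes the height bound."""
    objective = _height_objective(
        env, traits.with_leaf_dimension, params, cfg, mode, height_tol, solver_kwargs
    )
    return _optimize_trait(objective, bounds, n_grid, xtol)
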