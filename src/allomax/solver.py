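"""Maximum sustainable height from the three flow-rate constraints.

A tree of height h is viable when its evaporatively driven flow lies between
its basal metabolic requirement and its precipitation supply:

    Q0(h) <= Qevap(h, env) <= Qp(h, env)

The maximum height is the upper edge of the viable region attached to the
smallest trees — a tree must grow through every intermediate size, so
disconnected viable islands at larger h are diagnostic only.  The solver
scans a log-spaced height grid, then bisects the bracketing interval.

Also here: the uniform temperature-shift experiment, the scaling-exponent
perturbation analysis, and the signed relative-error metric used to compare
predictions with observed tallest trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .allometry import (
    AllometryConfig,
    ConfigError,
    DomainError,
    diameter_from_height,
    basal_flow,
)
from .hydrology import WaterBudgetParams, available_flow
from .microclimate import Environment, TraitSet, evaporative_flow_profile

__all__ = [
    "FlowCurves",
    "MaxHeightResult",
    "flow_curves",
    "max_height",
    "max_height_from_flows",
    "temperature_sensitivity",
    "exponent_sensitivity",
    "relative_error",
    "DEFAULT_H_MIN",
    "DEFAULT_H_CAP",
]

DEFAULT_H_MIN = 0.5    # m — seedling scale
DEFAULT_H_CAP = 150.0  # m — above the tallest known trees
DEFAULT_N_GRID = 400
DEFAULT_TOL = 0.01     # m


@dataclass(frozen=True)
class FlowCurves:
    """The three flow curves (L/day) along a common height grid (m)."""

    heights: np.ndarray
    q_required: np.ndarray      # Q0
    q_available: np.ndarray     # Qp
    q_evaporative: np.ndarray   # Qevap

    def __post_init__(self) -> None:
        n = len(self.heights)
        if not (len(self.q_required) == len(self.q_available) == len(self.q_evaporative) == n):
            raise DomainError("flow curves must share the height grid length")
        if np.any(np.diff(self.heights) <= 0):
            raise DomainError("heights must be strictly increasing")
        for name in ("q_required", "q_available", "q_evaporative"):
            if np.any(getattr(self, name) < 0):
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MaxHeightResult:
    """Solver output: the height bound and which constraint sets it.

    ``max_height`` is NaN when no viable height exists (arid sites genuinely
    support no trees in-model; infeasibility is data, not an error).
    ``binding_constraint`` is one of ``metabolic`` (Qevap falls to Q0),
    ``water`` (Qevap exceeds Qp), ``cap`` (viable through the search ceiling)
    or ``infeasible``.
    """

    max_height: float
    binding_constraint: str
    curves: FlowCurves
    bracket: tuple[float, float]
    feasible_islands: int = 1

    @property
    def feasible(self) -> bool:
        return not math.isnan(self.max_height)


def flow_curves(
    env: Environment,
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    h_grid,
) -> FlowCurves:
    """Evaluate Q0, Qp and Qevap (L/day) on a strictly increasing height grid."""
    h = np.asarray(h_grid, dtype=float)
    if h.ndim != 1 or h.size == 0 or np.any(h <= 0) or np.any(np.diff(h) <= 0):
        raise DomainError("h_grid must be a strictly increasing positive vector")
    q0 = basal_flow(diameter_from_height(h, cfg), cfg)
    qp = available_flow(h, env.precipitation, params, cfg)
    qe = evaporative_flow_profile(h, env, traits, cfg)
    return FlowCurves(h, np.atleast_1d(q0), np.atleast_1d(qp), np.atleast_1d(qe))


def _feasible_mask(q0, qe, qp, mode: str) -> np.ndarray:
    if mode == "metabolic_only":
        return np.asarray(qe >= q0)
    if mode == "both":
        return np.asarray((qe >= q0) & (qe <= qp))
    raise ConfigError(f"unknown mode {mode!r}; expected 'metabolic_only' or 'both'")


def _count_islands(mask: np.ndarray) -> int:
    diff = np.diff(mask.astype(int))
    return int(mask[0]) + int(np.sum(diff == 1))


def max_height_from_flows(
    q0_fn: Callable[[np.ndarray], np.ndarray],
    qevap_fn: Callable[[np.ndarray], np.ndarray],
    qp_fn: Callable[[np.ndarray], np.ndarray],
    *,
    mode: str = "metabolic_only",
    h_min: float = DEFAULT_H_MIN,
    h_cap: float = DEFAULT_H_CAP,
    n_grid: int = DEFAULT_N_GRID,
    tol: float = DEFAULT_TOL,
) -> MaxHeightResult:
    """Core search over arbitrary flow callables (each mapping h-array to L/day).

    Scans ``n_grid`` log-spaced heights in [h_min, h_cap]; the viable region
    containing h_min is followed to its upper edge, which is then bisected to
    within ``tol`` metres.
    """
    h = np.geomspace(h_min, h_cap, n_grid)
    q0 = np.asarray(q0_fn(h), dtype=float)
    qe = np.asarray(qevap_fn(h), dtype=float)
    qp = np.asarray(qp_fn(h), dtype=float)
    curves = FlowCurves(h, q0, qp, qe)
    mask = _feasible_mask(q0, qe, qp, mode)
    islands = _count_islands(mask)

    def feasible_at(x: float) -> bool:
        xa = np.asarray([x])
        return bool(
            _feasible_mask(q0_fn(xa), qevap_fn(xa), qp_fn(xa), mode)[0]
        )

    def binding_at(x: float) -> str:
        xa = np.asarray([x])
        q0x = float(np.asarray(q0_fn(xa))[0])
        qex = float(np.asarray(qevap_fn(xa))[0])
        qpx = float(np.asarray(qp_fn(xa))[0])
        if qex < q0x:
            return "metabolic"
        if mode == "both" and qex > qpx:
            return "water"
        return "metabolic"  # unreachable for a genuinely infeasible x

    if not mask[0]:
        return MaxHeightResult(float("nan"), "infeasible", curves, (h_min, h_min), islands)
    if mask.all():
        return MaxHeightResult(h_cap, "cap", curves, (h[-1], h[-1]), islands)

    i_fail = int(np.argmin(mask))  # first False after the feasible run from h_min
    lo, hi = float(h[i_fail - 1]), float(h[i_fail])
    bracket = (lo, hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible_at(mid):
            lo = mid
        else:
            hi = mid
    return MaxHeightResult(0.5 * (lo + hi), binding_at(hi), curves, bracket, islands)


def max_height(
    env: Environment,
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    *,
    mode: str = "metabolic_only",
    h_min: float = DEFAULT_H_MIN,
    h_cap: float = DEFAULT_H_CAP,
    n_grid: int = DEFAULT_N_GRID,
    tol: float = DEFAULT_TOL,
) -> MaxHeightResult:
    """Maximum sustainable tree height for one site.

    The default ``metabolic_only`` mode locates the height at which Qevap
    falls to the basal requirement Q0 — the practically best-predicting
    procedure once root efficiency is calibrated; ``both`` enforces the full
    chain Q0 <= Qevap <= Qp, so arid sites can be water-bound or infeasible.
    """

    def q0_fn(h):
        return basal_flow(diameter_from_height(h, cfg), cfg)

    def qe_fn(h):
        return evaporative_flow_profile(h, env, traits, cfg)

    def qp_fn(h):
        return available_flow(h, env.precipitation, params, cfg)

    return max_height_from_flows(
        q0_fn, qe_fn, qp_fn, mode=mode, h_min=h_min, h_cap=h_cap, n_grid=n_grid, tol=tol
    )


def temperature_sensitivity(
    envs: Iterable[Environment],
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    delta_t: float,
    *,
    mode: str = "both",
    **solver_kwargs,
) -> tuple[pd.DataFrame, float]:
    """Percent change in max height under a uniform air-temperature shift.

    Recomputes every site with ``air_temperature + delta_t`` and all traits
    fixed.  Returns a per-site table (site_id, h_base, h_shifted, pct_change,
    status) and the mean percent change over sites feasible both before and
    after the shift.  Sites infeasible before the shift are excluded from the
    mean and reported with status ``infeasible_base``.

    The default mode keeps the full constraint chain: without the water
    ceiling a uniform warming can only raise the evaporative bound.
    """
    envs = list(envs)
    if not envs:
        raise DomainError("need at least one site")
    rows = []
    for env in envs:
        base = max_height(env, traits, params, cfg, mode=mode, **solver_kwargs)
        shifted_env = Environment(
            precipitation=env.precipitation,
            air_temperature=env.air_temperature + delta_t,
            relative_humidity=env.relative_humidity,
            wind_speed=env.wind_speed,
            solar_radiation=env.solar_radiation,
            air_pressure=env.air_pressure,
            site_id=env.site_id,
        )
        shifted = max_height(shifted_env, traits, params, cfg, mode=mode, **solver_kwargs)
        if not base.feasible:
            status = "infeasible_base"
            pct = float("nan")
        elif not shifted.feasible:
            status = "infeasible_shifted"
            pct = float("nan")
        else:
            status = "ok"
            pct = 100.0 * (shifted.max_height - base.max_height) / base.max_height
        rows.append(
            {
                "site_id": env.site_id,
                "h_base_m": base.max_height,
                "h_shifted_m": shifted.max_height,
                "pct_change": pct,
                "status": status,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    mean_pct = float(ok["pct_change"].mean()) if len(ok) else float("nan")
    return table, mean_pct


def exponent_sensitivity(
    envs: Iterable[Environment],
    traits: TraitSet,
    params: WaterBudgetParams,
    cfg: AllometryConfig,
    law_name: str,
    perturbations: Sequence[float],
    *,
    observed: Sequence[float] | None = None,
    mode: str = "metabolic_only",
    **solver_kwargs,
) -> pd.DataFrame:
    """Perturb one scaling exponent by the given percentages and re-predict.

    For each perturbation the named law's exponent is scaled by
    ``1 + pct/100`` and maximum heights are recomputed for every site.  The
    returned table has one row per perturbation with the median relative
    height change versus the unperturbed run, and — when ``observed`` tallest
    tree heights are supplied — the median signed relative error against them.
    """
    envs = list(envs)
    if law_name not in AllometryConfig.LAW_NAMES:
        raise ConfigError(f"unknown scaling law {law_name!r}; known: {AllometryConfig.LAW_NAMES}")
    if observed is not None and len(observed) != len(envs):
        raise DomainError("observed heights must match the site list length")

    def predict_all(c: AllometryConfig) -> np.ndarray:
        return np.asarray(
            [max_height(e, traits, params, c, mode=mode, **solver_kwargs).max_height for e in envs]
        )

    base_heights = predict_all(cfg)
    rows = []
    for pct in perturbations:
        law = getattr(cfg, law_name).with_exponent_perturbed(pct)
        heights = predict_all(cfg.replace_law(law_name, law))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel_change = (heights - base_heights) / base_heights
        row = {
            "perturbation_pct": float(pct),
            "median_height_change": float(np.nanmedian(rel_change)),
        }
        if observed is not None:
            errs = relative_error(heights, np.asarray(observed, dtype=float))
            row["median_relative_error"] = float(np.nanmedian(errs))
        rows.append(row)
    return pd.DataFrame(rows)


def relative_error(predicted, observed):
    """Signed relative error (predicted - observed) / observed.

    Positive values are over-predictions; the sign is kept so over- and
    under-prediction can be distinguished in error histograms.
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs <= 0):
        raise DomainError(f"observed height must be positive, got {observed!r}")
    err = (np.asarray(predicted, dtype=float) - obs) / obs
    return float(err) if np.ndim(predicted) == 0 and np.ndim(observed) == 0 else err
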