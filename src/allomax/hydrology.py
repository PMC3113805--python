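"""Precipitation-limited water supply.

The available flow Qp is the precipitation intercepted by the flat ground
disc above the root system, scaled by a root absorption efficiency.  Runoff,
pooling and subsurface storage are deliberately excluded: supply is direct
interception over the root footprint only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allometry import (
    AllometryConfig,
    ConfigError,
    DomainError,
    evaluate_law,
    liters_per_day_from_m3_per_year,
)

__all__ = ["WaterBudgetParams", "available_flow"]


@dataclass(frozen=True)
class WaterBudgetParams:
    """Scalar water-budget parameters.

    root_absorption_efficiency is the fraction of intercepted precipitation
    the root system actually takes up, a single calibratable scalar per run.
    """

    root_absorption_efficiency: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.root_absorption_efficiency <= 1.0:
            raise ConfigError(
                f"root_absorption_efficiency must lie in [0, 1], "
                f"got {self.root_absorption_efficiency}"
            )


def available_flow(h, precipitation: float, params: WaterBudgetParams, cfg: AllometryConfig):
    """Available flow Qp (L/day) at height(s) ``h`` (m).

    Qp = efficiency * precipitation (m/yr) * pi * r_root(h)^2, converted from
    m^3/yr to L/day.  Linear in precipitation and in efficiency; scales with
    height as h^(2 * root-radius exponent).
    """
    arr = np.asarray(h, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"height must be positive, got {h!r}")
    if precipitation < 0:
        raise DomainError(f"precipitation must be non-negative, got {precipitation}")
    r_root = evaluate_law(cfg.root_radius, arr)
    q_m3_yr = params.root_absorption_efficiency * precipitation * np.pi * r_root ** 2
    q = liters_per_day_from_m3_per_year(q_m3_yr)
    return float(q) if np.ndim(h) == 0 else q
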