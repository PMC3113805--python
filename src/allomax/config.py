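"""Strict TOML configuration for the allometric laws, traits and water budget.

The shipped default file (``allomax/data/default_config.toml``) carries
versioned calibration values; any user file must follow exactly the same
schema — unknown or missing keys are rejected so silent typos cannot change
a calibration.  Every prediction run is expected to log the fully resolved
configuration (see :func:`resolved_config_dict` and the CLI run-logs).
"""

from __future__ import annotations

import dataclasses
import tomllib
from importlib import resources
from pathlib import Path

from .allometry import AllometryConfig, ConfigError, ScalingLaw
from .hydrology import WaterBudgetParams
from .microclimate import TraitSet

__all__ = [
    "load_config",
    "default_config",
    "resolved_config_dict",
]

_LAW_KEYS = {"prefactor", "exponent", "input_units", "output_units"}
_ALLOMETRY_SCALARS = {"crossover_diameter_cm", "leaf_area_single_m2"}
_WATER_KEYS = {"root_absorption_efficiency"}
_TRAIT_KEYS = {
    "stomatal_density_per_mm2",
    "reference_stomatal_density_per_mm2",
    "reference_stomatal_conductance_mol_m2_s",
    "leaf_characteristic_dimension_m",
    "leaf_shortwave_absorptivity",
    "canopy_extinction_coefficient",
    "thermal_emissivity",
    "soil_reflectance",
    "deep_canopy_reflectance",
    "effective_area_thermal",
    "effective_area_sensible",
    "effective_area_evaporative",
}
_TOP_KEYS = {"schema_version", "allometry", "water", "traits"}


def _check_keys(section: dict, expected: set[str], where: str) -> None:
    missing = expected - section.keys()
    extra = section.keys() - expected
    problems = []
    if missing:
        problems.append(f"missing keys {sorted(missing)}")
    if extra:
        problems.append(f"unknown keys {sorted(extra)}")
    if problems:
        raise ConfigError(f"[{where}]: " + "; ".join(problems))


def _parse_law(section: dict, where: str) -> ScalingLaw:
    _check_keys(section, _LAW_KEYS, where)
    return ScalingLaw(
        prefactor=float(section["prefactor"]),
        exponent=float(section["exponent"]),
        input_units=str(section["input_units"]),
        output_units=str(section["output_units"]),
    )


def _parse(data: dict) -> tuple[AllometryConfig, TraitSet, WaterBudgetParams]:
    _check_keys(data, _TOP_KEYS, "top level")
    allo = data["allometry"]
    law_sections = set(AllometryConfig.LAW_NAMES)
    _check_keys(allo, _ALLOMETRY_SCALARS | law_sections, "allometry")
    laws = {name: _parse_law(allo[name], f"allometry.{name}") for name in law_sections}
    cfg = AllometryConfig(
        crossover_diameter=float(allo["crossover_diameter_cm"]),
        leaf_area_single=float(allo["leaf_area_single_m2"]),
        **laws,
    )
    water = data["water"]
    _check_keys(water, _WATER_KEYS, "water")
    params = WaterBudgetParams(float(water["root_absorption_efficiency"]))
    tr = data["traits"]
    _check_keys(tr, _TRAIT_KEYS, "traits")
    traits = TraitSet(
        stomatal_density=float(tr["stomatal_density_per_mm2"]),
        reference_stomatal_density=float(tr["reference_stomatal_density_per_mm2"]),
        reference_stomatal_conductance=float(tr["reference_stomatal_conductance_mol_m2_s"]),
        leaf_characteristic_dimension=float(tr["leaf_characteristic_dimension_m"]),
        leaf_shortwave_absorptivity=float(tr["leaf_shortwave_absorptivity"]),
        canopy_extinction_coefficient=float(tr["canopy_extinction_coefficient"]),
        thermal_emissivity=float(tr["thermal_emissivity"]),
        soil_reflectance=float(tr["soil_reflectance"]),
        deep_canopy_reflectance=float(tr["deep_canopy_reflectance"]),
        effective_area_coefficients=(
            float(tr["effective_area_thermal"]),
            float(tr["effective_area_sensible"]),
            float(tr["effective_area_evaporative"]),
        ),
    )
    return cfg, traits, params


def load_config(path: str | Path | None = None) -> tuple[AllometryConfig, TraitSet, WaterBudgetParams]:
    """Load (allometry config, trait set, water params) from a TOML file.

    With ``path=None`` the shipped default calibration is used.
    """
    if path is None:
        text = resources.files("allomax.data").joinpath("default_config.toml").read_bytes()
        data = tomllib.loads(text.decode())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return _parse(data)


def default_config() -> tuple[AllometryConfig, TraitSet, WaterBudgetParams]:
    """The shipped default calibration."""
    return load_config(None)


def resolved_config_dict(
    cfg: AllometryConfig, traits: TraitSet, params: WaterBudgetParams
) -> dict:
    """A JSON-serializable dump of a fully resolved configuration (for run logs)."""
    return {
        "allometry": {
            **{name: dataclasses.asdict(getattr(cfg, name)) for name in cfg.LAW_NAMES},
            "crossover_diameter_cm": cfg.crossover_diameter,
            "leaf_area_single_m2": cfg.leaf_area_single,
        },
        "water": dataclasses.asdict(params),
        "traits": {
            **dataclasses.asdict(traits),
            "effective_area_coefficients": list(traits.effective_area_coefficients),
        },
    }
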