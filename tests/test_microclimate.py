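import dataclasses
import math

import numpy as np
import pytest

import allomax.microclimate as mc
from allomax import (
    DomainError,
    Environment,
    ScalingLaw,
    TraitSet,
    absorbed_radiation,
    canopy_albedo,
    conductances,
    evaporative_flow,
    evaporative_flow_profile,
    geometry_from_height,
    molar_flux_to_flow,
    saturation_vapor_pressure,
    solve_energy_balance,
)

from test_allometry import identity_config


def random_environment(rng):
    return Environment(
        precipitation=float(rng.uniform(0.05, 3.0)),
        air_temperature=float(rng.uniform(-5.0, 35.0)),
        relative_humidity=float(rng.uniform(0.1, 1.0)),
        wind_speed=float(rng.uniform(0.1, 10.0)),
        solar_radiation=float(rng.uniform(0.0, 400.0)),
        air_pressure=float(rng.uniform(80.0, 105.0)),
    )


def brute_force_canopy_temperature(geom, env, traits, step=0.001):
    """Independent oracle: scan the residual on a fine temperature grid."""
    t = np.arange(env.air_temperature - 40.0, env.air_temperature + 40.0, step)
    c_l, c_h, c_e = traits.effective_area_coefficients
    a = geom.total_leaf_area
    r_abs = absorbed_radiation(geom, env, traits)
    cond = conductances(traits, env)
    e_air = env.relative_humidity * mc._esat(env.air_temperature)
    losses = (
        c_l * a * traits.thermal_emissivity * mc.STEFAN_BOLTZMANN * (t + 273.15) ** 4
        + c_h * a * mc.CP_MOLAR * cond.g_ha * (t - env.air_temperature)
        + c_e * a * mc.LATENT_HEAT_VAPORIZATION * cond.g_v * (mc._esat(t) - e_air) / env.air_pressure
    )
    return float(t[np.argmin(np.abs(r_abs - losses))])


class TestSaturationVaporPressure:
    @pytest.mark.parametrize("t, expected, tol", [(0.0, 0.6108, 1e-4), (20.0, 2.338, 1e-3)])
    def test_reference_values(self, t, expected, tol):
        assert saturation_vapor_pressure(t) == pytest.approx(expected, abs=tol)

    def test_strictly_increasing(self):
        t = np.linspace(-40.0, 59.0, 200)
        assert np.all(np.diff(saturation_vapor_pressure(t)) > 0)

    @pytest.mark.parametrize("t", [-41.0, 61.0])
    def test_domain_bounds(self, t):
        with pytest.raises(DomainError):
            saturation_vapor_pressure(t)


class TestConductances:
    def test_boundary_layer_value(self, traits):
        env = Environment(1.0, 20.0, 0.5, 1.0, 200.0)
        tr = dataclasses.replace(traits, leaf_characteristic_dimension=0.1)
        c = conductances(tr, env)
        assert c.g_va == pytest.approx(1.4 * 0.147 * math.sqrt(10.0), rel=1e-12)
        assert c.g_ha == pytest.approx(1.4 * 0.135 * math.sqrt(10.0), rel=1e-12)

    def test_symmetric_series_combination(self, traits):
        # choose wind so g_va equals g_s, then g_v = g_s / 2
        tr = dataclasses.replace(
            traits, reference_stomatal_conductance=0.2, stomatal_density=200.0
        )
        d = tr.leaf_characteristic_dimension
        wind = (0.2 / (1.4 * 0.147)) ** 2 * d
        c = conductances(tr, Environment(1.0, 20.0, 0.5, wind, 200.0))
        assert c.g_v == pytest.approx(c.g_s / 2.0, rel=1e-9)

    def test_closed_stomata_shut_down_vapor_path(self, traits, temperate_env, cfg):
        tr = traits.with_stomatal_density(0.0)
        c = conductances(tr, temperate_env)
        assert c.g_s == 0.0 and c.g_v == 0.0
        q = evaporative_flow(geometry_from_height(10.0, cfg), temperate_env, tr)
        assert q == 0.0

    def test_zero_leaf_dimension_rejected(self, traits, temperate_env):
        with pytest.raises(DomainError):
            conductances(traits.with_leaf_dimension(0.0), temperate_env)


class TestAbsorbedRadiation:
    def test_no_leaves_no_shortwave(self, traits):
        geom = dataclasses.replace(
            geometry_from_height(1.0, identity_config()),
            leaf_count=0.0, total_leaf_area=0.0, leaf_area_index=0.0,
        )
        env = Environment(1.0, 20.0, 0.5, 1.0, 1000.0)
        # no leaf area: no shortwave interception and no thermal area either
        assert absorbed_radiation(geom, env, traits) == 0.0

    def test_shortwave_term_arithmetic(self):
        tr = TraitSet(leaf_shortwave_absorptivity=0.8, thermal_emissivity=0.0)
        env = Environment(1.0, 20.0, 0.5, 1.0, 1000.0)
        geom = dataclasses.replace(
            geometry_from_height(4.0, identity_config(canopy_radius=ScalingLaw(0.5, 1.0))),
            leaf_area_index=100.0,  # saturate Beer-Lambert: factor -> absorptivity
        )
        assert geom.projected_canopy_area == pytest.approx(12.566, abs=1e-3)
        assert absorbed_radiation(geom, env, tr) == pytest.approx(
            0.8 * 1000.0 * geom.projected_canopy_area, rel=1e-6
        )

    def test_dense_canopy_limit(self, traits, cfg):
        env = Environment(1.0, 20.0, 0.5, 1.0, 300.0)
        tr = dataclasses.replace(traits, thermal_emissivity=0.0)
        k = tr.canopy_extinction_coefficient
        for lai in (5.0 / k, 8.0 / k):
            geom = dataclasses.replace(
                geometry_from_height(30.0, cfg), leaf_area_index=lai
            )
            full = tr.leaf_shortwave_absorptivity * 300.0 * geom.projected_canopy_area
            assert absorbed_radiation(geom, env, tr) == pytest.approx(full, rel=0.01)


class TestCanopyAlbedo:
    def test_limits_and_arithmetic(self):
        # constant-LAI toy: n_L = 2*pi, r_can = 1, single leaf area 1 -> LAI = 2
        cfg = identity_config(
            leaf_count=ScalingLaw(2.0 * math.pi, 0.0),
            canopy_radius=ScalingLaw(1.0, 0.0),
        )
        tr = TraitSet(soil_reflectance=0.30, deep_canopy_reflectance=0.15,
                      canopy_extinction_coefficient=0.5)
        assert canopy_albedo(3.0, tr, cfg) == pytest.approx(
            0.15 + 0.15 * math.exp(-1.0), rel=1e-9
        )

    def test_soil_and_deep_canopy_limits(self, traits, cfg):
        assert canopy_albedo(1e-7, traits, cfg) == pytest.approx(
            traits.soil_reflectance, abs=1e-3
        )
        assert canopy_albedo(1e6, traits, cfg) == pytest.approx(
            traits.deep_canopy_reflectance, abs=1e-3
        )

    def test_monotone_decreasing_in_height_and_bounded(self, traits, cfg):
        h = np.geomspace(0.1, 200.0, 80)
        albedo = np.array([canopy_albedo(x, traits, cfg) for x in h])
        assert np.all(np.diff(albedo) < 0)
        assert np.all(albedo <= traits.soil_reflectance + 1e-12)
        assert np.all(albedo >= traits.deep_canopy_reflectance - 1e-12)


class TestEnergyBalance:
    def test_equilibrium_fixed_point(self, cfg):
        # no sun, saturated air, blackbody canopy: canopy sits at air temperature
        tr = TraitSet(thermal_emissivity=1.0)
        env = Environment(1.0, 12.0, 1.0, 2.0, 0.0)
        res = solve_energy_balance(geometry_from_height(20.0, cfg), env, tr)
        assert res.canopy_temperature == pytest.approx(12.0, abs=1e-6)
        assert res.evaporative_molar_flux == 0.0
        assert res.latent_heat == 0.0

    def test_blackbody_emission_at_300k(self):
        # equilibrium at T_air = 26.85 degC (300 K) with unit effective areas:
        # the emitted thermal term is sigma * T^4 = 459.3 W
        tr = TraitSet(thermal_emissivity=1.0, effective_area_coefficients=(1.0, 1.0, 1.0))
        cfg = identity_config()  # h = 1 -> total leaf area 1 m^2
        env = Environment(1.0, 26.85, 1.0, 1.0, 0.0)
        res = solve_energy_balance(geometry_from_height(1.0, cfg), env, tr)
        assert res.emitted_thermal == pytest.approx(459.3, abs=0.1)

    def test_energy_closure_on_random_environments(self, traits, cfg):
        rng = np.random.default_rng(3)
        for _ in range(100):
            env = random_environment(rng)
            geom = geometry_from_height(float(rng.uniform(0.5, 120.0)), cfg)
            res = solve_energy_balance(geom, env, traits)
            assert abs(res.residual) <= 1e-6 * max(1.0, res.absorbed_radiation)

    def test_newton_matches_brute_force_scan(self, traits, cfg):
        rng = np.random.default_rng(5)
        for _ in range(10):
            env = random_environment(rng)
            geom = geometry_from_height(float(rng.uniform(1.0, 100.0)), cfg)
            res = solve_energy_balance(geom, env, traits)
            oracle = brute_force_canopy_temperature(geom, env, traits)
            assert res.canopy_temperature == pytest.approx(oracle, abs=0.01)

    def test_sunlit_saturated_canopy_warmer_than_air(self, traits, cfg):
        env = Environment(1.0, 15.0, 1.0, 2.0, 250.0)
        res = solve_energy_balance(geometry_from_height(15.0, cfg), env, traits)
        assert res.canopy_temperature > env.air_temperature


class TestEvaporativeFlow:
    def test_molar_flux_conversion(self):
        assert molar_flux_to_flow(1e-3, 1.0) == pytest.approx(1.5565, abs=1e-3)

    def test_no_gradient_no_flow(self, traits, cfg):
        env = Environment(1.0, 10.0, 1.0, 2.0, 0.0)
        tr = dataclasses.replace(traits, thermal_emissivity=1.0)
        assert evaporative_flow(geometry_from_height(10.0, cfg), env, tr) == 0.0

    def test_decreasing_in_humidity_increasing_in_sun(self, traits, cfg):
        h = np.asarray([12.0])
        base = dict(precipitation=1.0, air_temperature=18.0, wind_speed=2.5)
        q_rh = [
            evaporative_flow_profile(
                h, Environment(**base, relative_humidity=rh, solar_radiation=200.0),
                traits, cfg,
            )[0]
            for rh in (0.3, 0.5, 0.7, 0.9)
        ]
        assert np.all(np.diff(q_rh) < 0)
        q_sun = [
            evaporative_flow_profile(
                h, Environment(**base, relative_humidity=0.5, solar_radiation=s),
                traits, cfg,
            )[0]
            for s in (50.0, 150.0, 250.0, 350.0)
        ]
        assert np.all(np.diff(q_sun) > 0)
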