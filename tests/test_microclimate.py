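"""Physics core: radiation, resistances, leaf balance, snow, soil, column."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeline_thermo import ARCHETYPES, generate_forcing, simulate
from treeline_thermo.microclimate import (
    SIGMA,
    PhysicsParams,
    SnowState,
    SoilState,
    aerodynamic_resistance,
    attenuate_shortwave,
    leaf_energy_balance,
    saturation_vapor_pressure,
    step_snowpack,
    step_soil_heat,
)
from treeline_thermo.vegetation import FunctionalGroup, VegetationScenario


class TestAttenuateShortwave:
    def test_no_canopy_full_transmission(self):
        absorbed, g_abs, g_inc = attenuate_shortwave(
            500.0, np.zeros(20), 0.5, ground_albedo=0.2)
        assert g_inc == pytest.approx(500.0)
        assert absorbed.sum() == 0.0

    def test_closed_form_ground_incidence(self):
        lad = np.zeros(20)
        lad[5] = 2.0
        _, _, g_inc = attenuate_shortwave(500.0, lad, 0.5, 0.2)
        assert g_inc == pytest.approx(500.0 * math.exp(-1.0), rel=1e-12)

    def test_slab_composition(self):
        """20 thin sub-layers transmit exactly like one slab."""
        profile = np.full(20, 2.0 / 20)
        _, _, g_split = attenuate_shortwave(500.0, profile, 0.5, 0.2)
        lad1 = np.zeros(20)
        lad1[0] = 2.0
        _, _, g_slab = attenuate_shortwave(500.0, lad1, 0.5, 0.2)
        assert g_split == pytest.approx(g_slab, abs=1e-9)

    @given(sw=st.floats(0, 1200), lai=st.floats(0, 8), k=st.floats(0.1, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_radiation_accounting_closes(self, sw, lai, k):
        """absorbed + reflected + ground terms account for all of SW_in."""
        refl = 0.1
        albedo = 0.2
        lad = np.full(20, lai / 20)
        absorbed, g_abs, g_inc = attenuate_shortwave(sw, lad, k, albedo, refl)
        intercepted = absorbed.sum() / (1 - refl) if refl < 1 else 0.0
        canopy_reflected = intercepted * refl
        total = absorbed.sum() + canopy_reflected + g_abs + g_inc * albedo
        assert total == pytest.approx(sw, abs=1e-9 * max(sw, 1))

    @given(lai_lo=st.floats(0, 8), lai_hi=st.floats(0, 8))
    @settings(max_examples=100, deadline=None)
    def test_shading_monotone_in_lai(self, lai_lo, lai_hi):
        """Ground absorbed shortwave never increases with total LAI."""
        lo, hi = sorted((lai_lo, lai_hi))
        _, g_lo, _ = attenuate_shortwave(800.0, np.full(20, lo / 20), 0.5, 0.2)
        _, g_hi, _ = attenuate_shortwave(800.0, np.full(20, hi / 20), 0.5, 0.2)
        assert g_hi <= g_lo + 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            attenuate_shortwave(-1.0, np.zeros(20), 0.5, 0.2)


class TestAerodynamicResistance:
    def test_monotone_decreasing_in_wind(self):
        r = [aerodynamic_resistance(u, 10.0, 1.0) for u in (1, 2, 5, 10)]
        assert all(a > b for a, b in zip(r, r[1:]))

    def test_wind_floor(self):
        assert aerodynamic_resistance(0.0, 10.0, 1.0) == aerodynamic_resistance(
            0.5, 10.0, 1.0)

    def test_matches_hand_computed_log_profile(self):
        # h=1 m: d=0.67, z0=0.1; r = ln((10-0.67)/0.1)^2 / (0.4^2 * 2)
        expected = math.log(9.33 / 0.1) ** 2 / (0.16 * 2.0)
        assert aerodynamic_resistance(2.0, 10.0, 1.0) == pytest.approx(
            expected, rel=1e-12)

    def test_measurement_below_displacement_rejected(self):
        with pytest.raises(ValueError):
            aerodynamic_resistance(2.0, 5.0, 10.0)


def _brute_force_leaf(absorbed, t_air, rh, r_a, stomata_open, params,
                      pressure=101.325, lai=1.0):
    """Independent grid scan of the leaf energy-balance residual."""
    from treeline_thermo.microclimate import CP_AIR, GAMMA_PSY, R_DRY

    rho = pressure * 1000.0 / (R_DRY * t_air)
    a = rho * CP_AIR / r_a
    r_s = (params.stomatal_open if stomata_open
           else params.stomatal_closed) / lai
    b = rho * CP_AIR / (GAMMA_PSY * (r_a + r_s))
    e_air = rh / 100.0 * float(saturation_vapor_pressure(t_air))
    T = np.arange(t_air - params.leaf_bracket, t_air + params.leaf_bracket,
                  0.001)
    res = (absorbed - a * (T - t_air)
           - b * (saturation_vapor_pressure(T) - e_air)
           - params.leaf_emissivity * SIGMA * (T**4 - t_air**4))
    return float(T[np.argmin(np.abs(res))])


class TestLeafEnergyBalance:
    def test_equilibrium_no_drivers(self):
        t, le, h = leaf_energy_balance(0.0, 285.0, 100.0, 50.0, True)
        assert t == pytest.approx(285.0, abs=1e-4)
        assert le == pytest.approx(0.0, abs=0.01)
        assert h == pytest.approx(0.0, abs=0.01)

    def test_absorption_warms_leaf(self):
        t, le, h = leaf_energy_balance(300.0, 285.0, 100.0, 50.0, True)
        assert t > 285.0
        assert h > 0.0
        assert le > 0.0

    def test_closed_stomata_suppress_latent_heat(self):
        _, le_open, _ = leaf_energy_balance(300.0, 285.0, 40.0, 50.0, True)
        _, le_closed, _ = leaf_energy_balance(300.0, 285.0, 40.0, 50.0, False)
        assert le_closed < le_open

    def test_root_matches_brute_force_scan(self, rng):
        """Solver equals an exhaustive 1 mK residual scan."""
        params = PhysicsParams()
        for _ in range(60):
            absorbed = rng.uniform(0, 700)
            t_air = rng.uniform(250, 305)
            rh = rng.uniform(20, 100)
            r_a = rng.uniform(5, 300)
            open_ = bool(rng.random() < 0.5)
            t, _, _ = leaf_energy_balance(absorbed, t_air, rh, r_a, open_,
                                          params)
            t_ref = _brute_force_leaf(absorbed, t_air, rh, r_a, open_, params)
            assert t == pytest.approx(t_ref, abs=2e-3)


class TestSnowpack:
    def test_pure_accumulation(self):
        snow, used = step_snowpack(SnowState(), 5.0, 0.0, 1800.0)
        assert snow.swe == pytest.approx(5.0)
        assert used == 0.0

    def test_latent_heat_closed_form(self):
        """3.34 MJ/m2 melts exactly 10 mm at 0.334 MJ/kg."""
        params = PhysicsParams()
        energy = 3.34e6 / 1800.0
        snow, used = step_snowpack(SnowState(swe=10.0), 0.0, energy, 1800.0,
                                   params)
        assert snow.swe == pytest.approx(0.0, abs=1e-9)
        assert used == pytest.approx(energy)

    def test_melt_capped_at_available_swe(self):
        params = PhysicsParams()
        energy_for_5mm = 5.0 * params.latent_heat_fusion / 1800.0
        snow, used = step_snowpack(SnowState(swe=2.0), 0.0, energy_for_5mm,
                                   1800.0, params)
        assert snow.swe == 0.0
        assert used == pytest.approx(2.0 * params.latent_heat_fusion / 1800.0)
        assert used < energy_for_5mm  # surplus returned to the caller

    def test_surface_capped_at_freezing_while_snow(self):
        snow, _ = step_snowpack(SnowState(swe=50.0, surface_temp=270.0), 0.0,
                                0.0, 1800.0, T_air=285.0)
        assert snow.surface_temp <= 273.15

    def test_albedo_ages_and_resets(self):
        params = PhysicsParams()
        snow = SnowState(swe=50.0, age_seconds=0.0)
        for _ in range(48 * 20):  # 20 days, no fresh snow
            snow, _ = step_snowpack(snow, 0.0, 0.0, 1800.0, params,
                                    T_air=265.0)
        assert snow.albedo < 0.65
        snow, _ = step_snowpack(snow, 5.0, 0.0, 1800.0, params, T_air=265.0)
        assert snow.albedo == pytest.approx(params.snow_albedo_fresh)

    def test_negative_snowfall_rejected(self):
        with pytest.raises(ValueError):
            step_snowpack(SnowState(), -1.0, 0.0, 1800.0)


class TestSoilHeat:
    def test_uniform_equilibrium(self):
        params = PhysicsParams()
        soil = SoilState.uniform(280.0, params)
        out = step_soil_heat(soil, 0.0, 1800.0)
        np.testing.assert_allclose(out.layer_temps, 280.0, atol=1e-12)

    def test_energy_conservation_under_sustained_flux(self):
        params = PhysicsParams()
        soil = SoilState.uniform(275.0, params)
        e0 = soil.energy()
        G, dt, n = 50.0, 1800.0, 480
        for _ in range(n):
            soil = step_soil_heat(soil, G, dt)
        gained = soil.energy() - e0
        assert gained == pytest.approx(G * dt * n, rel=1e-9)

    def test_step_response_approaches_uniform(self):
        """Zero-flux bottom: a pulse equilibrates to a warmer uniform
        column."""
        params = PhysicsParams()
        soil = SoilState.uniform(275.0, params)
        for _ in range(48 * 5):
            soil = step_soil_heat(soil, 20.0, 1800.0)
        for _ in range(48 * 400):
            soil = step_soil_heat(soil, 0.0, 1800.0)
        assert np.ptp(soil.layer_temps) < 0.01
        assert soil.layer_temps.mean() > 275.0

    def test_unstable_step_rejected(self):
        params = PhysicsParams()
        soil = SoilState.uniform(275.0, params)
        with pytest.raises(ValueError, match="unstable"):
            step_soil_heat(soil, 0.0, 1e6)


def _isothermal_forcing(n_days, T0):
    n = n_days * 48
    return pd.DataFrame({
        "timestamp": (np.datetime64("2001-01-01")
                      + (np.arange(n) * 1800).astype("timedelta64[s]")),
        "SW_in": 0.0,
        "LW_in": SIGMA * T0**4,
        "T_air": T0,
        "precip": 0.0,
        "phase": "rain",
        "wind": 2.0,
        "RH": 100.0,
        "pressure": 101.325,
        "year": 0,
        "doy": np.arange(n) // 48 + 1,
        "hour": np.tile(np.arange(48) * 0.5, n_days),
    })


@pytest.fixture(scope="module")
def grass_scenario():
    return VegetationScenario(
        label="T-grass", groups=(FunctionalGroup(
            name="grass_or_sedge", max_LAI=1.5, canopy_top=0.3),), h_e=12.0)


@pytest.fixture(scope="module")
def tree_scenario():
    return VegetationScenario(
        label="T-tree", groups=(FunctionalGroup(
            name="evergreen_needleleaf_tree", max_LAI=4.0, canopy_top=12.0,
            canopy_bottom=1.0, evergreen=True, stem_area_index=0.5),),
        h_e=12.0)


@pytest.fixture(scope="module")
def winter_slice():
    """60 days of alpine forcing starting in winter."""
    return generate_forcing(ARCHETYPES["alpine"], 1, seed=21).head(60 * 48)


class TestSimulate:
    def test_isothermal_equilibrium(self, tree_scenario):
        """Blackbody sky at the air temperature, no sun, saturated air:
        the column stays at its initial uniform temperature and exchanges
        no turbulent heat."""
        T0 = 285.0
        forcing = _isothermal_forcing(5, T0)
        out = simulate(forcing, tree_scenario, initial_temp=T0)
        t = out.table
        assert np.abs(t["T_surf"] - T0).max() < 0.05
        assert np.abs(t["LE"]).max() < 0.5
        assert np.abs(t["H"]).max() < 0.5

    def test_bit_identical_reruns(self, winter_slice, grass_scenario):
        a = simulate(winter_slice, grass_scenario)
        b = simulate(winter_slice, grass_scenario)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.layer_temps, b.layer_temps)

    def test_energy_closure_every_step(self, winter_slice, tree_scenario):
        out = simulate(winter_slice, tree_scenario)
        assert np.abs(out.table["closure_residual"]).max() <= 1.0

    def test_snow_mass_balance_exact(self, winter_slice, tree_scenario,
                                     grass_scenario):
        """Change in SWE equals snowfall - melt - wind scour exactly."""
        for scen in (tree_scenario, grass_scenario):
            t = simulate(winter_slice, scen).table
            budget = (t["snowfall"].sum() - t["melt_mm"].sum()
                      - t["scour_mm"].sum())
            assert t["swe"].iloc[-1] == pytest.approx(budget, abs=1e-9)

    def test_melt_pins_surface_at_freezing(self, tree_scenario):
        """While snow is present and melting, the thermodynamic surface
        temperature is exactly 273.15 K."""
        f = generate_forcing(ARCHETYPES["alpine"], 1, seed=21)
        spring = f[(f["doy"] > 60) & (f["doy"] < 200)].reset_index(drop=True)
        t = simulate(spring, tree_scenario).table
        melting = (t["swe"] > 0) & (t["melt_mm"] > 0)
        assert melting.any()
        assert (t.loc[melting, "T_surf"] == 273.15).all()

    def test_snow_surface_never_above_freezing(self, winter_slice,
                                               tree_scenario):
        t = simulate(winter_slice, tree_scenario).table
        snowy = t["swe"] > 0
        assert (t.loc[snowy, "T_snow_surf"] <= 273.15 + 1e-9).all()

    def test_temperatures_within_sanity_bounds(self, winter_slice,
                                               tree_scenario):
        t = simulate(winter_slice, tree_scenario).table
        assert t["T_surf"].between(180.0, 340.0).all()
        lt = simulate(winter_slice, tree_scenario).layer_temps
        finite = lt[np.isfinite(lt)]
        assert ((finite > 180.0) & (finite < 340.0)).all()
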