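import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropdrivers.crop_model import (
    CANONICAL_TREATMENTS,
    CropParameters,
    canopy_temperature,
    co2_factors,
    daily_vpd,
    heat_stress_retention,
    preset,
    saturation_vapor_pressure,
    simulate_season,
    thermal_time_increment,
    transpiration_demand,
    water_balance_step,
)
from cropdrivers.synthetic_data import SoilProfile, ScenarioDeltas, apply_delta_change


class TestPsychrometrics:
    def test_tetens_values(self):
        assert saturation_vapor_pressure(0.0) == pytest.approx(0.6108)
        assert saturation_vapor_pressure(20.0) == pytest.approx(2.339, abs=1e-3)

    def test_convexity_drives_nonlinear_demand(self):
        es = saturation_vapor_pressure
        assert es(30.0) - es(25.0) > es(15.0) - es(10.0)

    def test_vpd(self):
        es20 = saturation_vapor_pressure(20.0)
        assert daily_vpd(20.0, 20.0, es20) == pytest.approx(0.0)
        assert daily_vpd(20.0, 20.0, 0.0) == pytest.approx(es20)
        # warming both extremes at fixed humidity raises demand
        assert daily_vpd(30.0, 20.0, 1.0) > daily_vpd(25.0, 15.0, 1.0)
        with pytest.raises(ValueError):
            daily_vpd(10.0, 20.0, 1.0)


class TestThermalTime:
    @pytest.mark.parametrize(
        "tavg,expected", [(0.0, 0.0), (12.0, 12.0), (35.0, 30.0), (-5.0, 0.0)]
    )
    def test_piecewise_response(self, tavg, expected):
        assert thermal_time_increment(tavg, 0.0, 30.0) == expected

    def test_base_must_be_below_opt(self):
        with pytest.raises(ValueError):
            thermal_time_increment(10.0, 20.0, 10.0)


class TestCanopyTemperature:
    def test_cooling_and_heating_limits(self):
        p = preset("winter_wheat").replace(delta_heat=5.0, delta_cool=2.0)
        assert canopy_temperature(30.0, 1.0, p) == pytest.approx(28.0)
        assert canopy_temperature(30.0, 0.0, p) == pytest.approx(35.0)
        # strictly decreasing in the water factor
        assert canopy_temperature(30.0, 0.3, p) > canopy_temperature(30.0, 0.7, p)

    def test_zero_offsets_reduce_to_air(self):
        p = preset("winter_wheat").replace(delta_heat=0.0, delta_cool=0.0)
        for f_w in (0.0, 0.5, 1.0):
            assert canopy_temperature(25.0, f_w, p) == 25.0

    def test_rejects_out_of_range_stress(self):
        with pytest.raises(ValueError):
            canopy_temperature(25.0, 1.2, preset("winter_wheat"))


class TestHeatRetention:
    def test_no_exceedance_keeps_full_harvest_index(self):
        assert heat_stress_retention([28.0, 30.0, 31.0], 31.0, 0.05) == 1.0

    def test_single_exceedance(self):
        assert heat_stress_retention([33.0], 31.0, 0.05) == pytest.approx(0.90)

    def test_floor_at_zero(self):
        assert heat_stress_retention([80.0] * 10, 31.0, 0.05) == 0.0


class TestCo2Factors:
    def test_reference_point(self):
        for crop in ("winter_wheat", "grain_maize"):
            p = preset(crop)
            assert co2_factors(p.crop_class, 360.0, p) == (1.0, 1.0, 1.0)

    def test_c4_photosynthesis_is_co2_saturated(self):
        p = preset("grain_maize")
        rue, te, lai = co2_factors("C4", 571.0, p)
        assert rue == 1.0 and lai == 1.0 and te > 1.0

    def test_c3_log_response(self):
        p = preset("winter_wheat").replace(beta_rue=0.08)
        rue, te, lai = co2_factors("C3", 571.0, p)
        assert rue == pytest.approx(1.0369, abs=1e-4)
        assert te == pytest.approx(1.0 + 0.10 * math.log(571 / 360), rel=1e-12)

    def test_below_ambient_rejected(self):
        with pytest.raises(ValueError):
            co2_factors("C3", 300.0, preset("winter_wheat"))

    def test_c4_invariants_enforced(self):
        with pytest.raises(ValueError):
            preset("grain_maize").replace(beta_rue=0.05)


class TestTranspirationDemand:
    def test_zero_vpd_zero_demand(self):
        assert transpiration_demand(20.0, 0.0, 5.0) == 0.0

    def test_linear_in_vpd_and_te(self):
        d1 = transpiration_demand(20.0, 1.0, 5.0)
        assert transpiration_demand(20.0, 2.0, 5.0) == pytest.approx(2 * d1)
        assert transpiration_demand(20.0, 1.0, 5.0, te_mult=1.1) == pytest.approx(
            d1 / 1.1
        )

    def test_te_must_be_nonzero(self):
        with pytest.raises(ValueError):
            transpiration_demand(20.0, 1.0, 0.0)


class TestWaterBalance:
    def test_irrigation_forces_unstressed(self, soil):
        step = water_balance_step(10.0, 0.0, 8.0, soil, irrigation=True)
        assert step.f_w == 1.0
        assert step.supply == 8.0
        assert step.irrigation_applied == pytest.approx(8.0 - min(8.0, 1.0))

    def test_empty_bucket_full_stress(self, soil):
        step = water_balance_step(0.0, 0.0, 5.0, soil, irrigation=False)
        assert step.f_w == 0.0 and step.supply == 0.0

    def test_zero_demand_is_unstressed(self, soil):
        assert water_balance_step(50.0, 2.0, 0.0, soil, irrigation=False).f_w == 1.0

    def test_overflow_becomes_drainage(self, soil):
        step = water_balance_step(soil.tawc_mm, 30.0, 0.0, soil, irrigation=False)
        assert step.drainage == pytest.approx(30.0)
        assert step.new_state == soil.tawc_mm

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_conservation_on_random_trajectories(self, seed):
        # bookkeeping oracle: inflows - outflows == change of store to 1e-9 mm
        soil = SoilProfile(depth_cm=100.0, tawc_mm=140.0, wp=0.10, fc=0.24)
        rng = np.random.default_rng(seed)
        state = float(rng.uniform(0, soil.tawc_mm))
        start = state
        total_in = total_out = 0.0
        for _ in range(100):
            precip = float(rng.exponential(2.0)) if rng.random() < 0.4 else 0.0
            demand = float(rng.uniform(0, 6.0))
            irrigation = bool(rng.random() < 0.3)
            step = water_balance_step(state, precip, demand, soil, irrigation)
            total_in += precip + step.irrigation_applied
            total_out += step.supply + step.drainage
            state = step.new_state
        assert total_in - total_out == pytest.approx(state - start, abs=1e-9)

    def test_rejects_negative_inputs(self, soil):
        with pytest.raises(ValueError):
            water_balance_step(-1.0, 0.0, 1.0, soil, irrigation=False)
        with pytest.raises(ValueError):
            water_balance_step(1.0, 0.0, -1.0, soil, irrigation=False)


class TestSimulateSeason:
    def test_zero_radiation_means_zero_yield(self, soil, south_weather):
        w = south_weather.copy()
        w.data["rad"] = 1e-12
        res = simulate_season(
            w, soil, preset("grain_maize"), CANONICAL_TREATMENTS["T1"]
        )
        assert res.yield_t_ha == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("crop", ["winter_wheat", "grain_maize"])
    def test_warming_matures_strictly_earlier(self, soil, south_weather,
                                              central_weather, crop):
        params = preset(crop)
        for w in (south_weather, central_weather):
            warmed = apply_delta_change(
                w, ScenarioDeltas(scenario_id="w", temp_offsets=(2.0,) * 12)
            )
            base = simulate_season(w, soil, params, CANONICAL_TREATMENTS["T1"])
            warm = simulate_season(warmed, soil, params, CANONICAL_TREATMENTS["T1"])
            assert base.matured and warm.matured
            assert warm.maturity_date < base.maturity_date

    def test_stress_switch_ordering(self, soil, south_weather):
        params = preset("grain_maize")
        res = {
            t: simulate_season(south_weather, soil, params, CANONICAL_TREATMENTS[t])
            for t in CANONICAL_TREATMENTS
        }
        y = {t: r.yield_t_ha for t, r in res.items()}
        assert y["T1"] >= y["T2"] >= 0
        assert y["T3"] >= y["T2"]  # transpirational cooling under irrigation
        assert y["T1"] >= y["T4"] >= y["T5"]
        assert y["T4"] >= y["T6"]
        for t in ("T1", "T2", "T3"):
            assert res[t].mean_fw == 1.0

    def test_c4_potential_invariant_to_co2(self, soil, south_weather):
        params = preset("grain_maize")
        ys = [
            simulate_season(
                south_weather, soil, params, CANONICAL_TREATMENTS["T1"], co2=c
            ).yield_t_ha
            for c in (360.0, 442.0, 499.0, 571.0)
        ]
        assert len(set(ys)) == 1  # bit-identical

    def test_c3_potential_nondecreasing_in_co2(self, soil, central_weather):
        params = preset("winter_wheat")
        ys = [
            simulate_season(
                central_weather, soil, params, CANONICAL_TREATMENTS["T1"], co2=c
            ).yield_t_ha
            for c in (360.0, 442.0, 499.0, 571.0)
        ]
        assert all(b >= a for a, b in zip(ys, ys[1:]))
        assert ys[-1] > ys[0]

    @pytest.mark.parametrize("crop", ["winter_wheat", "grain_maize"])
    def test_water_limited_nondecreasing_in_co2(self, soil, south_weather, crop):
        params = preset(crop)
        ys = [
            simulate_season(
                south_weather, soil, params, CANONICAL_TREATMENTS["T4"], co2=c
            ).yield_t_ha
            for c in (360.0, 442.0, 499.0, 571.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))

    def test_rejects_nan_weather(self, soil, south_weather):
        w = south_weather.copy()
        w.data.loc[5, "rad"] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            simulate_season(w, soil, preset("grain_maize"), CANONICAL_TREATMENTS["T1"])

    def test_yield_within_biomass_harvest_index(self, soil, south_weather):
        params = preset("grain_maize")
        res = simulate_season(south_weather, soil, params, CANONICAL_TREATMENTS["T6"])
        assert 0 <= res.yield_t_ha <= res.biomass_t_ha * params.harvest_index + 1e-12
        assert res.maturity_date >= res.anthesis_date >= res.sowing_date
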