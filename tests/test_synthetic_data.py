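import numpy as np
import pandas as pd
import pytest

from cropdrivers.synthetic_data import (
    CLIMATE_PROFILES,
    ClimateProfile,
    RegionPlan,
    ScenarioDeltas,
    SoilProfile,
    WET_DAY_MM,
    apply_delta_change,
    derive_field_capacity,
    generate_grid,
    generate_weather,
    initial_soil_water,
    plan_flips,
    synthesize_observed_yields,
    wind_at_2m,
)


class TestGenerateWeather:
    def test_deterministic_under_seed(self):
        p = CLIMATE_PROFILES["central"]
        a = generate_weather(p, 30, seed=1)
        b = generate_weather(p, 30, seed=1)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_weather(p, 30, seed=2)
        assert not a.data["tavg"].equals(c.data["tavg"])

    def test_invariants_hold(self):
        for p in CLIMATE_PROFILES.values():
            w = generate_weather(p, 4, seed=3)
            df = w.data
            assert (df["tmin"] <= df["tavg"]).all()
            assert (df["tavg"] <= df["tmax"]).all()
            assert (df["precip"] >= 0).all()
            assert (df["rad"] > 0).all()
            assert (df["ea"] >= 0).all()
            assert w.n_years == 4

    def test_degenerate_noise_gives_pure_cycle(self):
        p = ClimateProfile(tavg_sd=0.0, wet_prob=(0.0,) * 12, wind_sd=0.0)
        w = generate_weather(p, 2, seed=9)
        doy = pd.DatetimeIndex(w.data["date"]).dayofyear.to_numpy()
        expected = p.tavg_mean + p.tavg_amplitude * np.cos(
            2 * np.pi * (doy - p.peak_doy) / 365.25
        )
        np.testing.assert_allclose(w.data["tavg"], expected, atol=1e-12)
        assert (w.data["precip"] == 0).all()

    def test_long_run_mean_matches_profile(self):
        # Monte-Carlo check against the generator's closed-form annual mean
        p = CLIMATE_PROFILES["central"]
        w = generate_weather(p, 200, seed=7)
        assert abs(w.data["tavg"].mean() - p.tavg_mean) < 0.2

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_weather(CLIMATE_PROFILES["central"], 0, seed=1)
        with pytest.raises(ValueError):
            ClimateProfile(diurnal_range=-1.0)


class TestDeltaChange:
    def test_baseline_deltas_are_identity(self, central_weather):
        out = apply_delta_change(central_weather, ScenarioDeltas.baseline())
        pd.testing.assert_frame_equal(out.data, central_weather.data)

    def test_uniform_offset_is_pure_shift(self, central_weather):
        deltas = ScenarioDeltas(scenario_id="s", temp_offsets=(2.0,) * 12)
        out = apply_delta_change(central_weather, deltas)
        for col in ("tmin", "tavg", "tmax"):
            np.testing.assert_allclose(
                out.data[col], central_weather.data[col] + 2.0
            )
        np.testing.assert_allclose(out.data["precip"], central_weather.data["precip"])

    def test_wet_to_dry_flip_adjusts_radiation(self, central_weather):
        df = central_weather.data
        wet_days = df.loc[df["precip"] >= WET_DAY_MM, "date"]
        day = pd.Timestamp(wet_days.iloc[10])
        rad_before = float(df.loc[df["date"] == day, "rad"].iloc[0])
        out = apply_delta_change(
            central_weather, ScenarioDeltas(scenario_id="s", wet_to_dry=[day])
        )
        row = out.data[out.data["date"] == day].iloc[0]
        assert row["precip"] == 0.0
        assert row["rad"] == pytest.approx(rad_before * 1.10, rel=1e-12)
        # all other days untouched
        others = out.data["date"] != day
        np.testing.assert_allclose(out.data.loc[others, "rad"], df.loc[others, "rad"])

    def test_dry_to_wet_flip(self, central_weather):
        df = central_weather.data
        dry_days = df.loc[df["precip"] < WET_DAY_MM, "date"]
        day = pd.Timestamp(dry_days.iloc[5])
        rad_before = float(df.loc[df["date"] == day, "rad"].iloc[0])
        out = apply_delta_change(
            central_weather,
            ScenarioDeltas(scenario_id="s", dry_to_wet={day: 4.0}),
        )
        row = out.data[out.data["date"] == day].iloc[0]
        assert row["precip"] == 4.0
        assert row["rad"] == pytest.approx(rad_before * 0.90, rel=1e-12)

    def test_inconsistent_flip_raises(self, central_weather):
        df = central_weather.data
        dry_day = pd.Timestamp(df.loc[df["precip"] < WET_DAY_MM, "date"].iloc[0])
        with pytest.raises(ValueError, match="dry"):
            apply_delta_change(
                central_weather,
                ScenarioDeltas(scenario_id="s", wet_to_dry=[dry_day]),
            )
        with pytest.raises(ValueError):
            ScenarioDeltas(scenario_id="s", precip_factors=(-0.5,) * 12)

    def test_plan_flips_consistent_with_baseline(self, central_weather):
        w2d, d2w = plan_flips(central_weather, 0.2, 0.1, seed=4)
        assert len(w2d) > 0 and len(d2w) > 0
        # the drawn plan must apply without consistency errors
        out = apply_delta_change(
            central_weather,
            ScenarioDeltas(scenario_id="s", wet_to_dry=w2d, dry_to_wet=d2w),
        )
        out.validate()


class TestSoilHelpers:
    def test_wind_profile_conversion(self):
        assert wind_at_2m(0.0) == 0.0
        assert wind_at_2m(3.0) == pytest.approx(2.2439, abs=1e-3)
        assert wind_at_2m(2.0) < wind_at_2m(3.0)
        with pytest.raises(ValueError):
            wind_at_2m(-1.0)

    @pytest.mark.parametrize(
        "wp,tawc,depth,expected",
        [(0.10, 120.0, 100.0, 0.22), (0.13, 0.0, 80.0, 0.13),
         (0.15, 90.0, 60.0, 0.30)],
    )
    def test_field_capacity_formula(self, wp, tawc, depth, expected):
        assert derive_field_capacity(wp, tawc, depth) == pytest.approx(expected)

    def test_field_capacity_guards(self):
        with pytest.raises(ValueError, match="40 cm"):
            derive_field_capacity(0.1, 100.0, 35.0)
        with pytest.raises(ValueError, match="saturation"):
            derive_field_capacity(0.2, 300.0, 100.0, saturation=0.45)

    @pytest.mark.parametrize(
        "tawc,raw,expected", [(100.0, 0.5, 85.0), (0.0, 0.5, 0.0), (100.0, 1.0, 70.0)]
    )
    def test_initial_water_depletion_rule(self, tawc, raw, expected):
        profile = SoilProfile(
            depth_cm=100.0, tawc_mm=tawc, wp=0.10, fc=0.10 + tawc / 1000.0
        ) if tawc > 0 else None
        if profile is None:
            profile = SoilProfile(depth_cm=100.0, tawc_mm=1e-9, wp=0.10,
                                  fc=0.10 + 1e-12)
            assert initial_soil_water(profile, raw) == pytest.approx(0.0, abs=1e-9)
            return
        assert initial_soil_water(profile, raw) == pytest.approx(expected)

    def test_initial_water_rejects_bad_fraction(self, soil):
        with pytest.raises(ValueError):
            initial_soil_water(soil, 0.0)
        with pytest.raises(ValueError):
            initial_soil_water(soil, 1.5)


class TestGenerateGrid:
    def test_depth_exclusion_and_determinism(self, small_plan):
        a = generate_grid(50, seed=3, region_plan=small_plan)
        b = generate_grid(50, seed=3, region_plan=small_plan)
        assert all(c.soil.depth_cm >= 40 for c in a)
        assert [c.soil.tawc_mm for c in a] == [c.soil.tawc_mm for c in b]
        assert {c.region for c in a} == {"A", "B"}

    def test_single_cell(self, small_plan):
        cells = generate_grid(1, seed=1, region_plan=small_plan)
        assert len(cells) == 1 and cells[0].region == "A"
        assert all(v >= 0 for v in cells[0].rainfed_area.values())

    def test_all_shallow_plan_respects_strictness(self):
        plan = RegionPlan(
            regions=("A",), lat_band={"A": "south"},
            depth_mean_cm=35.0, depth_sd_cm=0.0,
        )
        with pytest.raises(ValueError):
            generate_grid(3, seed=1, region_plan=plan, strict=True)
        with pytest.raises(ValueError, match="rejected"):
            generate_grid(3, seed=1, region_plan=plan, strict=False)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            RegionPlan(regions=(), lat_band={})


class TestObservedYields:
    def _truth(self, n=20):
        years = np.arange(1990, 1990 + n)
        rng = np.random.default_rng(0)
        return pd.Series(6.0 + rng.normal(0, 0.5, n), index=years)

    def test_zero_noise_zero_trend_is_identity(self):
        truth = self._truth()
        obs = synthesize_observed_yields(truth, 0.0, 0.0, seed=1)
        np.testing.assert_allclose(obs.yields, truth.to_numpy())

    def test_reproducible_and_metadata(self):
        truth = self._truth()
        a = synthesize_observed_yields(truth, 0.05, 0.3, seed=9)
        b = synthesize_observed_yields(truth, 0.05, 0.3, seed=9)
        np.testing.assert_array_equal(a.yields, b.yields)
        assert a.meta["seed"] == 9 and a.meta["trend_slope"] == 0.05

    def test_trend_removed_by_detrending(self):
        from cropdrivers.evaluation import detrend_moving_window

        truth = self._truth(30)
        obs = synthesize_observed_yields(truth, 0.05, 0.0, seed=1)
        a_obs = detrend_moving_window(obs.as_series())
        a_truth = detrend_moving_window(truth)
        # centred windows annihilate the added linear trend at interior years
        np.testing.assert_allclose(
            a_obs.iloc[2:-2], a_truth.iloc[2:-2], atol=1e-9
        )

    def test_rejects_negative_noise_and_short_truth(self):
        with pytest.raises(ValueError):
            synthesize_observed_yields(self._truth(), 0.0, -0.1, seed=1)
        with pytest.raises(ValueError):
            synthesize_observed_yields(self._truth(2), 0.0, 0.1, seed=1)
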