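"""Crop simulator: phenology, soil physics, events, yield accounting."""

import numpy as np
import pandas as pd
import pytest

import arscore
from arscore.cropsim import (CropParams, CropState, SoilProfile, simulate_season,
                             soil_temperature_profile, step_soil_water,
                             thermal_time, traces_from_csv, traces_to_csv)
from arscore.weathergen import ClimateParams, WeatherSeries, generate_weather


def constant_weather(tmean, n_years=2, precip=0.0, radiation=10.0):
    days = n_years * 365
    df = pd.DataFrame({
        "year": np.repeat(np.arange(1, n_years + 1), 365),
        "doy": np.tile(np.arange(1, 366), n_years),
        "tmin": tmean - 1, "tmean": tmean, "tmax": tmean + 1,
        "precip": precip, "radiation": radiation,
    })
    return WeatherSeries(data=df, station_label="const")


class TestThermalTime:
    def test_zero_at_base_temperature(self):
        series = constant_weather(5.0, 1)
        tt = thermal_time(series, 1, 1, base_temp=5.0)
        assert np.all(tt == 0.0)

    def test_constant_increment(self):
        series = constant_weather(10.0, 1)
        tt = thermal_time(series, 1, 1, base_temp=5.0)
        assert tt[9] == pytest.approx(50.0)

    def test_matches_brute_force_loop(self, weather_7y):
        tt = thermal_time(weather_7y, 2, 100, base_temp=0.0)
        df = weather_7y.data
        sub = df[(df["year"] > 2) | ((df["year"] == 2) & (df["doy"] >= 100))]
        acc, expected = 0.0, []
        for t in sub["tmean"]:
            acc += max(0.0, t - 0.0)
            expected.append(acc)
        np.testing.assert_allclose(tt, expected)
        assert np.all(np.diff(tt) >= 0)

    def test_start_outside_series_rejected(self, weather_7y):
        with pytest.raises(ValueError):
            thermal_time(weather_7y, 99, 1, 0.0)


class TestSoilTemperature:
    def test_constant_forcing_converges(self):
        temps = soil_temperature_profile([12.0] * 400, [5, 10, 50])
        for v in temps.values():
            assert v == pytest.approx(12.0, abs=1e-6)

    def test_amplitude_damped_with_depth(self):
        days = np.arange(730)
        forcing = 10 + 8 * np.sin(2 * np.pi * days / 365)
        # track each depth over the final year by repeated calls
        series = {d: [] for d in (5, 50)}
        state = {d: forcing[0] for d in (5, 50)}
        for t_air in forcing:
            for d in (5, 50):
                tau = 1.0 + d / 15.0
                state[d] += (t_air - state[d]) / tau
                series[d].append(state[d])
        amp5 = np.ptp(series[5][-365:])
        amp50 = np.ptp(series[50][-365:])
        assert amp50 < amp5

    def test_step_response_slower_at_depth(self):
        history = [0.0] * 50
        half_time = {}
        for depth in (5, 50):
            temp, tau = 0.0, 1.0 + depth / 15.0
            for day in range(1, 1000):
                temp += (10.0 - temp) / tau
                if temp >= 5.0:
                    half_time[depth] = day
                    break
        final = soil_temperature_profile(history + [10.0] * 5, [5, 50])
        assert half_time[50] > half_time[5]
        assert final[5] > final[50]  # shallow tracks the step faster

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            soil_temperature_profile([], [5])


def _bare_state(soil, water_pct, lai=0.0, bbch=0.0):
    return CropState(year=1, doy=1, bbch=bbch, lai=lai, agb=0.0, gen_biomass=0.0,
                     soil_water={c: water_pct for c in soil.water_columns},
                     soil_temp={c: 10.0 for c in soil.temp_columns})


class TestSoilWater:
    def test_closed_system_unchanged(self, default_soil):
        crop = CropParams(soil_evap_coeff=0.0)
        state = _bare_state(default_soil, 25.0, lai=0.0)
        day = {"precip": 0.0, "radiation": 10.0, "tmean": 12.0}
        new, stress, bal = step_soil_water(state, day, default_soil, crop)
        for c in default_soil.water_columns:
            assert new[c] == pytest.approx(25.0)
        assert bal["transpiration"] == 0.0

    def test_heavy_rain_capped_at_field_capacity(self, default_soil, default_crop):
        state = _bare_state(default_soil, default_soil.field_capacity_pct)
        day = {"precip": 80.0, "radiation": 0.0, "tmean": 10.0}
        new, _, bal = step_soil_water(state, day, default_soil, default_crop)
        for c in default_soil.water_columns:
            assert new[c] <= default_soil.field_capacity_pct + 1e-9
        assert bal["drainage"] == pytest.approx(80.0)  # profile already full

    def test_daily_mass_balance_closes(self, default_soil, default_crop):
        rng = np.random.default_rng(0)
        state = _bare_state(default_soil, 28.0, lai=3.0, bbch=35.0)
        cap = default_soil.layer_capacity_mm
        for _ in range(60):
            day = {"precip": float(rng.exponential(2.0)),
                   "radiation": float(rng.uniform(2, 25)),
                   "tmean": float(rng.uniform(2, 22))}
            old_mm = sum(state.soil_water[c] * cap for c in default_soil.water_columns)
            new, _, bal = step_soil_water(state, day, default_soil, default_crop)
            new_mm = sum(new[c] * cap for c in default_soil.water_columns)
            closure = (old_mm + bal["precip"] - bal["drainage"]
                       - bal["transpiration"] - bal["evaporation"])
            assert new_mm == pytest.approx(closure, abs=1e-9)
            state.soil_water = new

    def test_dry_spell_with_canopy_draws_down(self, default_soil, default_crop):
        state = _bare_state(default_soil, 30.0, lai=5.0, bbch=50.0)
        top = default_soil.water_columns[0]
        day = {"precip": 0.0, "radiation": 22.0, "tmean": 20.0}
        previous = state.soil_water[top]
        for _ in range(30):
            new, _, _ = step_soil_water(state, day, default_soil, default_crop)
            assert (new[top] < previous
                    or previous <= default_soil.wilting_point_pct + 1e-9)
            previous = new[top]
            state.soil_water = new
        assert previous >= default_soil.wilting_point_pct - 1e-9


class TestSeason:
    def test_zero_radiation_no_assimilation(self, default_crop, default_soil):
        series = constant_weather(12.0, 2, radiation=0.0)
        tr = simulate_season(series, 283, default_crop, default_soil)
        assert tr.daily["agb"].max() <= default_crop.seed_biomass
        assert tr.yield_dt == pytest.approx(0.0, abs=1.0)

    def test_event_ordering_and_triggers(self, weather_7y, default_crop,
                                         default_soil):
        tr = simulate_season(weather_7y, 290, default_crop, default_soil,
                             sowing_year=2)
        kinds = [e.kind for e in tr.events]
        assert kinds == ["sowing", "fertilization_1", "fertilization_2",
                         "fertilization_3", "harvest"]
        dates = [(e.year, e.doy) for e in tr.events]
        assert dates == sorted(dates)
        fert1 = tr.event("fertilization_1")
        assert tr.state_on(fert1.year, fert1.doy)["bbch"] >= 25.0

    def test_bbch_monotone_and_biomass_ordering(self, small_grid):
        for tr in small_grid[:6]:
            d = tr.daily
            assert (np.diff(d["bbch"]) >= -1e-9).all()
            assert (d["gen_biomass"] <= d["agb"] + 1e-9).all()
            assert (d["gen_biomass"] >= 0).all()

    def test_yield_is_harvest_generative_biomass(self, small_grid):
        for tr in small_grid[:6]:
            if not tr.failed:
                assert tr.yield_dt == pytest.approx(
                    tr.daily.iloc[-1]["gen_biomass"] / 100.0)

    def test_late_sowing_lowers_mean_yield(self, weather_7y, default_crop,
                                           default_soil):
        early = [simulate_season(weather_7y, 283, default_crop, default_soil,
                                 sowing_year=y).yield_dt for y in range(1, 7)]
        late = [simulate_season(weather_7y, 328, default_crop, default_soil,
                                sowing_year=y).yield_dt for y in range(1, 7)]
        assert np.mean(early) > np.mean(late)

    def test_season_never_maturing_flagged_failed(self, default_crop,
                                                  default_soil):
        series = constant_weather(1.0, 2)  # barely any thermal time
        tr = simulate_season(series, 283, default_crop, default_soil)
        assert tr.failed
        assert tr.yield_dt == 0.0
        assert tr.event("harvest") is None


def test_trace_csv_round_trip(tmp_path, small_grid):
    subset = small_grid[:4]
    daily, events = tmp_path / "d.csv", tmp_path / "e.csv"
    traces_to_csv(subset, daily, events)
    back = traces_from_csv(daily, events)
    assert len(back) == len(subset)
    for a, b in zip(subset, back):
        assert a.trace_id == b.trace_id
        assert a.sowing_doy == b.sowing_doy
        assert a.failed == b.failed
        assert a.yield_dt == pytest.approx(b.yield_dt, abs=1e-6)
        pd.testing.assert_frame_equal(a.daily, b.daily, atol=1e-5,
                                      check_exact=False, check_dtype=False)
        assert [e.kind for e in a.events] == [e.kind for e in b.events]
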