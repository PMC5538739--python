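"""Lightweight winter-wheat season simulator.

One season = one (weather series, sowing day-of-year) pair.  The model is
a daily-time-step radiation-use-efficiency crop model with:

* thermal-time phenology mapped onto the BBCH decimal scale (piecewise
  linear between calibrated growing-degree-day milestones; progression
  stalls whenever the daily mean temperature sits at or below the base
  temperature, which is what keeps autumn-sown wheat dormant in winter);
* biomass growth ``RUE * radiation * (1 - exp(-k * LAI))`` modulated by
  temperature, soil-water stress, fertilization bonus windows and a
  late-sowing penalty;
* a tipping-bucket soil-water profile (default layers centred at 30, 60,
  90 and 120 cm) with exact daily mass balance;
* exponentially damped, lagged soil temperature at configurable depths
  (default 5, 10 and 50 cm);
* management events fired by BBCH triggers: three fertilizations at BBCH
  25 / 30 / 39 and harvest at maturity.

Grain (generative) biomass accumulates after anthesis from new assimilate
plus remobilization of vegetative reserves; final yield is generative
biomass at harvest converted from kg/ha to dt/ha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weathergen import DAYS_PER_YEAR, WeatherSeries

logger = logging.getLogger(__name__)

KG_PER_DT = 100.0  # 1 dt/ha = 100 kg/ha


@dataclass(frozen=True)
class CropParams:
    """Winter-wheat parameters; defaults calibrated once for the synthetic
    climate so that grid yields span roughly 40-100 dt/ha with a median
    near 74 and success frequency that falls off with later sowing."""

    base_temp: float = 0.0
    # Cumulative thermal time (degC d from sowing) at each BBCH milestone.
    tt_emergence: float = 130.0     # BBCH 10
    tt_tillering: float = 420.0     # BBCH 25
    tt_stem_start: float = 700.0    # BBCH 30
    tt_flag_leaf: float = 900.0     # BBCH 39
    tt_anthesis: float = 1350.0     # BBCH 61
    tt_maturity: float = 2050.0     # BBCH 92
    maturity_bbch: float = 92.0
    rue_kg_per_mj: float = 15.0     # kg/ha above-ground per MJ m-2 intercepted
    extinction_k: float = 0.55
    sla_lai_per_kg: float = 0.00105  # LAI per kg/ha AGB before anthesis
    max_lai: float = 6.8
    senesced_lai_fraction: float = 0.25  # LAI retained at maturity
    grain_partition: float = 0.5    # share of post-anthesis growth to grain
    remobilization_rate: float = 0.010  # per-day transfer of (agb - gen)
    temp_opt: float = 17.0
    fert_boost: float = 1.22
    fert_window_days: int = 28
    water_stress_sensitivity: float = 1.0
    late_sowing_penalty: float = 0.0065  # growth multiplier lost per DOY late
    penalty_reference_doy: int = 283
    seed_biomass: float = 40.0      # kg/ha at emergence
    soil_evap_coeff: float = 0.4
    pet_coeff_mm_per_mj: float = 0.16

    def __post_init__(self) -> None:
        tts = (self.tt_emergence, self.tt_tillering, self.tt_stem_start,
               self.tt_flag_leaf, self.tt_anthesis, self.tt_maturity)
        if any(b <= a for a, b in zip(tts, tts[1:])):
            raise ValueError("BBCH thermal-time thresholds must be strictly increasing")
        if not 0.0 <= self.grain_partition <= 1.0:
            raise ValueError("grain_partition must lie in [0, 1]")
        for name in ("rue_kg_per_mj", "extinction_k", "sla_lai_per_kg", "max_lai",
                     "remobilization_rate", "fert_boost", "water_stress_sensitivity",
                     "late_sowing_penalty", "seed_biomass", "soil_evap_coeff",
                     "pet_coeff_mm_per_mj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def bbch_milestones(self) -> tuple[np.ndarray, np.ndarray]:
        """(thermal time, BBCH) nodes of the phenology interpolation."""
        tt = np.array([0.0, self.tt_emergence, self.tt_tillering,
                       self.tt_stem_start, self.tt_flag_leaf,
                       self.tt_anthesis, self.tt_maturity])
        bbch = np.array([0.0, 10.0, 25.0, 30.0, 39.0, 61.0, self.maturity_bbch])
        return tt, bbch

    def bbch_from_tt(self, tt: float) -> float:
        nodes_tt, nodes_bbch = self.bbch_milestones
        if tt >= nodes_tt[-1]:
            # keep the final slope so harvest-day BBCH can exceed 92 slightly
            slope = (nodes_bbch[-1] - nodes_bbch[-2]) / (nodes_tt[-1] - nodes_tt[-2])
            return min(100.0, nodes_bbch[-1] + slope * (tt - nodes_tt[-1]))
        return float(np.interp(tt, nodes_tt, nodes_bbch))


@dataclass(frozen=True)
class SoilProfile:
    """Layered soil description.

    ``water_depths_cm`` are the reporting depths of the water layers (one
    bucket per depth, each ``layer_thickness_cm`` thick);
    ``temp_depths_cm`` are the soil-temperature reporting depths.
    """

    water_depths_cm: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    temp_depths_cm: tuple[float, ...] = (5.0, 10.0, 50.0)
    layer_thickness_cm: float = 30.0
    field_capacity_pct: float = 34.0
    wilting_point_pct: float = 11.0
    initial_water_pct: float = 29.0
    damping_depth_cm: float = 15.0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.water_depths_cm, self.water_depths_cm[1:])):
            raise ValueError("water depths must be strictly increasing")
        if any(b <= a for a, b in zip(self.temp_depths_cm, self.temp_depths_cm[1:])):
            raise ValueError("temperature depths must be strictly increasing")
        if self.wilting_point_pct >= self.field_capacity_pct:
            raise ValueError("wilting point must be below field capacity")

    @property
    def layer_capacity_mm(self) -> float:
        """Water (mm) held per layer per 1 % volumetric content."""
        return self.layer_thickness_cm * 10.0 / 100.0

    @property
    def water_columns(self) -> list[str]:
        return [f"sw_{int(d)}" for d in self.water_depths_cm]

    @property
    def temp_columns(self) -> list[str]:
        return [f"st_{int(d)}" for d in self.temp_depths_cm]


@dataclass
class ManagementEvent:
    kind: str  # sowing | fertilization_1..3 | harvest
    year: int
    doy: int
    trigger: str = ""


@dataclass
class CropState:
    """End-of-day crop and soil state."""

    year: int
    doy: int
    bbch: float
    lai: float
    agb: float
    gen_biomass: float
    soil_water: dict[str, float]   # % volume keyed by sw_<depth>
    soil_temp: dict[str, float]    # degC keyed by st_<depth>


@dataclass
class GrowthTrace:
    """One simulated season: daily states, management events, final yield."""

    sowing_doy: int
    weather_year_label: int
    daily: pd.DataFrame
    events: list[ManagementEvent]
    yield_dt: float
    failed: bool = False
    trace_id: str = ""

    def event(self, kind: str) -> ManagementEvent | None:
        for ev in self.events:
            if ev.kind == kind:
                return ev
        return None

    def state_on(self, year: int, doy: int) -> pd.Series | None:
        sel = self.daily[(self.daily["year"] == year) & (self.daily["doy"] == doy)]
        return sel.iloc[0] if len(sel) else None


def thermal_time(series: WeatherSeries, start_year: int, start_doy: int,
                 base_temp: float) -> np.ndarray:
    """Cumulative growing-degree days from the start date to series end.

    Daily increment is ``max(0, tmean - base_temp)``; the returned sequence
    is non-decreasing with one entry per day starting at the start date.
    """
    df = series.data
    mask = (df["year"] > start_year) | ((df["year"] == start_year) & (df["doy"] >= start_doy))
    if not mask.any() or df.loc[mask].iloc[0]["year"] != start_year:
        raise ValueError("start date outside the weather series")
    tmean = df.loc[mask, "tmean"].to_numpy()
    return np.cumsum(np.maximum(0.0, tmean - base_temp))


def soil_temperature_profile(air_temp_history, depths_cm, damping_depth_cm: float = 15.0):
    """Soil temperature at each depth after forcing with an air-temperature
    history, using a first-order (exponentially damped, lagged) response
    whose time constant grows with depth.

    Returns a dict depth -> temperature after the final day.  Shallow
    depths track the air temperature more closely than deep ones.
    """
    history = np.asarray(air_temp_history, dtype=float)
    if history.size == 0:
        raise ValueError("air temperature history must be non-empty")
    if any(d <= 0 for d in depths_cm):
        raise ValueError("depths must be positive")
    out = {}
    for depth in depths_cm:
        tau = 1.0 + depth / damping_depth_cm
        temp = history[0]
        for t_air in history[1:]:
            temp += (t_air - temp) / tau
        out[depth] = float(temp)
    return out


def step_soil_water(state: CropState, day, soil: SoilProfile, crop: CropParams):
    """Advance the layered soil-water store by one day.

    Mass balance per layer: new = old + infiltration - drainage - uptake,
    with contents clamped to [wilting point, field capacity] (excess above
    field capacity drains to the next layer, the bottom layer drains out
    of the profile).  Returns ``(new_soil_water, stress_factor, balance)``
    where ``balance`` collects the day's fluxes in mm and the relative
    water-stress factor is 1 when the root zone is wet and falls toward 0
    as it dries toward wilting point.
    """
    cap = soil.layer_capacity_mm
    fc, wp = soil.field_capacity_pct, soil.wilting_point_pct
    cols = soil.water_columns
    mm = np.array([state.soil_water[c] * cap for c in cols])
    wp_mm, fc_mm = wp * cap, fc * cap

    precip = float(day["precip"])
    radiation = float(day["radiation"])
    tmean = float(day["tmean"])
    lai = state.lai

    # infiltration + drainage cascade
    drained_out = 0.0
    inflow = precip
    for i in range(len(mm)):
        mm[i] += inflow
        excess = max(0.0, mm[i] - fc_mm)
        mm[i] -= excess
        inflow = excess
    drained_out = inflow

    # demand: transpiration through the canopy, evaporation from bare soil
    pet = crop.pet_coeff_mm_per_mj * radiation * np.clip(tmean / 18.0, 0.05, 1.2)
    cover = 1.0 - np.exp(-crop.extinction_k * lai)
    transp_demand = pet * cover
    evap_demand = crop.soil_evap_coeff * pet * (1.0 - cover)

    # roots reach deeper with development; top layers supply most uptake
    n_root = 1 + min(len(mm) - 1, int(state.bbch // 25))
    weights = np.zeros(len(mm))
    weights[:n_root] = np.linspace(1.0, 0.4, n_root)
    weights /= weights.sum()

    transp_actual = 0.0
    for i, w in enumerate(weights):
        take = min(transp_demand * w, max(0.0, mm[i] - wp_mm))
        mm[i] -= take
        transp_actual += take
    evap_actual = min(evap_demand, max(0.0, mm[0] - wp_mm))
    mm[0] -= evap_actual

    # relative available water in the rooted zone drives the stress factor
    rooted = slice(0, n_root)
    avail = (mm[rooted] - wp_mm).sum() / (n_root * (fc_mm - wp_mm))
    stress = float(np.clip(avail / 0.45, 0.0, 1.0)) ** crop.water_stress_sensitivity

    new_water = {c: float(mm[i] / cap) for i, c in enumerate(cols)}
    balance = {
        "precip": precip, "drainage": float(drained_out),
        "transpiration": float(transp_actual), "evaporation": float(evap_actual),
    }
    return new_water, stress, balance


def simulate_season(series: WeatherSeries, sowing_doy: int, crop: CropParams,
                    soil: SoilProfile, sowing_year: int | None = None,
                    trace_id: str = "") -> GrowthTrace:
    """Simulate one winter-wheat season sown on ``sowing_doy`` of
    ``sowing_year`` (default: first year of the series).

    Fertilizations fire on the first day BBCH reaches 25 / 30 / 39 and
    harvest on the first day BBCH reaches maturity.  If the series ends
    before maturity the trace is flagged failed with yield 0.
    """
    years = series.years
    if sowing_year is None:
        sowing_year = years[0]
    if sowing_year not in years:
        raise ValueError(f"sowing year {sowing_year} not in series")
    if not 1 <= sowing_doy <= DAYS_PER_YEAR:
        raise ValueError("sowing_doy outside the calendar")

    df = series.data
    year_arr = df["year"].to_numpy()
    doy_arr = df["doy"].to_numpy()
    tmean_arr = df["tmean"].to_numpy()
    start = int(np.searchsorted(year_arr * 1000 + doy_arr, sowing_year * 1000 + sowing_doy))
    n_days = len(df)

    sow_factor = max(0.3, 1.0 - crop.late_sowing_penalty
                     * max(0, sowing_doy - crop.penalty_reference_doy))

    cols = soil.water_columns
    tcols = soil.temp_columns
    soil_water = {c: soil.initial_water_pct for c in cols}
    # soil temperature spun up from pre-sowing air temperature
    spin = tmean_arr[max(0, start - 60):start + 1]
    if spin.size == 0:
        spin = np.array([tmean_arr[start]])
    soil_temp = {f"st_{int(d)}": v for d, v in
                 soil_temperature_profile(spin, soil.temp_depths_cm,
                                          soil.damping_depth_cm).items()}
    taus = {f"st_{int(d)}": 1.0 + d / soil.damping_depth_cm for d in soil.temp_depths_cm}

    tt = 0.0
    agb = 0.0
    gen = 0.0
    lai_peak = 0.0
    emerged = False
    events = [ManagementEvent("sowing", sowing_year, sowing_doy, trigger="planned")]
    fert_stages = [("fertilization_1", 25.0), ("fertilization_2", 30.0),
                   ("fertilization_3", 39.0)]
    fert_active_until = -1  # absolute day index
    rows = []
    harvested = False

    precip_arr = df["precip"].to_numpy()
    rad_arr = df["radiation"].to_numpy()

    state = CropState(sowing_year, sowing_doy, 0.0, 0.0, 0.0, 0.0,
                      dict(soil_water), dict(soil_temp))

    for idx in range(start, n_days):
        yr, dy = int(year_arr[idx]), int(doy_arr[idx])
        tmean = float(tmean_arr[idx])
        day = {"precip": float(precip_arr[idx]), "radiation": float(rad_arr[idx]),
               "tmean": tmean}

        tt += max(0.0, tmean - crop.base_temp)
        bbch = crop.bbch_from_tt(tt)

        if not emerged and bbch >= 10.0:
            emerged = True
            agb = crop.seed_biomass

        # soil temperature first-order update toward today's air temperature
        for key, tau in taus.items():
            soil_temp[key] += (tmean - soil_temp[key]) / tau

        state.bbch, state.lai = bbch, state.lai
        new_water, stress, _ = step_soil_water(state, day, soil, crop)
        soil_water = new_water
        state.soil_water = soil_water

        if emerged and not harvested:
            lai_green = min(crop.max_lai, crop.sla_lai_per_kg * agb)
            if bbch <= 61.0:
                lai = lai_green
                lai_peak = max(lai_peak, lai)
            else:
                frac = (crop.maturity_bbch - min(bbch, crop.maturity_bbch)) \
                    / (crop.maturity_bbch - 61.0)
                lai = lai_peak * (crop.senesced_lai_fraction
                                  + (1.0 - crop.senesced_lai_fraction) * frac)
            f_temp = float(np.clip((tmean - crop.base_temp) / crop.temp_opt, 0.0, 1.0))
            fert_mult = crop.fert_boost if idx <= fert_active_until else 1.0
            growth = (crop.rue_kg_per_mj * day["radiation"]
                      * (1.0 - np.exp(-crop.extinction_k * lai))
                      * f_temp * stress * fert_mult * sow_factor)
            agb += growth
            if bbch >= 61.0:
                gen += crop.grain_partition * growth \
                    + crop.remobilization_rate * (agb - gen)
                gen = min(gen, agb)
        else:
            lai = state.lai if harvested else 0.0

        state = CropState(yr, dy, bbch, float(lai), float(agb), float(gen),
                          dict(soil_water), dict(soil_temp))

        for kind, threshold in fert_stages:
            if bbch >= threshold and not any(ev.kind == kind for ev in events):
                events.append(ManagementEvent(kind, yr, dy, trigger=f"BBCH>={threshold:g}"))
                fert_active_until = idx + crop.fert_window_days

        rows.append({"year": yr, "doy": dy, "bbch": bbch, "lai": float(lai),
                     "agb": float(agb), "gen_biomass": float(gen),
                     **soil_water, **soil_temp})

        if not harvested and bbch >= crop.maturity_bbch:
            events.append(ManagementEvent("harvest", yr, dy,
                                          trigger=f"BBCH>={crop.maturity_bbch:g}"))
            harvested = True
            break

    daily = pd.DataFrame(rows, columns=["year", "doy", "bbch", "lai", "agb",
                                        "gen_biomass", *cols, *tcols])
    if harvested:
        yield_dt = gen / KG_PER_DT
        failed = False
    else:
        yield_dt = 0.0
        failed = True
        logger.warning("season sown %d/DOY %d never reached maturity; flagged failed",
                       sowing_year, sowing_doy)
    return GrowthTrace(sowing_doy=sowing_doy, weather_year_label=sowing_year,
                       daily=daily, events=events, yield_dt=float(yield_dt),
                       failed=failed, trace_id=trace_id)


# ---------------------------------------------------------------------------
# trace round-tripping (long-format CSVs)

def traces_to_csv(traces, daily_path, events_path) -> None:
    daily_frames, event_rows = [], []
    for tr in traces:
        d = tr.daily.copy()
        d.insert(0, "trace_id", tr.trace_id)
        daily_frames.append(d)
        for ev in tr.events:
            event_rows.append({"trace_id": tr.trace_id, "kind": ev.kind,
                               "year": ev.year, "doy": ev.doy, "trigger": ev.trigger})
        event_rows.append({"trace_id": tr.trace_id, "kind": "_meta",
                           "year": tr.weather_year_label, "doy": tr.sowing_doy,
                           "trigger": f"yield={tr.yield_dt:.6f};failed={int(tr.failed)}"})
    pd.concat(daily_frames, ignore_index=True).to_csv(daily_path, index=False,
                                                      float_format="%.6f")
    pd.DataFrame(event_rows).to_csv(events_path, index=False)


def traces_from_csv(daily_path, events_path) -> list[GrowthTrace]:
    daily_all = pd.read_csv(daily_path)
    events_all = pd.read_csv(events_path).fillna({"trigger": ""})
    traces = []
    for tid, ev_grp in events_all.groupby("trace_id", sort=False):
        meta = ev_grp[ev_grp["kind"] == "_meta"].iloc[0]
        parts = dict(p.split("=") for p in meta["trigger"].split(";"))
        events = [ManagementEvent(r["kind"], int(r["year"]), int(r["doy"]),
                                  str(r["trigger"]))
                  for _, r in ev_grp.iterrows() if r["kind"] != "_meta"]
        daily = daily_all[daily_all["trace_id"] == tid].drop(columns="trace_id") \
            .reset_index(drop=True)
        traces.append(GrowthTrace(sowing_doy=int(meta["doy"]),
                                  weather_year_label=int(meta["year"]),
                                  daily=daily, events=events,
                                  yield_dt=float(parts["yield"]),
                                  failed=bool(int(parts["failed"])),
                                  trace_id=str(tid)))
    return traces
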