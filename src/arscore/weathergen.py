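"""Synthetic daily weather for a temperate winter-wheat region.

A deliberately small stochastic generator that stands in for station
records or statistical-downscaling realizations: a sinusoidal seasonal
mean with AR(1) temperature anomalies, a two-state Markov chain for
precipitation occurrence with gamma-distributed wet-day amounts, and a
clear-sky radiation curve attenuated on wet days.  Default parameters
target a mean annual temperature of 9-10 degC and annual precipitation of
730-830 mm.  Years are fixed at 365 days: leap-day bookkeeping adds
nothing to the risk-scoring method downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365

#: Column order of the canonical daily-weather table.
WEATHER_COLUMNS = ["year", "doy", "tmin", "tmean", "tmax", "precip", "radiation"]


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the stochastic weather model.

    Temperature (degC) follows ``annual_mean + amplitude * cos(2*pi*(doy -
    peak_doy)/365)`` plus an AR(1) anomaly with stationary standard
    deviation ``temp_noise_sd`` and lag-1 autocorrelation ``temp_autocorr``.
    Precipitation occurrence is a two-state Markov chain
    (``p_wet_after_dry``, ``p_wet_after_wet``); wet-day amounts are gamma
    with mean ``wet_day_mean_mm``.  Radiation follows a clear-sky seasonal
    curve, multiplied by ``1 - cloud_attenuation`` on wet days.
    """

    annual_mean_temp: float = 9.5
    seasonal_amplitude: float = 8.5
    temp_peak_doy: float = 200.0
    temp_noise_sd: float = 3.0
    temp_autocorr: float = 0.7
    diurnal_half_range_down: float = 4.5  # tmean - tmin
    diurnal_half_range_up: float = 5.5    # tmax - tmean
    p_wet_after_dry: float = 0.32
    p_wet_after_wet: float = 0.55
    wet_day_mean_mm: float = 5.15
    wet_day_gamma_shape: float = 0.85
    clearsky_mean: float = 14.0
    clearsky_amplitude: float = 11.0
    clearsky_peak_doy: float = 172.0
    cloud_attenuation: float = 0.55

    def __post_init__(self) -> None:
        for name in ("temp_noise_sd", "diurnal_half_range_down",
                     "diurnal_half_range_up", "wet_day_mean_mm",
                     "wet_day_gamma_shape", "clearsky_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_wet_after_dry", "p_wet_after_wet", "cloud_attenuation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.temp_autocorr < 1.0:
            raise ValueError("temp_autocorr must lie in [0, 1)")
        if self.clearsky_mean - self.clearsky_amplitude < 0:
            raise ValueError("clear-sky curve must stay non-negative")

    def seasonal_tmean(self, doy: np.ndarray | float) -> np.ndarray | float:
        """Closed-form seasonal mean temperature for a day of year."""
        return self.annual_mean_temp + self.seasonal_amplitude * np.cos(
            2.0 * np.pi * (np.asarray(doy, dtype=float) - self.temp_peak_doy) / DAYS_PER_YEAR
        )

    def clearsky_radiation(self, doy: np.ndarray | float) -> np.ndarray | float:
        return self.clearsky_mean + self.clearsky_amplitude * np.cos(
            2.0 * np.pi * (np.asarray(doy, dtype=float) - self.clearsky_peak_doy) / DAYS_PER_YEAR
        )


@dataclass
class WeatherSeries:
    """A multi-year daily weather table plus provenance."""

    data: pd.DataFrame
    station_label: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in WEATHER_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"weather table missing columns: {missing}")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_slice(self, year: int) -> pd.DataFrame:
        return self.data[self.data["year"] == year]

    def annual_mean_temp(self) -> float:
        return float(self.data["tmean"].mean())

    def annual_precip_mean(self) -> float:
        return float(self.data.groupby("year")["precip"].sum().mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, station_label: str = "file") -> "WeatherSeries":
        df = pd.read_csv(path)
        df["year"] = df["year"].astype(int)
        df["doy"] = df["doy"].astype(int)
        return cls(data=df[WEATHER_COLUMNS], station_label=station_label)


def generate_weather(params: ClimateParams, n_years: int, seed: int,
                     station_label: str = "synthetic",
                     start_year: int = 1) -> WeatherSeries:
    """Generate ``n_years`` whole 365-day years of daily weather.

    Deterministic for a fixed ``(params, seed)`` pair: all randomness flows
    from one ``numpy.random.default_rng(seed)`` stream.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n_days = n_years * DAYS_PER_YEAR

    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    year = np.repeat(np.arange(start_year, start_year + n_years), DAYS_PER_YEAR)

    # AR(1) anomaly with stationary sd temp_noise_sd.
    rho, sd = params.temp_autocorr, params.temp_noise_sd
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal(n_days)
    anomaly = np.empty(n_days)
    prev = sd * eps[0] if sd > 0 else 0.0
    anomaly[0] = prev
    for i in range(1, n_days):
        prev = rho * prev + innov_sd * eps[i]
        anomaly[i] = prev

    tmean = params.seasonal_tmean(doy) + anomaly
    tmin = tmean - params.diurnal_half_range_down
    tmax = tmean + params.diurnal_half_range_up

    # Two-state Markov occurrence, then gamma amounts on wet days.
    u = rng.random(n_days)
    wet = np.zeros(n_days, dtype=bool)
    climatological_wet = params.p_wet_after_dry / max(
        1.0 + params.p_wet_after_dry - params.p_wet_after_wet, 1e-12)
    wet[0] = u[0] < climatological_wet
    for i in range(1, n_days):
        p = params.p_wet_after_wet if wet[i - 1] else params.p_wet_after_dry
        wet[i] = u[i] < p
    precip = np.zeros(n_days)
    n_wet = int(wet.sum())
    if n_wet and params.wet_day_mean_mm > 0:
        shape = params.wet_day_gamma_shape
        scale = params.wet_day_mean_mm / shape
        precip[wet] = rng.gamma(shape, scale, size=n_wet)

    radiation = np.asarray(params.clearsky_radiation(doy), dtype=float).copy()
    radiation[wet] *= 1.0 - params.cloud_attenuation
    radiation = np.clip(radiation, 0.0, None)

    df = pd.DataFrame({
        "year": year, "doy": doy,
        "tmin": tmin, "tmean": tmean, "tmax": tmax,
        "precip": precip, "radiation": radiation,
    })
    return WeatherSeries(data=df, station_label=station_label, seed=seed)


def climate_shift(params: ClimateParams, delta_temp: float,
                  precip_factor: float) -> ClimateParams:
    """Return new params with the mean temperature shifted by ``delta_temp``
    degC and the wet-day mean precipitation scaled by ``precip_factor``.

    The input is unchanged; occurrence probabilities are untouched, so the
    shift scales totals without altering wet-day frequency.
    """
    if precip_factor <= 0:
        raise ValueError("precip_factor must be > 0")
    return replace(
        params,
        annual_mean_temp=params.annual_mean_temp + delta_temp,
        wet_day_mean_mm=params.wet_day_mean_mm * precip_factor,
    )
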