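"""Synthetic station weather for a single virtual alpine station.

The observation model mirrors typical inner-alpine station records: hourly
mean temperature (deg C) and hourly maximum wind speed (km/h), precipitation
(mm) summed over 3-hour bins and attached to the bin end, and snow depth
(cm) read once per day at 05:00.  Weather is spatially constant.

Temperature is a seasonal mean plus a diurnal harmonic (warmest mid
afternoon) plus AR(1) noise.  Wind is positively coupled to the temperature
anomaly with configurable correlation.  Precipitation is zero-inflated
gamma per 3-h bin.  Snow depth is a non-negative bounded random walk in
winter and identically zero in summer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASON_MONTHS = {"summer": (6, 7, 8, 9, 10), "winter": (12, 1, 2, 3, 4)}


@dataclass
class WeatherSeries:
    """Hourly station table with sparse precipitation / snow columns.

    ``hourly`` has a strictly increasing DatetimeIndex and columns
    ``temp_c`` and ``wind_kmh``.  ``precip_mm_3h`` is non-null only on rows
    ending a 3-h bin (hours 0, 3, ..., 21 plus the closing bin) and holds
    the sum over the bin ``(t - 3h, t]``.  ``snow_cm`` is non-null only at
    05:00 rows.
    """

    hourly: pd.DataFrame

    def __post_init__(self):
        idx = self.hourly.index
        if idx.has_duplicates:
            raise ValueError("duplicate weather timestamps")
        if not idx.is_monotonic_increasing:
            raise ValueError("weather timestamps must be increasing")
        if (self.hourly["precip_mm_3h"].dropna() < 0).any():
            raise ValueError("negative precipitation")
        if (self.hourly["snow_cm"].dropna() < 0).any():
            raise ValueError("negative snow depth")

    # --- point lookups used to annotate strata ---------------------------

    def temperature_wind(self, timestamps):
        """Hourly record covering each timestamp (floor to the hour)."""
        t = pd.DatetimeIndex(timestamps).floor("h")
        sub = self.hourly.reindex(t)
        if sub["temp_c"].isna().any():
            raise ValueError("timestamp outside weather coverage")
        return sub["temp_c"].to_numpy(), sub["wind_kmh"].to_numpy()

    def precipitation(self, timestamps):
        """Value of the 3-h bin containing each timestamp."""
        t = pd.DatetimeIndex(timestamps)
        bin_end = t.ceil("3h")
        vals = self.hourly["precip_mm_3h"].reindex(bin_end)
        if vals.isna().any():
            raise ValueError("timestamp outside precipitation coverage")
        return vals.to_numpy()

    def snow(self, timestamps):
        """That calendar day's 05:00 snow reading, per timestamp."""
        t = pd.DatetimeIndex(timestamps).normalize() + pd.Timedelta(hours=5)
        vals = self.hourly["snow_cm"].reindex(t)
        if vals.isna().any():
            raise ValueError("timestamp outside snow coverage")
        return vals.to_numpy()

    def to_csv(self, path):
        df = self.hourly.copy()
        df.index.name = "timestamp"
        df.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
        return cls(hourly=df)


def generate_weather(
    start: str | pd.Timestamp,
    n_days: int,
    season: str = "summer",
    mean_temp: float | None = None,
    seasonal_amplitude: float = 4.0,
    diurnal_amplitude: float = 5.0,
    ar_phi: float = 0.8,
    ar_sd: float = 1.2,
    wind_mean: float = 14.0,
    wind_sd: float = 8.0,
    wind_temp_corr: float = 0.45,
    precip_zero_prob: float = 0.8,
    precip_shape: float = 0.6,
    precip_scale: float = 3.0,
    snow_start_cm: float = 50.0,
    snow_walk_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> WeatherSeries:
    """Simulate an hourly station series starting at ``start`` 00:00.

    ``mean_temp`` defaults to a season-typical value (10 C summer, -8 C
    winter at ~2000 m asl).  ``wind_temp_corr`` sets the latent correlation
    between wind and the standardized temperature anomaly before the
    clipping of wind at zero.
    """
    if n_days < 1:
        raise ValueError("window must cover at least one day")
    if not 0.0 <= precip_zero_prob <= 1.0:
        raise ValueError("precip_zero_prob must be a probability")
    if min(precip_shape, precip_scale, ar_sd, wind_sd) <= 0:
        raise ValueError("scale parameters must be positive")
    if not -1.0 <= wind_temp_corr <= 1.0:
        raise ValueError("wind_temp_corr must be in [-1, 1]")

    rng = np.random.default_rng(seed)
    if mean_temp is None:
        mean_temp = 10.0 if season == "summer" else -8.0

    t0 = pd.Timestamp(start).normalize()
    n_hours = n_days * 24
    idx = pd.date_range(t0, periods=n_hours + 3, freq="h")  # pad one 3-h bin
    hours = np.arange(len(idx))

    seasonal = seasonal_amplitude * np.sin(2 * np.pi * hours / (24 * n_days + 72))
    diurnal = diurnal_amplitude * np.cos(
        2 * np.pi * (idx.hour.to_numpy() - 14) / 24.0)
    ar = np.empty(len(idx))
    ar[0] = rng.normal(0, ar_sd / np.sqrt(1 - ar_phi**2))
    eps = rng.normal(0, ar_sd, len(idx))
    for k in range(1, len(idx)):
        ar[k] = ar_phi * ar[k - 1] + eps[k]
    temp = mean_temp + seasonal + diurnal + ar

    z = (temp - temp.mean()) / temp.std()
    wind_noise = rng.standard_normal(len(idx))
    r = wind_temp_corr
    wind = wind_mean + wind_sd * (r * z + np.sqrt(1 - r * r) * wind_noise)
    wind = np.clip(wind, 0.0, None)

    precip = np.full(len(idx), np.nan)
    bin_rows = np.nonzero(idx.hour % 3 == 0)[0]
    wet = rng.random(len(bin_rows)) >= precip_zero_prob
    amounts = np.where(
        wet, rng.gamma(precip_shape, precip_scale, len(bin_rows)), 0.0
    )
    precip[bin_rows] = amounts

    snow = np.full(len(idx), np.nan)
    snow_rows = np.nonzero(idx.hour == 5)[0]
    if season == "winter":
        walk = np.empty(len(snow_rows))
        level = snow_start_cm
        for k in range(len(snow_rows)):
            level = min(max(level + rng.normal(0.0, snow_walk_sd), 0.0), 300.0)
            walk[k] = level
        snow[snow_rows] = walk
    else:
        snow[snow_rows] = 0.0

    df = pd.DataFrame(
        {"temp_c": temp, "wind_kmh": wind, "precip_mm_3h": precip, "snow_cm": snow},
        index=idx,
    )
    df.index.name = "timestamp"
    return WeatherSeries(hourly=df)
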