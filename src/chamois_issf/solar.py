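"""Sunrise/sunset and day/night classification.

Implements the NOAA solar-geometry equations (fractional-year Fourier
expansions for the equation of time and solar declination, hour-angle
inversion at a zenith of 90.833 degrees, i.e. including atmospheric
refraction and the solar semidiameter, so sunrise is the moment the top
edge of the disc crosses the horizon).  All timestamps are treated as UTC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: zenith at the moment the upper limb touches the horizon (degrees)
RISE_SET_ZENITH = 90.833

#: study-site defaults (Swiss National Park area)
DEFAULT_LAT = 46.65
DEFAULT_LON = 10.17


def _fractional_year(ts: pd.Timestamp) -> float:
    doy = ts.dayofyear
    days_in_year = 366 if ts.is_leap_year else 365
    return 2.0 * np.pi / days_in_year * (doy - 1 + (ts.hour - 12) / 24.0)


def _eqtime_decl(gamma: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    return eqtime, decl


class PolarDayNight(ValueError):
    """The sun does not cross the rise/set zenith on this date/latitude."""


def sunrise_sunset(date, latitude: float = DEFAULT_LAT,
                   longitude: float = DEFAULT_LON):
    """UTC sunrise and sunset for a calendar date.

    Longitude is positive east.  Raises :class:`PolarDayNight` when the sun
    never rises or never sets (not expected at mid-latitudes).
    """
    day = pd.Timestamp(date).normalize()
    lat = np.radians(latitude)

    def event_minutes(at_minutes: float, rise: bool) -> float:
        # eqtime/declination evaluated at the event estimate and iterated
        gamma = _fractional_year(day + pd.Timedelta(minutes=at_minutes))
        eqtime, decl = _eqtime_decl(gamma)
        cos_ha = (
            np.cos(np.radians(RISE_SET_ZENITH)) / (np.cos(lat) * np.cos(decl))
            - np.tan(lat) * np.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise PolarDayNight(
                f"no sunrise/sunset at {latitude} deg on {day.date()}")
        ha = np.degrees(np.arccos(cos_ha))
        return 720.0 - 4.0 * (longitude + (ha if rise else -ha)) - eqtime

    sunrise_min = 720.0
    sunset_min = 720.0
    for _ in range(3):
        sunrise_min = event_minutes(sunrise_min, rise=True)
        sunset_min = event_minutes(sunset_min, rise=False)
    return (
        day + pd.Timedelta(minutes=float(sunrise_min)),
        day + pd.Timedelta(minutes=float(sunset_min)),
    )


def assign_daynight(timestamps, latitude: float = DEFAULT_LAT,
                    longitude: float = DEFAULT_LON) -> np.ndarray:
    """1 for daytime (sunrise <= t < sunset), 0 for night, per timestamp."""
    scalar = np.isscalar(timestamps) or isinstance(timestamps, pd.Timestamp)
    ts = pd.DatetimeIndex([timestamps] if scalar else timestamps)
    out = np.zeros(len(ts), dtype=np.int64)
    cache: dict = {}
    dates = ts.normalize()
    for i, (t, d) in enumerate(zip(ts, dates)):
        if d not in cache:
            cache[d] = sunrise_sunset(d, latitude, longitude)
        rise, sset = cache[d]
        out[i] = 1 if (rise <= t < sset) else 0
    if scalar:
        return out[0]
    return out
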