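"""From raw GPS fixes to annotated, standardized use-availability strata.

The preparation chain: screen implausible positions (round-trip speed
rule), form steps between consecutive fixes on the nominal 4-h schedule,
fit a tentative gamma step-length distribution per individual, sample 10
random (available) steps per realized step from the gamma x uniform
turning-angle kernel — giving strata of 11 positions — then annotate every
position with terrain covariates, station weather at the step's end time,
and a day/night flag, and finally z-standardize the continuous covariates
per season.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from . import solar
from .landscape import LandscapeStack
from .weather import SEASON_MONTHS, WeatherSeries

HABITAT_TERMS = ("elevation", "slope", "tcd", "northness", "eastness")
WEATHER_TERMS = ("temperature", "wind", "precipitation", "snow")

#: default plausibility ceiling for the position screen (m/h)
DEFAULT_SPEED_CEILING = 5000.0

#: floor applied to zero step lengths before gamma fitting (m)
LENGTH_FLOOR = 1.0


# --------------------------------------------------------------------------
# position screening and step construction

def screen_positions(fixes: pd.DataFrame,
                     max_speed_m_per_h: float = DEFAULT_SPEED_CEILING):
    """Remove fixes implying implausibly fast out-and-back movement.

    A fix is dropped when the speed both into and out of it exceeds the
    ceiling (both legs required, so endpoints and two-fix tracks are never
    removed).  Applied iteratively until stable.

    Returns ``(cleaned, report)`` where ``report`` is a DataFrame of the
    removed rows.
    """
    df = fixes.sort_values("timestamp").reset_index(drop=True)
    removed = []
    while len(df) >= 3:
        t = df["timestamp"].to_numpy()
        dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
        dist = np.hypot(np.diff(df["x"].to_numpy()), np.diff(df["y"].to_numpy()))
        with np.errstate(divide="ignore"):
            speed = np.where(dt_h > 0, dist / dt_h, np.inf)
        bad = np.zeros(len(df), dtype=bool)
        bad[1:-1] = (speed[:-1] > max_speed_m_per_h) & (speed[1:] > max_speed_m_per_h)
        if not bad.any():
            break
        removed.append(df[bad])
        df = df[~bad].reset_index(drop=True)
    report = (pd.concat(removed, ignore_index=True) if removed
              else df.iloc[0:0].copy())
    return df, report


def _wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float) % (2 * np.pi)
    return np.where(a > np.pi, a - 2 * np.pi, a)


def build_steps(fixes: pd.DataFrame, interval_h: float = 4.0,
                tolerance_min: float = 30.0) -> pd.DataFrame:
    """Steps between consecutive fixes on the nominal schedule.

    Gaps outside ``interval +/- tolerance`` split the track into bursts; no
    step spans a burst boundary and turning angles are defined only when
    the previous step lies in the same burst.

    Returns a DataFrame with one row per step: start/end time and
    coordinates, length (m), absolute direction (rad, east = 0, CCW) and
    turning angle (rad in (-pi, pi], NaN when undefined).
    """
    df = fixes.sort_values("timestamp").reset_index(drop=True)
    if len(df) < 2:
        return pd.DataFrame(columns=[
            "individual", "t0", "t1", "x0", "y0", "x1", "y1",
            "length", "direction", "turn", "burst"])
    t = df["timestamp"].to_numpy()
    dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
    tol_h = tolerance_min / 60.0
    ok = np.abs(dt_h - interval_h) <= tol_h
    burst_of_fix = np.concatenate([[0], np.cumsum(~ok)])

    x = df["x"].to_numpy(); y = df["y"].to_numpy()
    rows = dict(
        individual=df["individual"].to_numpy()[:-1][ok],
        t0=t[:-1][ok], t1=t[1:][ok],
        x0=x[:-1][ok], y0=y[:-1][ok], x1=x[1:][ok], y1=y[1:][ok],
        length=np.hypot(np.diff(x), np.diff(y))[ok],
        direction=np.arctan2(np.diff(y), np.diff(x))[ok],
        burst=burst_of_fix[:-1][ok],
    )
    steps = pd.DataFrame(rows)
    prev_dir = steps["direction"].shift(1)
    same_burst = steps["burst"].shift(1) == steps["burst"]
    consecutive = steps["t1"].shift(1) == steps["t0"]
    turn = _wrap_angle(steps["direction"] - prev_dir)
    steps["turn"] = np.where(same_burst & consecutive, turn, np.nan)
    return steps


# --------------------------------------------------------------------------
# tentative step-length distribution

@dataclass
class GammaKernel:
    """Tentative gamma step-length distribution for one individual."""

    shape: float
    scale: float
    n: int
    individual: object = None

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


def fit_tentative_gamma(lengths, individual=None,
                        floor: float = LENGTH_FLOOR) -> GammaKernel:
    """Maximum-likelihood gamma fit to step lengths.

    Zero lengths are floored at ``floor`` metres (gamma support is
    positive).  The shape solves the profile score equation
    ``log(k) - digamma(k) = log(mean) - mean(log)`` by Newton iteration
    from the standard moment-based start; scale = mean / shape.
    """
    x = np.asarray(lengths, dtype=float)
    x = np.where(x < floor, floor, x)
    if len(x) < 10:
        raise ValueError("need at least 10 step lengths")
    if np.any(x <= 0):
        raise ValueError("non-positive step length after flooring")
    m = x.mean()
    c = math.log(m) - np.log(x).mean()
    if c <= 0:  # numerically constant sample
        raise ValueError("degenerate step-length sample")
    k = (3.0 - c + math.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    for _ in range(100):
        f = math.log(k) - digamma(k) - c
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * max(1.0, k):
            k = k_new
            break
        k = k_new
    else:
        raise RuntimeError("gamma shape Newton iteration did not converge")
    return GammaKernel(shape=float(k), scale=float(m / k), n=len(x),
                       individual=individual)


def gamma_loglik(lengths, shape: float, scale: float) -> float:
    from scipy import stats

    return float(stats.gamma.logpdf(lengths, a=shape, scale=scale).sum())


# --------------------------------------------------------------------------
# random (available) steps

def _sample_endpoints(x0, y0, ref_dir, kernel: GammaKernel, n: int,
                      landscape: LandscapeStack, rng: np.random.Generator,
                      max_retry: int = 100):
    """n alternative endpoints per step from the gamma x uniform kernel.

    Inputs are arrays over steps; returns (x, y, length) arrays of shape
    (n_steps, n).  Draws falling off the raster are redrawn up to
    ``max_retry`` rounds; a boolean per-step failure mask is also returned.
    """
    n_steps = len(x0)
    shape_ = (n_steps, n)
    L = rng.gamma(kernel.shape, kernel.scale, shape_)
    turn = rng.uniform(-np.pi, np.pi, shape_)
    ang = ref_dir[:, None] + turn
    ex = x0[:, None] + L * np.cos(ang)
    ey = y0[:, None] + L * np.sin(ang)
    bad = ~landscape.contains(ex, ey)
    tries = 0
    while bad.any() and tries < max_retry:
        k = int(bad.sum())
        L2 = rng.gamma(kernel.shape, kernel.scale, k)
        t2 = rng.uniform(-np.pi, np.pi, k)
        a2 = np.broadcast_to(ref_dir[:, None], shape_)[bad] + t2
        ex[bad] = np.asarray(x0)[:, None].repeat(n, 1)[bad] + L2 * np.cos(a2)
        ey[bad] = np.asarray(y0)[:, None].repeat(n, 1)[bad] + L2 * np.sin(a2)
        L[bad] = L2
        bad = ~landscape.contains(ex, ey)
        tries += 1
    failed = bad.any(axis=1)
    return ex, ey, L, failed


def sample_random_steps(step, kernel: GammaKernel, landscape: LandscapeStack,
                        n: int = 10, seed=0) -> pd.DataFrame:
    """One unannotated stratum: the realized step plus n random steps.

    ``step`` is a row (Series) from :func:`build_steps` with a defined
    previous direction (non-NaN turning angle reference), i.e. random turns
    are applied relative to the previous step's absolute direction.
    """
    if np.isnan(step["turn"]):
        raise ValueError("step has no turning-angle reference direction")
    rng = np.random.default_rng(seed)
    ref_dir = step["direction"] - step["turn"]  # previous step's direction
    ex, ey, L, failed = _sample_endpoints(
        np.array([step["x0"]]), np.array([step["y0"]]),
        np.array([ref_dir]), kernel, n, landscape, rng)
    if failed[0]:
        raise RuntimeError("random-step retry cap exhausted near raster edge")
    rec = pd.DataFrame({
        "individual": step["individual"],
        "t": step["t1"],
        "used": [1] + [0] * n,
        "x": np.concatenate([[step["x1"]], ex[0]]),
        "y": np.concatenate([[step["y1"]], ey[0]]),
        "step_length": np.concatenate([[step["length"]], L[0]]),
    })
    return rec


def build_strata(steps: pd.DataFrame, kernels: dict, landscape: LandscapeStack,
                 n_random: int = 10, seed=0) -> pd.DataFrame:
    """Unannotated strata for all steps with a defined turn reference.

    ``kernels`` maps individual id to its :class:`GammaKernel`.  Strata
    whose random steps cannot be placed inside the extent after the retry
    cap are dropped (counted in the ``attrs['dropped_strata']`` tag).
    """
    rng = np.random.default_rng(seed)
    usable = steps[steps["turn"].notna()].reset_index(drop=True)
    parts = []
    next_id = 0
    dropped = 0
    for ind, grp in usable.groupby("individual", sort=True):
        kern = kernels[ind]
        ref = (grp["direction"] - grp["turn"]).to_numpy()
        ex, ey, L, failed = _sample_endpoints(
            grp["x0"].to_numpy(), grp["y0"].to_numpy(), ref, kern,
            n_random, landscape, rng)
        keep = ~failed
        dropped += int(failed.sum())
        g = grp[keep]
        m = len(g)
        if m == 0:
            continue
        sid = next_id + np.arange(m)
        next_id += m
        size = n_random + 1
        part = pd.DataFrame({
            "stratum_id": np.repeat(sid, size),
            "individual": np.repeat(g["individual"].to_numpy(), size),
            "t": np.repeat(g["t1"].to_numpy(), size),
            "used": np.tile([1] + [0] * n_random, m),
            "x": np.column_stack([g["x1"].to_numpy(), ex[keep]]).ravel(),
            "y": np.column_stack([g["y1"].to_numpy(), ey[keep]]).ravel(),
            "step_length": np.column_stack(
                [g["length"].to_numpy(), L[keep]]).ravel(),
        })
        parts.append(part)
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=["stratum_id", "individual", "t", "used",
                                      "x", "y", "step_length"]))
    out.attrs["dropped_strata"] = dropped
    return out


# --------------------------------------------------------------------------
# annotation

def annotate_covariates(strata: pd.DataFrame, landscape: LandscapeStack,
                        weather: WeatherSeries,
                        latitude: float = solar.DEFAULT_LAT,
                        longitude: float = solar.DEFAULT_LON) -> pd.DataFrame:
    """Attach terrain, weather and day/night to every stratum position.

    Raster values are read from the cell containing each endpoint; tree
    cover uses the epoch nearest the fix year (ties towards the earlier
    epoch).  Weather is matched at the step end time: temperature/wind
    from the covering hourly record, precipitation from the covering 3-h
    bin, snow from that day's 05:00 reading.  Weather and the day flag are
    stratum-constant by construction (all members share the timestamp).
    """
    df = strata.copy()
    x = df["x"].to_numpy(); y = df["y"].to_numpy()
    if not landscape.contains(x, y).all():
        raise ValueError("stratum endpoint outside raster extent")
    t = pd.DatetimeIndex(df["t"])
    df["elevation"] = landscape.sample("elevation", x, y)
    df["slope"] = landscape.sample("slope", x, y)
    df["northness"] = landscape.sample("northness", x, y)
    df["eastness"] = landscape.sample("eastness", x, y)
    df["tcd"] = landscape.sample("tcd", x, y, epoch_year=t.year.to_numpy())
    temp, wind = weather.temperature_wind(t)
    df["temperature"] = temp
    df["wind"] = wind
    df["precipitation"] = weather.precipitation(t)
    df["snow"] = weather.snow(t)
    uniq, inv = np.unique(df["t"].to_numpy(), return_inverse=True)
    day_uniq = solar.assign_daynight(uniq, latitude, longitude)
    df["day"] = np.asarray(day_uniq)[inv]
    return df


# --------------------------------------------------------------------------
# seasons and completeness

def assign_season(timestamps):
    """'summer' (Jun-Oct), 'winter' (Dec-Apr) or 'excluded' (May, Nov)."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    month = t.month.to_numpy()
    out = np.where(np.isin(month, SEASON_MONTHS["summer"]), "summer",
                   np.where(np.isin(month, SEASON_MONTHS["winter"]),
                            "winter", "excluded"))
    if np.isscalar(timestamps) or isinstance(timestamps, pd.Timestamp):
        return out[0]
    return out


def season_days(season: str, year: int) -> int:
    """Calendar length of a season window starting in ``year``.

    Summer runs 1 June - 31 October of ``year``; winter runs 1 December of
    ``year`` - 30 April of ``year + 1``.
    """
    if season == "summer":
        return (pd.Timestamp(year, 11, 1) - pd.Timestamp(year, 6, 1)).days
    if season == "winter":
        return (pd.Timestamp(year + 1, 5, 1) - pd.Timestamp(year, 12, 1)).days
    raise ValueError(f"unknown season {season!r}")


def filter_individuals(counts: dict, season: str, year: int | None = None,
                       possible: int | None = None, threshold: float = 0.8,
                       fixes_per_day: int = 6) -> list:
    """Individuals with at least 80 % of theoretically possible positions.

    ``possible`` overrides the calendar computation (days x 6 fixes/day on
    the 4-h schedule).
    """
    if possible is None:
        if year is None:
            raise ValueError("need either possible or year")
        possible = season_days(season, year) * fixes_per_day
    cut = threshold * possible
    return [ind for ind, n in counts.items() if n >= cut]


# --------------------------------------------------------------------------
# standardization

@dataclass
class Standardization:
    """Per-covariate moments of the z-transform, for back-conversion."""

    season: str
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def z(self, name: str, value):
        return (np.asarray(value, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, zval):
        return np.asarray(zval, dtype=float) * self.sds[name] + self.means[name]

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name in self.means:
            out[name] = self.z(name, df[name].to_numpy())
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"season": self.season, "means": self.means,
                       "sds": self.sds}, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(season=d["season"], means=d["means"], sds=d["sds"])


def continuous_covariates(season: str) -> tuple:
    """Covariates standardized for a season (snow only enters in winter)."""
    cols = ["step_length", *HABITAT_TERMS, "temperature", "wind",
            "precipitation"]
    if season == "winter":
        cols.append("snow")
    return tuple(cols)


def standardize(strata: pd.DataFrame, season: str):
    """Centre and scale the continuous covariates over the pooled strata.

    Moments are computed over all used + available records of the season.
    Returns ``(z_strata, Standardization)``; raises naming the covariate if
    one is constant.
    """
    cols = [c for c in continuous_covariates(season) if c in strata.columns]
    std = Standardization(season=season)
    for c in cols:
        v = strata[c].to_numpy(dtype=float)
        s = v.std(ddof=1)
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"covariate {c!r} is constant; cannot standardize")
        std.means[c] = float(v.mean())
        std.sds[c] = float(s)
    return std.transform(strata), std
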