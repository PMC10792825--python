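"""Collar-trajectory simulation under known step-selection coefficients.

The generative scheme is the standard SSF-consistent one: at every 4-h
tick a finite set of candidate endpoints is drawn from the movement kernel
(gamma step lengths, uniform turning angles) and one candidate is selected
with probability proportional to exp(linear predictor), where the linear
predictor combines standardized habitat covariates at the candidate, the
station weather at the step end time, and their interactions.  As the
candidate set grows this converges to the continuous step-selection model.

Coefficients in :class:`TruthParams` are expressed on the generator's own
standardized scale: habitat moments over the full raster, weather moments
over the simulated window (see :func:`sim_standardization`).  Individual
heterogeneity enters as random slopes drawn per individual from the
configured SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .landscape import LandscapeStack
from .steps import Standardization
from .weather import WeatherSeries

HABITAT_TERMS = ("elevation", "slope", "tcd", "northness", "eastness")
MODIFIERS = ("temperature", "wind", "precipitation", "snow", "day")


@dataclass
class TruthParams:
    """Generative selection coefficients and movement kernel.

    ``beta`` maps term names (habitat mains, ``modifier:habitat``
    interactions, ``tcd:slope``) to coefficients on the generator's
    standardized scale.  The kernel defaults give a median step of about
    128 m at the 4-h schedule (exponential lengths, scale 185 m).
    """

    beta: dict = field(default_factory=dict)
    gamma_shape: float = 1.0
    gamma_scale: float = 185.0
    fix_interval_h: float = 4.0
    random_slope_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if any(v < 0 for v in self.random_slope_sd.values()):
            raise ValueError("random-slope SDs must be non-negative")
        for term in self.beta:
            parts = term.split(":")
            if len(parts) == 1:
                if term not in HABITAT_TERMS:
                    raise ValueError(f"unknown truth term {term!r}")
            else:
                mod, hab = parts
                if hab not in HABITAT_TERMS or (
                        mod not in MODIFIERS and (mod, hab) != ("tcd", "slope")):
                    raise ValueError(f"unknown truth term {term!r}")


@dataclass
class Trajectory:
    """Ordered GPS fixes of one individual."""

    individual: object
    fixes: pd.DataFrame  # columns: timestamp, x, y
    sex: str | None = None

    def __post_init__(self):
        t = self.fixes["timestamp"]
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("fix timestamps must be strictly increasing")


def trajectories_to_csv(trajectories, path):
    rows = []
    for tr in trajectories:
        d = tr.fixes.copy()
        d.insert(0, "id", tr.individual)
        rows.append(d)
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def trajectories_from_csv(path):
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [Trajectory(individual=ind, fixes=g[["timestamp", "x", "y"]]
                       .reset_index(drop=True))
            for ind, g in df.groupby("id", sort=True)]


def sim_standardization(landscape: LandscapeStack, weather: WeatherSeries,
                        season: str = "summer") -> Standardization:
    """Generator-scale moments: habitat over the raster, weather over the
    simulated window (hourly temperature/wind, 3-h precipitation bins,
    daily snow readings)."""
    std = Standardization(season=season)
    for name in HABITAT_TERMS:
        arr = landscape.tcd[2015] if name == "tcd" else getattr(landscape, name)
        std.means[name] = float(arr.mean())
        sd = float(arr.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"constant raster {name!r}")
        std.sds[name] = sd
    h = weather.hourly
    for name, col in (("temperature", "temp_c"), ("wind", "wind_kmh")):
        std.means[name] = float(h[col].mean())
        std.sds[name] = float(h[col].std(ddof=1))
    pr = h["precip_mm_3h"].dropna()
    std.means["precipitation"] = float(pr.mean())
    std.sds["precipitation"] = float(pr.std(ddof=1)) or 1.0
    if season == "winter":
        sn = h["snow_cm"].dropna()
        std.means["snow"] = float(sn.mean())
        std.sds["snow"] = float(sn.std(ddof=1)) or 1.0
    return std


def _weather_z_at(weather: WeatherSeries, std: Standardization, times,
                  season: str, latitude, longitude):
    """Standardized stratum-constant modifiers per timestamp."""
    temp, wind = weather.temperature_wind(times)
    out = {
        "temperature": std.z("temperature", temp),
        "wind": std.z("wind", wind),
        "precipitation": std.z("precipitation", weather.precipitation(times)),
        "day": solar.assign_daynight(times, latitude, longitude).astype(float),
    }
    if season == "winter":
        out["snow"] = std.z("snow", weather.snow(times))
    else:
        out["snow"] = np.zeros(len(pd.DatetimeIndex(times)))
    return out


def simulate_trajectories(
    landscape: LandscapeStack,
    weather: WeatherSeries,
    truth: TruthParams,
    n_individuals: int = 30,
    n_steps: int = 200,
    proposals_per_step: int = 200,
    start_time="2019-06-01 00:00",
    season: str = "summer",
    latitude: float = solar.DEFAULT_LAT,
    longitude: float = solar.DEFAULT_LON,
    start_margin_frac: float = 0.25,
    max_retry: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[Trajectory]:
    """Simulate ``n_individuals`` collared animals for ``n_steps`` ticks.

    All individuals move on the common 4-h schedule starting at
    ``start_time``; candidates falling outside the raster are redrawn
    (bounded retries).  Deterministic for a fixed (config, seed).
    """
    if proposals_per_step < 50:
        raise ValueError("need at least 50 proposals per step")
    rng = np.random.default_rng(seed)
    std = sim_standardization(landscape, weather, season)
    times = pd.date_range(pd.Timestamp(start_time),
                          periods=n_steps + 1,
                          freq=pd.Timedelta(hours=truth.fix_interval_h))
    wz = _weather_z_at(weather, std, times, season, latitude, longitude)

    # per-individual coefficients on habitat mains (random slopes)
    beta_main = np.array([truth.beta.get(h, 0.0) for h in HABITAT_TERMS])
    b = np.zeros((n_individuals, len(HABITAT_TERMS)))
    for j, h in enumerate(HABITAT_TERMS):
        sd = truth.random_slope_sd.get(h, 0.0)
        if sd > 0:
            b[:, j] = rng.normal(0.0, sd, n_individuals)
    coef_ind = beta_main[None, :] + b

    # interaction coefficients keyed (modifier, habitat)
    inter = {}
    for term, val in truth.beta.items():
        if ":" in term:
            mod, hab = term.split(":")
            inter[(mod, hab)] = val
    beta_ts = inter.pop(("tcd", "slope"), 0.0)

    xmin, xmax, ymin, ymax = landscape.extent
    mx = (xmax - xmin) * start_margin_frac
    my = (ymax - ymin) * start_margin_frac
    px = rng.uniform(xmin + mx, xmax - mx, n_individuals)
    py = rng.uniform(ymin + my, ymax - my, n_individuals)
    heading = rng.uniform(-np.pi, np.pi, n_individuals)

    traj_x = np.empty((n_steps + 1, n_individuals))
    traj_y = np.empty((n_steps + 1, n_individuals))
    traj_x[0] = px
    traj_y[0] = py

    M = proposals_per_step
    for k in range(n_steps):
        L = rng.gamma(truth.gamma_shape, truth.gamma_scale, (n_individuals, M))
        turn = rng.uniform(-np.pi, np.pi, (n_individuals, M))
        ang = heading[:, None] + turn
        ex = px[:, None] + L * np.cos(ang)
        ey = py[:, None] + L * np.sin(ang)
        bad = ~landscape.contains(ex, ey)
        tries = 0
        while bad.any() and tries < max_retry:
            nbad = int(bad.sum())
            L2 = rng.gamma(truth.gamma_shape, truth.gamma_scale, nbad)
            t2 = rng.uniform(-np.pi, np.pi, nbad)
            a2 = np.broadcast_to(heading[:, None], (n_individuals, M))[bad] + t2
            ex[bad] = np.broadcast_to(px[:, None], (n_individuals, M))[bad] \
                + L2 * np.cos(a2)
            ey[bad] = np.broadcast_to(py[:, None], (n_individuals, M))[bad] \
                + L2 * np.sin(a2)
            bad = ~landscape.contains(ex, ey)
            tries += 1
        if bad.any():
            raise RuntimeError("candidate redraw cap exhausted at the edge")

        year = times[k + 1].year
        zhab = {}
        for h in HABITAT_TERMS:
            if h == "tcd":
                v = landscape.sample("tcd", ex, ey, epoch_year=year)
            else:
                v = landscape.sample(h, ex, ey)
            zhab[h] = std.z(h, v)

        # time-varying effective coefficient per habitat and individual
        eta = np.zeros((n_individuals, M))
        for j, h in enumerate(HABITAT_TERMS):
            c = coef_ind[:, j].copy()
            for (mod, hab), val in inter.items():
                if hab == h:
                    c = c + val * wz[mod][k + 1]
            eta += c[:, None] * zhab[h]
        if beta_ts:
            eta += beta_ts * zhab["tcd"] * zhab["slope"]

        emax = eta.max(axis=1, keepdims=True)
        w = np.exp(eta - emax)
        w /= w.sum(axis=1, keepdims=True)
        # vectorized categorical draw per individual
        cum = np.cumsum(w, axis=1)
        u = rng.random((n_individuals, 1))
        pick = (u > cum).sum(axis=1)
        nx = ex[np.arange(n_individuals), pick]
        ny = ey[np.arange(n_individuals), pick]
        heading = np.arctan2(ny - py, nx - px)
        px, py = nx, ny
        traj_x[k + 1] = px
        traj_y[k + 1] = py

    out = []
    for i in range(n_individuals):
        fixes = pd.DataFrame({"timestamp": times, "x": traj_x[:, i],
                              "y": traj_y[:, i]})
        out.append(Trajectory(individual=f"ind{i:03d}", fixes=fixes))
    return out
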