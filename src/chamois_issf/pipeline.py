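"""End-to-end orchestration and packaged simulation experiments.

Stages: generate (or load) landscape, weather and collar fixes; screen and
prepare use-availability strata; fit the step-selection model; backward
AIC; coefficient table and relative-selection curves.  A single global
seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is individually reproducible.

Also provides the parameter-recovery experiment (simulate under known
coefficients, run the full pipeline, compare on a common scale) and the
true-zero-term selection experiment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landscape import LandscapeStack, generate_landscape, load_stack, save_stack
from .model import (ModelSpec, build_design, fit_conditional_logistic,
                    fit_mixed_issf, full_model_spec)
from .selection import backward_aic
from .simulate import (TruthParams, simulate_trajectories, sim_standardization,
                       trajectories_from_csv, trajectories_to_csv)
from .steps import (Standardization, annotate_covariates, build_steps,
                    build_strata, fit_tentative_gamma, filter_individuals,
                    screen_positions, season_days, standardize)
from .surface import (coefficient_table, moderator_levels, plot_curves,
                      relative_selection_curve, table_to_markdown)
from .weather import WeatherSeries, generate_weather

log = logging.getLogger(__name__)

STAGES = ("landscape", "weather", "trajectories", "random_steps")


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    seed: int = 0
    season: str = "summer"
    landscape: dict = field(default_factory=dict)   # {'path': dir} or kwargs
    weather: dict = field(default_factory=dict)
    fixes: dict = field(default_factory=dict)       # {'path': csv} or sim kwargs
    truth: dict = field(default_factory=dict)       # TruthParams kwargs
    screen_ceiling: float = 5000.0
    gamma_floor: float = 1.0
    n_random_steps: int = 10
    fix_interval_h: float = 4.0
    fix_tolerance_min: float = 30.0
    random_slopes: tuple = ()
    run_selection: bool = True
    completeness_filter: bool = False
    moderator_kind: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("landscape", "weather", "fixes"):
            d = getattr(self, name)
            if "path" in d and len(d) > 1:
                raise ValueError(
                    f"config for {name!r} must give either a path or "
                    "generator settings, not both")
        if self.season not in ("summer", "winter"):
            raise ValueError("season must be 'summer' or 'winter'")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "random_slopes" in d:
            d["random_slopes"] = tuple(d["random_slopes"])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seeds(seed: int) -> dict:
    """Fan the global seed out to one child seed per randomized stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(ss.generate_state(1)[0] % 2**31)
            for name, ss in zip(STAGES, children)}


# --------------------------------------------------------------------------
# stage runners

def get_landscape(cfg: PipelineConfig, seeds) -> LandscapeStack:
    if "path" in cfg.landscape:
        return load_stack(cfg.landscape["path"])
    kw = dict(cfg.landscape)
    kw.setdefault("seed", seeds["landscape"])
    return generate_landscape(**kw)


def get_weather(cfg: PipelineConfig, seeds) -> WeatherSeries:
    if "path" in cfg.weather:
        return WeatherSeries.from_csv(cfg.weather["path"])
    kw = dict(cfg.weather)
    kw.setdefault("season", cfg.season)
    kw.setdefault("start", "2019-06-01" if cfg.season == "summer"
                  else "2019-12-01")
    kw.setdefault("n_days", 40)
    kw.setdefault("seed", seeds["weather"])
    return generate_weather(**kw)


def get_trajectories(cfg: PipelineConfig, seeds, landscape, weather):
    if "path" in cfg.fixes:
        return trajectories_from_csv(cfg.fixes["path"])
    kw = dict(cfg.fixes)
    kw.setdefault("season", cfg.season)
    kw.setdefault("start_time", weather.hourly.index[0])
    kw.setdefault("seed", seeds["trajectories"])
    truth = TruthParams(**cfg.truth)
    return simulate_trajectories(landscape, weather, truth, **kw)


def prepare_strata(trajectories, landscape, weather, cfg: PipelineConfig,
                   seeds) -> tuple[pd.DataFrame, Standardization, dict]:
    """Screen fixes, build steps and strata, annotate and standardize."""
    report = {"n_fixes_in": 0, "n_fixes_removed": 0, "individuals_in": 0,
              "individuals_retained": 0, "n_steps": 0}
    all_steps = []
    counts = {}
    for tr in trajectories:
        fixes = tr.fixes.copy()
        fixes["individual"] = tr.individual
        report["n_fixes_in"] += len(fixes)
        from .steps import assign_season

        season_mask = assign_season(fixes["timestamp"].to_numpy()) == cfg.season
        fixes = fixes[season_mask]
        cleaned, removed = screen_positions(fixes, cfg.screen_ceiling)
        report["n_fixes_removed"] += len(removed)
        counts[tr.individual] = len(cleaned)
        steps = build_steps(cleaned, cfg.fix_interval_h, cfg.fix_tolerance_min)
        all_steps.append(steps)
    report["individuals_in"] = len(trajectories)

    if cfg.completeness_filter:
        year = int(min(tr.fixes["timestamp"].min() for tr in trajectories).year)
        keep = set(filter_individuals(counts, cfg.season, year=year))
    else:
        keep = set(counts)
    report["individuals_retained"] = len(keep)

    steps = pd.concat([s for s in all_steps if len(s)], ignore_index=True)
    steps = steps[steps["individual"].isin(keep)]
    report["n_steps"] = len(steps)
    kernels = {}
    for ind, grp in steps.groupby("individual"):
        kernels[ind] = fit_tentative_gamma(grp["length"].to_numpy(), ind,
                                           floor=cfg.gamma_floor)
    strata = build_strata(steps, kernels, landscape, cfg.n_random_steps,
                          seed=seeds["random_steps"])
    report["n_strata"] = int(strata["stratum_id"].nunique())
    report["dropped_strata"] = strata.attrs.get("dropped_strata", 0)
    annotated = annotate_covariates(strata, landscape, weather)
    strata_z, std = standardize(annotated, cfg.season)
    return strata_z, std, report


def fit_spec(strata_z: pd.DataFrame, spec: ModelSpec):
    design = build_design(spec, strata_z)
    if spec.random_slopes:
        return fit_mixed_issf(design)
    return fit_conditional_logistic(design)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the artifact paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    artifacts = {}

    landscape = get_landscape(cfg, seeds)
    weather = get_weather(cfg, seeds)
    trajectories = get_trajectories(cfg, seeds, landscape, weather)
    save_stack(landscape, outdir / "landscape")
    weather.to_csv(outdir / "weather.csv")
    trajectories_to_csv(trajectories, outdir / "fixes.csv")
    artifacts["fixes"] = str(outdir / "fixes.csv")

    strata_z, std, report = prepare_strata(trajectories, landscape, weather,
                                           cfg, seeds)
    strata_path = outdir / "strata.csv"
    strata_z.to_csv(strata_path, index=False, date_format="%Y-%m-%dT%H:%M:%S",
                    float_format="%.10g")
    std.to_json(outdir / "standardization.json")
    artifacts["strata"] = str(strata_path)
    log.info("prepared %d strata from %d individuals", report.get("n_strata", 0),
             report["individuals_retained"])

    spec = full_model_spec(cfg.season, random_slopes=tuple(cfg.random_slopes))
    fit = fit_spec(strata_z, spec)
    fit.to_json(outdir / "fit_full.json")
    artifacts["fit_full"] = str(outdir / "fit_full.json")

    if cfg.run_selection:
        trace = backward_aic(spec, strata_z,
                             fitter=lambda sp, st: fit_spec(st, sp))
        trace.to_csv(outdir / "selection_trace.csv")
        final_fit = trace.final_fit
        final_fit.to_json(outdir / "fit_final.json")
        artifacts["trace"] = str(outdir / "selection_trace.csv")
        final_spec = trace.final_spec
    else:
        final_fit, final_spec = fit, spec

    table = coefficient_table(final_fit, full_spec=spec)
    table.to_csv(outdir / "coefficients.csv", index=False)
    (outdir / "coefficients.md").write_text(table_to_markdown(table))
    artifacts["table"] = str(outdir / "coefficients.csv")

    curve_dir = outdir / "curves"
    curve_dir.mkdir(exist_ok=True)
    for focal in ("elevation", "tcd", "northness"):
        if focal not in final_spec.mains:
            continue
        curves = []
        levels = moderator_levels(
            _destandardized(strata_z, std, "temperature"), "temperature")
        for name, level in levels.items():
            curves.append(relative_selection_curve(
                final_fit, std, focal, moderators={"temperature": level}))
        pd.concat([c.to_frame().assign(level=nm)
                   for c, nm in zip(curves, levels)]).to_csv(
            curve_dir / f"{focal}_by_temperature.csv", index=False)
        plot_curves(curves, curve_dir / f"{focal}_by_temperature.png",
                    xlabel=focal)
    artifacts["curves"] = str(curve_dir)

    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "report": report,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts


def _destandardized(strata_z, std: Standardization, *names) -> pd.DataFrame:
    out = strata_z.copy()
    for n in (names or std.means):
        if n in out.columns and n in std.means:
            out[n] = std.inverse(n, out[n].to_numpy())
    return out


# --------------------------------------------------------------------------
# coefficient scale conversion (exact affine algebra)

def _mu_s(std: Standardization, name: str):
    """Moments of a component; the 0/1 day flag is unscaled."""
    if name in std.means:
        return std.means[name], std.sds[name]
    return 0.0, 1.0


def scale_matrix_to_raw(terms, std: Standardization) -> np.ndarray:
    """Matrix R with beta_raw = R @ beta_std for the given term list.

    Raw space is spanned by the same terms read as raw monomials
    (x_h for mains, x_a * x_b for interactions).  Standardizing is affine,
    so an interaction of standardized components spills into the raw main
    effects of its standardized components; constants vanish in the
    conditional likelihood.
    """
    p = len(terms)
    R = np.zeros((p, p))
    idx = {t: i for i, t in enumerate(terms)}
    for j, t in enumerate(terms):
        parts = t.split(":")
        if len(parts) == 1:
            _, s = _mu_s(std, t)
            R[j, j] = 1.0 / s
        else:
            a, b = parts
            mu_a, s_a = _mu_s(std, a)
            mu_b, s_b = _mu_s(std, b)
            R[j, j] = 1.0 / (s_a * s_b)
            if a in idx:
                R[idx[a], j] -= mu_b / (s_a * s_b)
            if b in idx:
                R[idx[b], j] -= mu_a / (s_a * s_b)
    return R


def scale_conversion_matrix(terms, from_std: Standardization,
                            to_std: Standardization) -> np.ndarray:
    """A with beta_to = A @ beta_from, exact for the affine z-transforms."""
    R_from = scale_matrix_to_raw(terms, from_std)
    R_to = scale_matrix_to_raw(terms, to_std)
    return np.linalg.solve(R_to, R_from)


# --------------------------------------------------------------------------
# packaged experiments

def _one_synthetic_dataset(truth: TruthParams, cfg: PipelineConfig, seed: int,
                           n_individuals: int, n_steps: int,
                           proposals_per_step: int = 200):
    seeds = stage_seeds(seed)
    landscape = get_landscape(cfg, seeds)
    weather = get_weather(cfg, seeds)
    start = weather.hourly.index[0]
    trajectories = simulate_trajectories(
        landscape, weather, truth, n_individuals=n_individuals,
        n_steps=n_steps, proposals_per_step=proposals_per_step,
        start_time=start, season=cfg.season, seed=seeds["trajectories"])
    strata_z, std, report = prepare_strata(trajectories, landscape, weather,
                                           cfg, seeds)
    gen_std = sim_standardization(landscape, weather, cfg.season)
    return strata_z, std, gen_std, report


def parameter_recovery_experiment(
    truth: TruthParams,
    n_replicates: int = 50,
    seed: int = 1,
    n_individuals: int = 30,
    n_steps: int = 200,
    season: str = "summer",
    cfg: PipelineConfig | None = None,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Simulate -> pipeline -> fit; per-term bias, RMSE and CI coverage.

    Fitted coefficients (pooled-strata z-scale) are mapped onto the
    generator's standardized scale by the exact affine conversion, so
    estimates are compared with the truth term by term.  Replicate-level
    failures are recorded, not fatal.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = cfg or PipelineConfig(season=season)
    spec = spec or full_model_spec(season)
    master = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in master.spawn(n_replicates)]
    rows = []
    failures = []
    for r, rs in enumerate(rep_seeds):
        try:
            strata_z, std, gen_std, _ = _one_synthetic_dataset(
                truth, cfg, rs, n_individuals, n_steps)
            fit = fit_spec(strata_z, spec)
            if not fit.converged:
                raise RuntimeError("fit did not converge")
            A = scale_conversion_matrix(fit.terms, std, gen_std)
            beta_g = A @ fit.beta
            cov_g = A @ fit.cov @ A.T
            se_g = np.sqrt(np.clip(np.diag(cov_g), 0.0, None))
            for j, t in enumerate(fit.terms):
                tv = truth.beta.get(t, 0.0) if t != "step_length" else np.nan
                rows.append({"replicate": r, "term": t, "estimate": beta_g[j],
                             "se": se_g[j], "truth": tv})
        except Exception as exc:
            failures.append({"replicate": r, "error": str(exc)})
            log.warning("replicate %d failed: %s", r, exc)
    df = pd.DataFrame(rows)
    z = 1.959964
    df["covered"] = ((df["truth"] >= df["estimate"] - z * df["se"])
                     & (df["truth"] <= df["estimate"] + z * df["se"]))
    summary = (df.dropna(subset=["truth"])
               .groupby("term")
               .agg(truth=("truth", "first"),
                    mean_estimate=("estimate", "mean"),
                    sd_estimate=("estimate", "std"),
                    coverage=("covered", "mean"),
                    n=("estimate", "size")))
    summary["bias"] = summary["mean_estimate"] - summary["truth"]
    summary["rmse"] = np.sqrt(
        df.dropna(subset=["truth"])
        .assign(err2=lambda d: (d["estimate"] - d["truth"]) ** 2)
        .groupby("term")["err2"].mean())
    summary.attrs["failures"] = failures
    summary.attrs["replicates"] = df
    return summary.reset_index()


def selection_experiment(
    truth: TruthParams,
    zero_term: str,
    n_replicates: int = 20,
    seed: int = 2,
    n_individuals: int = 15,
    n_steps: int = 210,
    season: str = "summer",
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Backward-AIC behaviour with a known true-zero interaction.

    Returns one row per replicate with whether ``zero_term`` was removed
    and whether the accepted-AIC path was non-increasing.
    """
    cfg = cfg or PipelineConfig(season=season)
    assert truth.beta.get(zero_term, 0.0) == 0.0
    spec = full_model_spec(season)
    master = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in master.spawn(n_replicates)]
    rows = []
    for r, rs in enumerate(rep_seeds):
        strata_z, std, gen_std, _ = _one_synthetic_dataset(
            truth, cfg, rs, n_individuals, n_steps)
        trace = backward_aic(spec, strata_z,
                             fitter=lambda sp, st: fit_spec(st, sp))
        final_terms = trace.final_spec.terms
        aics = trace.aic_path
        rows.append({
            "replicate": r,
            "removed": zero_term not in final_terms,
            "aic_non_increasing": all(a2 <= a1 + 1e-9
                                      for a1, a2 in zip(aics, aics[1:])),
            "n_rounds": len(aics) - 1,
            "final_aic": aics[-1],
        })
    return pd.DataFrame(rows)
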