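"""Relative-selection curves and coefficient tables.

The relative selection strength f_u/f_a over a focal covariate compares the
model's linear predictor at a grid of focal values against a reference
point (season means, z = 0, by default), with moderators held at chosen
levels:

    ratio(x) = exp(eta(x, moderators) - eta(x_ref, moderators))

Values above 1 indicate preference, below 1 avoidance.  The 95 % band comes
from the delta method on the linear-predictor contrast (normal quantile
1.959964), using the fixed-effect covariance only — population-level
curves that ignore individual random-slope deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Z_975, FitResult, ModelSpec, star_code, wald_inference
from .steps import Standardization


@dataclass
class SelectionCurve:
    focal: str
    x: np.ndarray           # focal grid, original units
    ratio: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    moderators: dict = field(default_factory=dict)
    reference: float | None = None  # focal reference, original units

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "ratio": self.ratio,
                           "lower": self.lower, "upper": self.upper})
        for k, v in self.moderators.items():
            df[k] = v
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _term_value(term: str, setting: dict) -> float:
    """Value of a model term (on the model's z-scale) under a setting of
    z-values; unspecified components default to 0 (the season mean)."""
    parts = term.split(":")
    val = 1.0
    for p in parts:
        val *= setting.get(p, 0.0)
    return val


def relative_selection_curve(
    fit: FitResult,
    standardization: Standardization,
    focal: str,
    grid=None,
    moderators: dict | None = None,
    reference: float | None = None,
    observed_range: dict | None = None,
    n_grid: int = 100,
) -> SelectionCurve:
    """f_u/f_a over ``focal`` (original units) at fixed moderator levels.

    ``moderators`` maps modifier names to levels in original units (the
    day flag on its 0/1 scale).  ``reference`` is the focal value the curve
    is anchored at (ratio 1); default is the season mean.  ``grid`` is in
    original units; default spans +/- 2 SD around the mean.  A moderator
    level outside ``observed_range`` (name -> (lo, hi)) triggers a warning,
    not an error.
    """
    moderators = dict(moderators or {})
    if focal not in standardization.means:
        raise ValueError(f"unknown focal covariate {focal!r}")
    for name, level in moderators.items():
        if observed_range and name in observed_range:
            lo, hi = observed_range[name]
            if not lo <= level <= hi:
                import warnings

                warnings.warn(f"moderator {name}={level} outside observed "
                              f"range [{lo}, {hi}]")

    if grid is None:
        m, s = standardization.means[focal], standardization.sds[focal]
        grid = np.linspace(m - 2 * s, m + 2 * s, n_grid)
    grid = np.asarray(grid, dtype=float)
    zgrid = standardization.z(focal, grid)
    if reference is None:
        zref = 0.0
        reference = standardization.means[focal]
    else:
        zref = float(standardization.z(focal, reference))

    zmod = {}
    for name, level in moderators.items():
        if name in standardization.means:
            zmod[name] = float(standardization.z(name, level))
        else:  # the 0/1 day flag and other unscaled modifiers
            zmod[name] = float(level)

    ratio = np.empty(len(grid))
    lower = np.empty(len(grid))
    upper = np.empty(len(grid))
    base = dict(zmod)
    base[focal] = zref
    v_ref = np.array([_term_value(t, base) for t in fit.terms])
    for i, zx in enumerate(zgrid):
        setting = dict(zmod)
        setting[focal] = float(zx)
        v = np.array([_term_value(t, setting) for t in fit.terms])
        c = v - v_ref
        est = float(c @ fit.beta)
        sd = float(np.sqrt(max(c @ fit.cov @ c, 0.0)))
        ratio[i] = np.exp(est)
        lower[i] = np.exp(est - Z_975 * sd)
        upper[i] = np.exp(est + Z_975 * sd)
    return SelectionCurve(focal=focal, x=grid, ratio=ratio, lower=lower,
                          upper=upper, moderators=moderators,
                          reference=reference)


def moderator_levels(strata: pd.DataFrame, name: str,
                     kind: str = "min_mean_max") -> dict:
    """Low/intermediate/high moderator levels from the observed season data.

    Default: seasonal minimum, mean and maximum.  ``kind='quantile'`` caps
    the levels at the 50/90/99 % quantiles instead, appropriate for
    zero-skewed covariates such as precipitation.
    """
    v = strata[name].to_numpy(dtype=float)
    if kind == "quantile":
        lo, mid, hi = np.quantile(v, [0.5, 0.9, 0.99])
    else:
        lo, mid, hi = float(v.min()), float(v.mean()), float(v.max())
    return {"low": lo, "intermediate": mid, "high": hi}


def plot_curves(curves, path=None, xlabel=None, title=None):
    """Render one or more curves (with bands) to a matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if isinstance(curves, SelectionCurve):
        curves = [curves]
    for cv in curves:
        label = ", ".join(f"{k}={v:g}" for k, v in cv.moderators.items()) or None
        line, = ax.plot(cv.x, cv.ratio, label=label)
        ax.fill_between(cv.x, cv.lower, cv.upper, alpha=0.2,
                        color=line.get_color())
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(xlabel or curves[0].focal)
    ax.set_ylabel("f_u / f_a")
    if title:
        ax.set_title(title)
    if any(cv.moderators for cv in curves):
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def coefficient_table(fit: FitResult, full_spec: ModelSpec | None = None,
                      never_included: tuple = ()) -> pd.DataFrame:
    """Coefficient table: estimate (SE) with stars and the 95 % CI.

    Terms of ``full_spec`` removed during selection are rendered with the
    '-' marker; ``never_included`` terms (e.g. snow in summer) as 'n.a.'.
    Footer rows carry the stratum and individual counts.
    """
    inf = wald_inference(fit).set_index("term")
    all_terms = list(full_spec.terms) if full_spec is not None else list(fit.terms)
    rows = []
    for t in all_terms:
        if t in never_included:
            rows.append({"term": t, "estimate_se": "n.a.", "ci": "n.a."})
        elif t in inf.index:
            r = inf.loc[t]
            rows.append({
                "term": t,
                "estimate_se": f"{r.estimate:.3f} ({r.se:.3f}){r.stars}",
                "ci": f"{r.ci_lower:.3f}, {r.ci_upper:.3f}",
            })
        else:
            rows.append({"term": t, "estimate_se": "−", "ci": "−"})
    rows.append({"term": "N_individuals", "estimate_se": str(fit.n_individuals),
                 "ci": ""})
    rows.append({"term": "N_strata", "estimate_se": str(fit.n_strata), "ci": ""})
    return pd.DataFrame(rows)


def table_to_markdown(table: pd.DataFrame) -> str:
    lines = ["| Predictor | Estimate (SE) | 95% CI |", "|---|---|---|"]
    for _, r in table.iterrows():
        lines.append(f"| {r['term']} | {r['estimate_se']} | {r['ci']} |")
    return "\n".join(lines)
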