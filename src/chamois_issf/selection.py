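"""Stepwise backward AIC over the interaction grammar.

At each round every currently removable term is dropped in turn, every
candidate model is refitted, and the lowest-AIC candidate replaces the
incumbent if it improves on it; the procedure stops when no removal lowers
AIC.  Interactions are always removable; a habitat main only once it has
disappeared from all retained interactions (marginality rule); the step
length term, a movement-kernel adjustment, is never removable.  Near-ties
(delta AIC < 2 between the accepted model and a rejected candidate in the
same round) are recorded, mirroring how runner-up models are commonly
reported, but selection is strictly lowest-AIC with deterministic
tie-breaks (fewer parameters, then lexicographic term order).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import (Design, FitResult, ModelSpec, build_design,
                    fit_conditional_logistic, fit_mixed_issf)

log = logging.getLogger(__name__)


@dataclass
class SelectionTrace:
    rounds: list = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None
    near_ties: list = field(default_factory=list)

    @property
    def aic_path(self) -> list:
        return [r["aic"] for r in self.rounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rounds)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def default_fitter(spec: ModelSpec, strata: pd.DataFrame) -> FitResult:
    """Fit a spec: mixed when random slopes are requested, else the
    fixed-effects conditional-logistic Newton fit."""
    design = build_design(spec, strata)
    if spec.random_slopes:
        return fit_mixed_issf(design)
    return fit_conditional_logistic(design)


def removable_terms(spec: ModelSpec) -> list:
    """Interactions always; mains only when free of retained interactions."""
    terms = [f"{m}:{h}" for m, h in spec.interactions]
    bound = set()
    for m, h in spec.interactions:
        bound.add(h)
        if (m, h) == ("tcd", "slope"):
            bound.add(m)
    terms += [m for m in spec.mains if m not in bound]
    return terms


def backward_aic(full_spec: ModelSpec, strata: pd.DataFrame,
                 fitter=default_fitter, max_rounds: int = 100) -> SelectionTrace:
    """Backward AIC selection starting from the full model."""
    trace = SelectionTrace()
    incumbent_spec = full_spec
    incumbent_fit = fitter(full_spec, strata)
    if not incumbent_fit.converged:
        raise RuntimeError("full model did not converge")
    trace.rounds.append({"round": 0, "removed_term": None,
                         "aic": incumbent_fit.aic, "delta": 0.0})

    for rnd in range(1, max_rounds + 1):
        candidates = []
        for term in removable_terms(incumbent_spec):
            cand_spec = incumbent_spec.drop(term)
            try:
                fit = fitter(cand_spec, strata)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"candidate drop {term!r} failed: {exc}")
                continue
            if not fit.converged:
                warnings.warn(f"candidate drop {term!r} did not converge; skipped")
                continue
            candidates.append((term, cand_spec, fit))
        if not candidates:
            break
        # lowest AIC; ties -> fewer parameters, then term order
        candidates.sort(key=lambda c: (c[2].aic, c[2].n_params, c[0]))
        best_term, best_spec, best_fit = candidates[0]
        if best_fit.aic >= incumbent_fit.aic:
            break
        for term, _, fit in candidates[1:]:
            if fit.aic - best_fit.aic < 2.0:
                trace.near_ties.append({"round": rnd, "term": term,
                                        "aic": fit.aic,
                                        "delta_to_accepted": fit.aic - best_fit.aic})
        trace.rounds.append({"round": rnd, "removed_term": best_term,
                             "aic": best_fit.aic,
                             "delta": best_fit.aic - incumbent_fit.aic})
        log.info("round %d: removed %s (AIC %.2f -> %.2f)", rnd, best_term,
                 incumbent_fit.aic, best_fit.aic)
        incumbent_spec, incumbent_fit = best_spec, best_fit

    trace.final_spec = incumbent_spec
    trace.final_fit = incumbent_fit
    return trace
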