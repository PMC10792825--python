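"""Shared fixtures: small synthetic landscapes, weather, and direct
multinomial-choice strata (the exact data-generating process of the
conditional-logistic likelihood, independent of the trajectory simulator)."""

import numpy as np
import pandas as pd
import pytest

from chamois_issf import generate_landscape, generate_weather


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(n_rows=80, n_cols=80, cell_size=25.0,
                              smoothness=5.0, seed=42)


@pytest.fixture(scope="session")
def summer_weather():
    return generate_weather("2019-06-01", 40, season="summer", seed=7)


@pytest.fixture(scope="session")
def winter_weather():
    return generate_weather("2019-12-01", 40, season="winter", seed=8)


def make_choice_strata(seed, n_strata=200, n_avail=10, beta=None,
                       n_individuals=4, random_slope_sd=None,
                       modifiers=("temperature",), habitats=("elevation",)):
    """Strata drawn exactly from the conditional-logistic model.

    Habitat covariates are iid standard normal per record; modifiers are
    standard normal per stratum (stratum-constant); the used record is a
    multinomial draw with probabilities softmax(eta).  ``beta`` maps term
    names (mains, 'mod:hab' products, 'step_length') to coefficients.
    """
    rng = np.random.default_rng(seed)
    beta = beta or {}
    random_slope_sd = random_slope_sd or {}
    J = n_avail + 1
    rows = []
    per_ind = n_strata // n_individuals
    sid = 0
    for i in range(n_individuals):
        b = {h: rng.normal(0.0, sd) for h, sd in random_slope_sd.items()}
        for _ in range(per_ind):
            rec = {"stratum_id": sid, "individual": f"i{i}"}
            sid += 1
            cols = {h: rng.standard_normal(J) for h in habitats}
            cols["step_length"] = rng.standard_normal(J)
            mod = {m: float(rng.standard_normal()) for m in modifiers}
            eta = np.zeros(J)
            for term, val in beta.items():
                if ":" in term:
                    m, h = term.split(":")
                    x = cols[h] * (mod[m] if m in mod else cols[m])
                elif term in cols:
                    x = cols[term]
                else:
                    continue
                eta += (val + b.get(term, 0.0)) * x
            for h, bv in b.items():
                if h not in beta:
                    eta += bv * cols[h]
            p = np.exp(eta - eta.max())
            p /= p.sum()
            used = np.zeros(J)
            used[rng.choice(J, p=p)] = 1.0
            df = pd.DataFrame({**{k: np.full(J, v) for k, v in rec.items()},
                               "used": used, **cols,
                               **{m: np.full(J, v) for m, v in mod.items()}})
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
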