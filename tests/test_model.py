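"""Model grammar, conditional-logistic and Poisson-trick estimators,
mixed random-slope fit, and Wald inference."""

import numpy as np
import pandas as pd
import pytest

from chamois_issf.model import (ModelSpec, SpecError, build_design,
                                fit_conditional_logistic, fit_mixed_issf,
                                fit_poisson_trick, full_model_spec, star_code,
                                wald_inference)

from conftest import make_choice_strata


class TestModelSpec:
    def test_full_summer_has_19_columns(self):
        spec = full_model_spec("summer")
        assert len(spec.terms) == 19

    def test_full_winter_has_22_columns(self):
        spec = full_model_spec("winter")
        assert len(spec.terms) == 22
        extra = set(full_model_spec("winter").terms) \
            - set(full_model_spec("summer").terms)
        assert extra == {"snow:elevation", "snow:slope", "snow:tcd"}

    def test_lone_modifier_rejected(self):
        with pytest.raises(SpecError, match="constant within a stratum"):
            ModelSpec(mains=("temperature",))

    def test_eastness_never_interacts(self):
        spec = full_model_spec("summer")
        assert not any(h == "eastness" for _, h in spec.interactions)
        assert [h for m, h in spec.interactions if m == "temperature"] \
            == ["elevation", "tcd", "northness"]

    def test_random_slopes_must_be_mains(self):
        with pytest.raises(SpecError):
            ModelSpec(mains=("elevation",), random_slopes=("slope",))

    def test_drop_term(self):
        spec = full_model_spec("summer")
        smaller = spec.drop("wind:slope")
        assert "wind:slope" not in smaller.terms
        assert len(smaller.terms) == 18
        with pytest.raises(SpecError):
            spec.drop("nonexistent")


class TestConditionalLogistic:
    def test_null_loglik_is_minus_n_log_11(self):
        df = make_choice_strata(seed=1, n_strata=100, beta={})
        spec = ModelSpec(mains=("elevation",))
        design = build_design(spec, df)
        from chamois_issf.model import _cl_loglik_grad_hess

        ll0, _, _ = _cl_loglik_grad_hess(np.zeros(design.X.shape[1]), design)
        assert ll0 == pytest.approx(-100 * np.log(11.0), abs=1e-10)

    def test_recovers_simulated_coefficients(self):
        beta = {"elevation": 0.5, "step_length": -0.2,
                "temperature:elevation": 0.3}
        df = make_choice_strata(seed=2, n_strata=2000, beta=beta)
        spec = ModelSpec(mains=("elevation",),
                         interactions=(("temperature", "elevation"),))
        fit = fit_conditional_logistic(build_design(spec, df))
        assert fit.converged
        for t, truth in [("elevation", 0.5), ("step_length", -0.2),
                         ("temperature:elevation", 0.3)]:
            j = fit.terms.index(t)
            assert abs(fit.beta[j] - truth) < 3 * fit.se[j]

    def test_matches_statsmodels(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        beta = {"elevation": 0.4, "step_length": 0.1}
        df = make_choice_strata(seed=3, n_strata=400, beta=beta)
        spec = ModelSpec(mains=("elevation",))
        design = build_design(spec, df)
        fit = fit_conditional_logistic(design)
        sm = ConditionalLogit(design.used, design.X,
                              groups=np.repeat(np.arange(design.n_strata), 11)
                              ).fit(disp=0, method="bfgs", gtol=1e-10)
        assert np.allclose(fit.beta, sm.params, atol=1e-4)

    def test_gradient_zero_at_optimum(self):
        df = make_choice_strata(seed=4, n_strata=300, beta={"elevation": 0.3})
        design = build_design(ModelSpec(mains=("elevation",)), df)
        fit = fit_conditional_logistic(design)
        from chamois_issf.model import _cl_loglik_grad_hess

        _, grad, H = _cl_loglik_grad_hess(fit.beta, design)
        assert np.linalg.norm(grad) < 1e-6
        assert np.all(np.linalg.eigvalsh(H) > -1e-8)  # PSD information

    def test_separation_flagged(self):
        # used record is always the maximum of the covariate -> monotone lik.
        rng = np.random.default_rng(5)
        rows = []
        for s in range(30):
            x = rng.standard_normal(11)
            used = np.zeros(11)
            used[np.argmax(x)] = 1
            rows.append(pd.DataFrame({
                "stratum_id": s, "individual": "a", "used": used,
                "elevation": x, "step_length": rng.standard_normal(11)}))
        df = pd.concat(rows, ignore_index=True)
        fit = fit_conditional_logistic(
            build_design(ModelSpec(mains=("elevation",)), df))
        assert "separation" in fit.flags

    def test_stratum_without_used_rejected(self):
        df = make_choice_strata(seed=6, n_strata=20, beta={})
        df.loc[df.index[:11], "used"] = 0.0
        with pytest.raises(ValueError):
            build_design(ModelSpec(mains=("elevation",)), df)


class TestPoissonTrickEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_beta_agreement_small_datasets(self, seed):
        df = make_choice_strata(seed=seed, n_strata=48,
                                beta={"elevation": 0.4,
                                      "temperature:elevation": -0.3})
        spec = ModelSpec(mains=("elevation",),
                         interactions=(("temperature", "elevation"),))
        design = build_design(spec, df)
        cl = fit_conditional_logistic(design)
        pt = fit_poisson_trick(design)
        assert np.max(np.abs(cl.beta - pt.beta)) < 1e-4

    def test_loglik_offset_is_stratum_count(self):
        # at infinite intercept variance the offset is exactly -N (fitted
        # Poisson means sum to 1 per stratum); at 1e6 it differs by O(1/V)
        df = make_choice_strata(seed=11, n_strata=50, beta={"elevation": 0.4})
        design = build_design(ModelSpec(mains=("elevation",)), df)
        cl = fit_conditional_logistic(design)
        pt = fit_poisson_trick(design)
        assert (cl.loglik - pt.loglik) == pytest.approx(design.n_strata,
                                                        abs=0.01)

    def test_se_agreement(self):
        df = make_choice_strata(seed=12, n_strata=200, beta={"elevation": 0.4})
        design = build_design(ModelSpec(mains=("elevation",)), df)
        cl = fit_conditional_logistic(design)
        pt = fit_poisson_trick(design)
        assert np.allclose(cl.se, pt.se, rtol=1e-3)


class TestMixedModel:
    def test_zero_variance_limit_matches_fixed_fit(self):
        df = make_choice_strata(seed=21, n_strata=300, n_individuals=5,
                                beta={"elevation": 0.4})
        spec = ModelSpec(mains=("elevation",), random_slopes=("elevation",))
        design = build_design(spec, df)
        cl = fit_conditional_logistic(design)
        mx = fit_mixed_issf(design, theta_fixed=[1e-4])
        assert np.max(np.abs(cl.beta - mx.beta)) < 1e-4

    def test_recovers_random_slope_sd(self):
        df = make_choice_strata(seed=22, n_strata=6000, n_individuals=30,
                                beta={"elevation": 0.4},
                                random_slope_sd={"elevation": 0.5})
        spec = ModelSpec(mains=("elevation",), random_slopes=("elevation",))
        mx = fit_mixed_issf(build_design(spec, df))
        assert 0.3 <= mx.random_slope_sd["elevation"] <= 0.7
        # the fixed effect should track the realized individual mean slope
        # (per-individual conditional-logistic fits as the oracle)
        per_ind = [fit_conditional_logistic(
            build_design(ModelSpec(mains=("elevation",)), g)).coef("elevation")
            for _, g in df.groupby("individual")]
        assert abs(mx.coef("elevation") - np.mean(per_ind)) < 0.1

    def test_single_individual_rejected(self):
        df = make_choice_strata(seed=23, n_strata=50, n_individuals=1,
                                beta={"elevation": 0.4})
        spec = ModelSpec(mains=("elevation",), random_slopes=("elevation",))
        with pytest.raises(SpecError):
            fit_mixed_issf(build_design(spec, df))

    def test_true_zero_variance_reported_at_boundary(self):
        df = make_choice_strata(seed=24, n_strata=1000, n_individuals=10,
                                beta={"elevation": 0.4})
        spec = ModelSpec(mains=("elevation",), random_slopes=("elevation",))
        mx = fit_mixed_issf(build_design(spec, df))
        assert mx.random_slope_sd["elevation"] < 0.1


class TestWaldInference:
    def test_null_estimate_no_star(self):
        fit = _dummy_fit(beta=[0.0], se=[1.0])
        inf = wald_inference(fit)
        assert inf["p"].iloc[0] == pytest.approx(1.0)
        assert inf["stars"].iloc[0] == ""

    def test_boundary_star_rule(self):
        # |z| = 1.96 -> p = 0.04999... <= 0.05 -> one star
        inf = wald_inference(_dummy_fit(beta=[1.96], se=[1.0]))
        assert inf["p"].iloc[0] == pytest.approx(0.05, abs=1e-4)
        assert inf["stars"].iloc[0] == "*"
        assert star_code(0.05) == "*"
        assert star_code(0.01) == "**"
        assert star_code(0.001) == "***"
        assert star_code(0.050001) == ""

    def test_ci_uses_normal_quantile(self):
        fit = _dummy_fit(beta=[1.0], se=[0.5])
        lo, hi = fit.ci()
        assert lo[0] == pytest.approx(1.0 - 1.959964 * 0.5)
        assert hi[0] == pytest.approx(1.0 + 1.959964 * 0.5)


def _dummy_fit(beta, se):
    from chamois_issf.model import FitResult

    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    return FitResult(terms=tuple(f"x{i}" for i in range(len(beta))),
                     beta=beta, se=se, cov=np.diag(se**2), loglik=0.0,
                     aic=0.0, n_params=len(beta), converged=True,
                     n_strata=1, n_individuals=1, route="test")
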