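"""Integrated step-selection model fits.

The selection model is a conditional logistic regression over strata of one
used and ten available positions.  Three fitting routes are provided:

``fit_conditional_logistic``
    Newton-Raphson on the exact conditional (per-stratum softmax)
    log-likelihood; fixed effects only.  Serves as the analytic oracle.

``fit_poisson_trick``
    The equivalent Poisson reformulation: a per-record Poisson likelihood
    with one intercept per stratum, the intercepts shrunk by a normal
    penalty with variance fixed at a large constant (default 1e6) so they
    are effectively free.  As the variance grows this reproduces the
    conditional-logistic coefficients; the two log-likelihoods differ by an
    additive constant (-N at infinite variance, since each stratum's fitted
    Poisson means sum to one).

``fit_mixed_issf``
    The mixed model: stratum intercepts profiled out exactly (conditional
    likelihood), individual-specific random slopes on habitat terms with a
    diagonal covariance integrated out by a Laplace approximation per
    individual.  Variances are optimized on the log-SD scale (Nelder-Mead)
    with an inner joint Newton over fixed effects and random-effect modes.
    AIC counts fixed effects plus estimated variance components; the fixed
    stratum-intercept variance is not counted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

HABITAT_TERMS = ("elevation", "slope", "tcd", "northness", "eastness")
#: stratum-constant modifiers (weather + day/night); unidentifiable as lone
#: fixed effects in a conditional likelihood
MODIFIER_TERMS = ("temperature", "wind", "precipitation", "snow", "day")

Z_975 = 1.959964


class SpecError(ValueError):
    """Structured rejection of an invalid model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Term list for one season's model.

    Interactions are (modifier, habitat) pairs named ``modifier:habitat``;
    the single habitat-habitat interaction is ``('tcd', 'slope')``.
    """

    season: str = "summer"
    mains: tuple = HABITAT_TERMS
    interactions: tuple = ()
    step_length: bool = True
    random_slopes: tuple = ()
    stratum_variance: float = 1e6

    def __post_init__(self):
        for m in self.mains:
            if m in MODIFIER_TERMS:
                raise SpecError(
                    f"{m!r} is constant within a stratum and unidentifiable "
                    "as a lone fixed effect in a conditional likelihood; "
                    "it may only appear in interactions")
            if m not in HABITAT_TERMS:
                raise SpecError(f"unknown main term {m!r}")
        for mod, hab in self.interactions:
            if hab not in HABITAT_TERMS:
                raise SpecError(f"unknown habitat term {hab!r} in interaction")
            if mod not in MODIFIER_TERMS and (mod, hab) != ("tcd", "slope"):
                raise SpecError(
                    f"invalid interaction {mod}:{hab}; modifiers must be "
                    "stratum-constant except tcd:slope")
        if not set(self.random_slopes) <= set(self.mains):
            raise SpecError("random slopes must be a subset of main terms")

    @property
    def terms(self) -> tuple:
        cols = (["step_length"] if self.step_length else [])
        cols += list(self.mains)
        cols += [f"{m}:{h}" for m, h in self.interactions]
        return tuple(cols)

    def drop(self, term: str) -> "ModelSpec":
        """Spec with one term removed (used by backward selection)."""
        if term == "step_length":
            return ModelSpec(self.season, self.mains, self.interactions,
                             False, self.random_slopes, self.stratum_variance)
        if term in self.mains:
            mains = tuple(m for m in self.mains if m != term)
            rs = tuple(r for r in self.random_slopes if r != term)
            return ModelSpec(self.season, mains, self.interactions, self.step_length,
                             rs, self.stratum_variance)
        inter = tuple((m, h) for m, h in self.interactions if f"{m}:{h}" != term)
        if len(inter) == len(self.interactions):
            raise SpecError(f"term {term!r} not in spec")
        return ModelSpec(self.season, self.mains, inter, self.step_length,
                         self.random_slopes, self.stratum_variance)


def full_model_spec(season: str = "summer", random_slopes: tuple = (),
                    stratum_variance: float = 1e6) -> ModelSpec:
    """The full interaction grammar for a season.

    Interactions with every weather variable and day/night for elevation
    and tree cover; slope interacts with precipitation, wind, snow and
    day/night but not temperature; northness only with temperature;
    eastness with nothing; plus tcd x slope.  Snow terms enter in winter
    only; summer and winter are otherwise identical (19 vs 22 columns).
    """
    weather = ["temperature", "wind", "precipitation"]
    if season == "winter":
        weather.append("snow")
    inter = []
    for mod in weather + ["day"]:
        inter.append((mod, "elevation"))
        if mod != "temperature":
            inter.append((mod, "slope"))
        inter.append((mod, "tcd"))
    inter.append(("temperature", "northness"))
    inter.append(("tcd", "slope"))
    return ModelSpec(season=season, interactions=tuple(inter),
                     random_slopes=random_slopes,
                     stratum_variance=stratum_variance)


# --------------------------------------------------------------------------
# design construction

@dataclass
class Design:
    """Per-record design rows with stratum and individual indices.

    Rows are sorted by (individual, stratum); ``stratum_start`` gives the
    first-row offset of each stratum, ``ind_of_stratum`` the individual
    code of each stratum.
    """

    X: np.ndarray
    terms: tuple
    used: np.ndarray
    stratum_start: np.ndarray
    ind_of_stratum: np.ndarray
    individuals: tuple
    spec: ModelSpec

    @property
    def n_strata(self) -> int:
        return len(self.stratum_start)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def rs_columns(self) -> np.ndarray:
        return np.array([self.terms.index(t) for t in self.spec.random_slopes],
                        dtype=int)


def build_design(spec: ModelSpec, strata: pd.DataFrame) -> Design:
    """Design matrix from standardized strata.

    Interaction columns are elementwise products of the (standardized)
    modifier and habitat columns; the day flag stays on its 0/1 scale.
    """
    df = strata.sort_values(["individual", "stratum_id"], kind="stable")
    cols = {}
    if spec.step_length:
        cols["step_length"] = df["step_length"].to_numpy(dtype=float)
    for m in spec.mains:
        cols[m] = df[m].to_numpy(dtype=float)
    for mod, hab in spec.interactions:
        cols[f"{mod}:{hab}"] = (df[mod].to_numpy(dtype=float)
                                * df[hab].to_numpy(dtype=float))
    X = np.column_stack(list(cols.values()))
    used = df["used"].to_numpy(dtype=float)

    sid = df["stratum_id"].to_numpy()
    change = np.nonzero(np.concatenate([[True], sid[1:] != sid[:-1]]))[0]
    counts = np.diff(np.append(change, len(sid)))
    per_stratum_used = np.add.reduceat(used, change)
    if not np.allclose(per_stratum_used, 1.0):
        raise ValueError("every stratum must contain exactly one used record")

    inds, ind_code = np.unique(df["individual"].to_numpy(), return_inverse=True)
    ind_of_stratum = ind_code[change]
    return Design(X=X, terms=tuple(cols.keys()), used=used,
                  stratum_start=change, ind_of_stratum=ind_of_stratum,
                  individuals=tuple(inds), spec=spec)


# --------------------------------------------------------------------------
# results container

@dataclass
class FitResult:
    terms: tuple
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_strata: int
    n_individuals: int
    route: str
    flags: list = field(default_factory=list)
    random_slope_sd: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def ci(self):
        lo = self.beta - Z_975 * self.se
        hi = self.beta + Z_975 * self.se
        return lo, hi

    def to_json(self, path):
        lo, hi = self.ci()
        payload = {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci_lower": lo.tolist(),
            "ci_upper": hi.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_strata": self.n_strata,
            "n_individuals": self.n_individuals,
            "route": self.route,
            "flags": self.flags,
            "random_slope_sd": self.random_slope_sd,
            "trace": self.trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# conditional logistic (fixed effects)

def _softmax_by_stratum(eta: np.ndarray, start: np.ndarray) -> np.ndarray:
    emax = np.maximum.reduceat(eta, start)
    sizes = np.diff(np.append(start, len(eta)))
    e = np.exp(eta - np.repeat(emax, sizes))
    denom = np.add.reduceat(e, start)
    return e / np.repeat(denom, sizes), emax, denom, sizes


def _cl_loglik_grad_hess(beta, design: Design, hess: bool = True):
    X, y, start = design.X, design.used, design.stratum_start
    eta = X @ beta
    w, emax, denom, sizes = _softmax_by_stratum(eta, start)
    ll = float(eta[y == 1.0].sum() - (np.log(denom) + emax).sum())
    grad = X.T @ (y - w)
    if not hess:
        return ll, grad, None
    Xw = X * w[:, None]
    A = np.add.reduceat(Xw, start, axis=0)  # per-stratum weighted sums
    H = X.T @ Xw - A.T @ A  # observed information (negative Hessian of ll)
    return ll, grad, H


def fit_conditional_logistic(design: Design, max_iter: int = 100,
                             tol_grad: float = 1e-6,
                             tol_ll: float = 1e-9) -> FitResult:
    """Newton-Raphson from beta = 0 on the conditional log-likelihood."""
    p = design.X.shape[1]
    beta = np.zeros(p)
    flags = []
    ll_old = -np.inf
    trace = []
    converged = False
    for it in range(max_iter):
        ll, grad, H = _cl_loglik_grad_hess(beta, design)
        trace.append(ll)
        gnorm = float(np.linalg.norm(grad))
        if np.linalg.norm(beta) > 50.0:
            flags.append("separation")
            break
        rel = abs(ll - ll_old) / (abs(ll) + 1.0)
        # second clause: numerical floor — the loglik no longer moves at
        # double precision and the gradient is small relative to its scale
        if (gnorm < tol_grad and rel < tol_ll) or (rel < 1e-13 and
                                                   gnorm < 1e-3):
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        # step halving
        t = 1.0
        for _ in range(30):
            ll_new, _, _ = _cl_loglik_grad_hess(beta + t * step, design,
                                                hess=False)
            if ll_new >= ll:
                break
            t /= 2.0
        beta = beta + t * step
        ll_old = ll
    ll, grad, H = _cl_loglik_grad_hess(beta, design)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        flags.append("singular_information")
    aic = -2.0 * ll + 2.0 * p
    return FitResult(terms=design.terms, beta=beta, se=se, cov=cov,
                     loglik=ll, aic=aic, n_params=p, converged=converged,
                     n_strata=design.n_strata,
                     n_individuals=design.n_individuals,
                     route="conditional_logistic", flags=flags, trace=trace)


# --------------------------------------------------------------------------
# Poisson trick (fixed effects)

def _profiled_alphas(eta, start, sizes, V):
    """Per-stratum intercepts maximizing the penalized Poisson likelihood.

    Solves 1 - exp(a) * S - a / V = 0 per stratum by Newton, where
    S = sum_j exp(eta_j).
    """
    emax = np.maximum.reduceat(eta, start)
    S = np.add.reduceat(np.exp(eta - np.repeat(emax, sizes)), start)
    logS = np.log(S) + emax
    a = -logS  # exact solution at V = infinity
    for _ in range(50):
        mu_sum = np.exp(a + logS)
        f = 1.0 - mu_sum - a / V
        fp = -mu_sum - 1.0 / V
        da = f / fp
        a = a - da
        if np.max(np.abs(da)) < 1e-12:
            break
    return a, logS


def fit_poisson_trick(design: Design, max_iter: int = 100,
                      tol_grad: float = 1e-6) -> FitResult:
    """Fixed-effects Poisson reformulation with per-stratum intercepts.

    Intercepts carry a normal penalty with variance
    ``spec.stratum_variance`` (default 1e6) and are profiled out inside
    each Newton step for the slopes; the profiled Hessian uses the exact
    Schur complement of the (diagonal) intercept block.
    """
    X, y, start = design.X, design.used, design.stratum_start
    sizes = np.diff(np.append(start, len(y)))
    V = design.spec.stratum_variance
    p = X.shape[1]
    beta = np.zeros(p)
    flags = []
    converged = False

    def objective(beta):
        eta = X @ beta
        a, logS = _profiled_alphas(eta, start, sizes, V)
        mu = np.exp(np.repeat(a, sizes) + eta)
        ll = float((y * (np.repeat(a, sizes) + eta)).sum() - mu.sum()
                   - (a**2).sum() / (2.0 * V))
        return ll, a, mu

    ll_old = -np.inf
    for it in range(max_iter):
        ll, a, mu = objective(beta)
        grad = X.T @ (y - mu)
        gnorm = float(np.linalg.norm(grad))
        rel = abs(ll - ll_old) / (abs(ll) + 1.0)
        if (gnorm < tol_grad and rel < 1e-12) or (rel < 1e-13 and
                                                  gnorm < 1e-3):
            converged = True
            break
        if np.linalg.norm(beta) > 50.0:
            flags.append("separation")
            break
        Xmu = X * mu[:, None]
        H_bb = X.T @ Xmu
        H_ab = np.add.reduceat(Xmu, start, axis=0)      # (n_strata, p)
        H_aa = np.add.reduceat(mu, start) + 1.0 / V     # diagonal
        H = H_bb - H_ab.T @ (H_ab / H_aa[:, None])       # Schur complement
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        t = 1.0
        for _ in range(30):
            ll_new, _, _ = objective(beta + t * step)
            if ll_new >= ll:
                break
            t /= 2.0
        beta = beta + t * step
        ll_old = ll

    ll, a, mu = objective(beta)
    Xmu = X * mu[:, None]
    H_ab = np.add.reduceat(Xmu, start, axis=0)
    H_aa = np.add.reduceat(mu, start) + 1.0 / V
    H = X.T @ Xmu - H_ab.T @ (H_ab / H_aa[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        flags.append("singular_information")
    aic = -2.0 * ll + 2.0 * p
    return FitResult(terms=design.terms, beta=beta, se=se, cov=cov,
                     loglik=ll, aic=aic, n_params=p, converged=converged,
                     n_strata=design.n_strata,
                     n_individuals=design.n_individuals,
                     route="poisson_trick", flags=flags)


# --------------------------------------------------------------------------
# mixed model: conditional likelihood + individual random slopes (Laplace)

def _mixed_joint_newton(design: Design, rs_cols, D_inv, beta0, b0,
                        max_iter=50, tol=1e-9):
    """Joint penalized mode over (beta, b), Newton with step halving.

    b is (n_ind, k); penalty 0.5 * sum_i b_i' D^-1 b_i with D diagonal.
    Returns beta, b, penalized loglik, per-individual penalized Hessian
    blocks H_i (k x k) and the full joint Hessian (for SEs).
    """
    X, y, start = design.X, design.used, design.stratum_start
    sizes = np.diff(np.append(start, len(y)))
    ind_of_row = np.repeat(design.ind_of_stratum, sizes)
    n_ind = design.n_individuals
    k = len(rs_cols)
    p = X.shape[1]
    Xr = X[:, rs_cols]

    def eta_of(beta, b):
        return X @ beta + np.einsum("ij,ij->i", Xr, b[ind_of_row])

    def pen_ll(beta, b):
        eta = eta_of(beta, b)
        w, emax, denom, _ = _softmax_by_stratum(eta, start)
        ll = float(eta[y == 1.0].sum() - (np.log(denom) + emax).sum())
        pen = 0.5 * float((b * b * D_inv[None, :]).sum())
        return ll - pen, w

    beta = beta0.copy()
    b = b0.copy()
    ll_old = -np.inf
    for it in range(max_iter):
        ll, w = pen_ll(beta, b)
        resid = y - w
        grad_beta = X.T @ resid
        grad_b = np.zeros((n_ind, k))
        np.add.at(grad_b, ind_of_row, Xr * resid[:, None])
        grad_b -= b * D_inv[None, :]
        grad = np.concatenate([grad_beta, grad_b.ravel()])
        if np.linalg.norm(grad) < 1e-7 and abs(ll - ll_old) / (abs(ll) + 1) < tol:
            break
        # Hessian blocks: information = X'WX - A'A per block
        Xw = X * w[:, None]
        Xrw = Xr * w[:, None]
        A = np.add.reduceat(Xw, start, axis=0)       # (S, p)
        Ar = np.add.reduceat(Xrw, start, axis=0)     # (S, k)
        H = np.zeros((p + n_ind * k, p + n_ind * k))
        H[:p, :p] = X.T @ Xw - A.T @ A
        for i in range(n_ind):
            rows = ind_of_row == i
            srows = design.ind_of_stratum == i
            Hbb = Xr[rows].T @ Xrw[rows] - Ar[srows].T @ Ar[srows]
            Hcb = X[rows].T @ Xrw[rows] - A[srows].T @ Ar[srows]
            sl = slice(p + i * k, p + (i + 1) * k)
            H[sl, sl] = Hbb + np.diag(D_inv)
            H[:p, sl] = Hcb
            H[sl, :p] = Hcb.T
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H += 1e-8 * np.eye(H.shape[0])
            step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            ll_new, _ = pen_ll(beta + t * step[:p],
                               b + t * step[p:].reshape(n_ind, k))
            if ll_new >= ll:
                break
            t /= 2.0
        beta = beta + t * step[:p]
        b = b + t * step[p:].reshape(n_ind, k)
        ll_old = ll

    # final penalized Hessian blocks for the Laplace determinant
    ll, w = pen_ll(beta, b)
    Xw = X * w[:, None]
    Xrw = Xr * w[:, None]
    A = np.add.reduceat(Xw, start, axis=0)
    Ar = np.add.reduceat(Xrw, start, axis=0)
    H_blocks = []
    H = np.zeros((p + n_ind * k, p + n_ind * k))
    H[:p, :p] = X.T @ Xw - A.T @ A
    for i in range(n_ind):
        rows = ind_of_row == i
        srows = design.ind_of_stratum == i
        Hi = Xr[rows].T @ Xrw[rows] - Ar[srows].T @ Ar[srows] + np.diag(D_inv)
        H_blocks.append(Hi)
        Hcb = X[rows].T @ Xrw[rows] - A[srows].T @ Ar[srows]
        sl = slice(p + i * k, p + (i + 1) * k)
        H[sl, sl] = Hi
        H[:p, sl] = Hcb
        H[sl, :p] = Hcb.T
    return beta, b, ll, H_blocks, H


def fit_mixed_issf(design: Design, theta_fixed=None,
                   log_sd_bounds=(-6.0, 2.0)) -> FitResult:
    """Mixed iSSF: conditional likelihood + Laplace random slopes.

    Stratum intercepts are profiled out exactly, which is the limit of the
    Poisson-trick formulation as the fixed intercept variance grows.
    Random-slope SDs (``spec.random_slopes``, diagonal covariance) are
    estimated on the log scale unless ``theta_fixed`` (array of SDs) is
    given.  A variance landing on the lower bound is reported via the
    ``'variance_boundary'`` flag, not an error.
    """
    spec = design.spec
    rs_cols = design.rs_columns()
    k = len(rs_cols)
    if k == 0:
        raise SpecError("no random slopes requested; use the fixed-effects fits")
    if design.n_individuals < 2:
        raise SpecError("random slopes require at least 2 individuals")
    p = design.X.shape[1]
    n_ind = design.n_individuals
    flags = []

    state = {"beta": np.zeros(p), "b": np.zeros((n_ind, k))}

    def neg_laplace(log_sd):
        log_sd = np.clip(log_sd, log_sd_bounds[0], log_sd_bounds[1])
        sd = np.exp(log_sd)
        D_inv = 1.0 / sd**2
        beta, b, pll, H_blocks, _ = _mixed_joint_newton(
            design, rs_cols, D_inv, state["beta"], state["b"])
        state["beta"], state["b"] = beta, b
        logdet = sum(np.linalg.slogdet(Hi)[1] for Hi in H_blocks)
        # l_marg = pen_ll(mode) - 0.5*logdet(Hpen) - 0.5*logdet(D) per ind.
        lmarg = pll - 0.5 * logdet - n_ind * float(np.sum(np.log(sd**2))) / 2.0
        return -lmarg

    if theta_fixed is not None:
        log_sd = np.log(np.asarray(theta_fixed, dtype=float))
        nll = neg_laplace(log_sd)
        converged = True
    else:
        x0 = np.full(k, np.log(0.3))
        res = optimize.minimize(neg_laplace, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7,
                                         "maxiter": 400})
        log_sd = np.clip(res.x, log_sd_bounds[0], log_sd_bounds[1])
        nll = neg_laplace(log_sd)
        converged = bool(res.success)
        if np.any(log_sd <= log_sd_bounds[0] + 1e-6):
            flags.append("variance_boundary")

    sd = np.exp(log_sd)
    D_inv = 1.0 / sd**2
    beta, b, pll, H_blocks, H_joint = _mixed_joint_newton(
        design, rs_cols, D_inv, state["beta"], state["b"])
    try:
        cov_joint = np.linalg.inv(H_joint)
        cov = cov_joint[:p, :p]
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        flags.append("singular_information")

    lmarg = -nll
    n_var = 0 if theta_fixed is not None else k
    n_params = p + n_var
    aic = -2.0 * lmarg + 2.0 * n_params
    rs_sd = {spec.random_slopes[j]: float(sd[j]) for j in range(k)}
    return FitResult(terms=design.terms, beta=beta, se=se, cov=cov,
                     loglik=lmarg, aic=aic, n_params=n_params,
                     converged=converged, n_strata=design.n_strata,
                     n_individuals=design.n_individuals,
                     route="conditional_logistic_laplace",
                     flags=flags, random_slope_sd=rs_sd)


# --------------------------------------------------------------------------
# inference table

def star_code(p: float) -> str:
    """Significance stars at p <= 0.05 / 0.01 / 0.001 (boundary inclusive)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def wald_inference(fit: FitResult) -> pd.DataFrame:
    """Two-sided normal Wald tests and 95 % CIs per term."""
    if not fit.converged:
        warnings.warn("Wald inference on a non-converged fit")
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = fit.beta / fit.se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    lo, hi = fit.ci()
    return pd.DataFrame({
        "term": fit.terms,
        "estimate": fit.beta,
        "se": fit.se,
        "ci_lower": lo,
        "ci_upper": hi,
        "z": zval,
        "p": pval,
        "stars": [star_code(p) for p in pval],
    })
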