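"""Mixed-model and effect-size statistics for binomial McGurk counts.

The centerpiece is a maximum-likelihood binomial GLMM (logit link) with
crossed Gaussian random intercepts for participant and stimulus, estimated
with a Laplace approximation of the marginal likelihood -- the same
estimator (profiled Laplace, one quadrature point) used by lme4's glmer
default. Model selection uses BIC with n equal to the number of binomial
count records; a BIC difference of 10 or more is treated as decisive in
favor of the lower-BIC model, with exp(dBIC/2) as the approximate
evidence ratio.

Also provided: odds-ratio arithmetic on proportions, population-average
(marginalized) prevalence via Gauss-Hermite quadrature over the fitted
random-effect distributions, binomial variance n*p*q, a Gaussian linear
mixed model for per-record binomial variances (ML, not REML, so that
fixed-effect BIC comparisons are valid), and paired/independent t-tests.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

class ConvergenceWarning(UserWarning):
    """Estimation finished but the estimates may be unstable."""


__all__ = [
    "ConvergenceWarning",
    "FixedTerm",
    "GLMMSpec",
    "GLMMFit",
    "ModelComparison",
    "VarianceLMMFit",
    "TTestResult",
    "fit_glmm",
    "compare_models",
    "odds_ratio",
    "apply_odds_ratio",
    "marginal_expit",
    "marginal_prevalence",
    "binomial_variance",
    "fit_variance_lmm",
    "paired_t_test",
    "independent_t_test",
]


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedTerm:
    """One fixed-effect covariate: a column name and its coding."""

    name: str
    categorical: bool = True


@dataclass(frozen=True)
class GLMMSpec:
    """Binomial GLMM specification.

    ``fixed`` lists covariates beyond the intercept (categorical terms use
    treatment coding with the first sorted level as reference); ``random``
    names the columns whose levels receive Gaussian random intercepts;
    ``response`` is (successes column, totals column).
    """

    fixed: tuple[FixedTerm, ...] = ()
    random: tuple[str, ...] = ("participant_id", "stimulus_id")
    response: tuple[str, str] = ("n_da_tha", "n_trials")

    def __post_init__(self) -> None:
        if len(self.random) == 0:
            raise ValueError("at least one random-intercept factor is required")

    def to_dict(self) -> dict:
        return {
            "fixed": [{"name": t.name, "categorical": t.categorical} for t in self.fixed],
            "random": list(self.random),
            "response": list(self.response),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GLMMSpec":
        fixed = tuple(
            FixedTerm(str(t["name"]), bool(t.get("categorical", True)))
            for t in d.get("fixed", ())
        )
        return cls(
            fixed=fixed,
            random=tuple(d.get("random", ("participant_id", "stimulus_id"))),
            response=tuple(d.get("response", ("n_da_tha", "n_trials"))),
        )


def _build_design(df: pd.DataFrame, spec: GLMMSpec):
    """Design matrix with intercept; returns (X, names, term level map)."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    levels: dict[str, list[str] | None] = {}
    for term in spec.fixed:
        if term.name not in df.columns:
            raise ValueError(f"fixed term {term.name!r} is not a column of the trial table")
        if term.categorical:
            x = df[term.name].astype(str)
            levs = sorted(x.unique())
            if len(levs) < 2:
                raise ValueError(f"categorical term {term.name!r} has a single level")
            levels[term.name] = levs
            for lev in levs[1:]:
                cols.append((x == lev).to_numpy(dtype=float))
                names.append(f"{term.name}[{lev}]")
        else:
            levels[term.name] = None
            cols.append(pd.to_numeric(df[term.name]).to_numpy(dtype=float))
            names.append(term.name)
    return np.column_stack(cols), names, levels


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    """Fitted binomial GLMM: logit-scale estimates and information criteria."""

    coefficients: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    variance_components: dict[str, float]
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    converged: bool
    singular: bool
    message: str
    spec: GLMMSpec
    term_levels: dict[str, list[str] | None] = field(default_factory=dict)
    random_modes: dict[str, dict[str, float]] = field(default_factory=dict)

    def wald_z(self) -> dict[str, float]:
        return {k: self.coefficients[k] / self.se[k] for k in self.coefficients}

    def p_values(self) -> dict[str, float]:
        return {k: 2.0 * scipy.stats.norm.sf(abs(z)) for k, z in self.wald_z().items()}

    def summary(self) -> str:
        lines = [
            f"binomial GLMM (logit link), Laplace ML; n_obs={self.n_obs}, "
            f"n_params={self.n_params}",
            f"logLik={self.loglik:.3f}  BIC={self.bic:.3f}",
        ]
        z, p = self.wald_z(), self.p_values()
        for name, est in self.coefficients.items():
            lines.append(
                f"  {name:<24s} {est:+.4f} (SE {self.se[name]:.4f}, z={z[name]:+.2f}, "
                f"p={p[name]:.3g}, OR={math.exp(est):.3f})"
            )
        for factor, var in self.variance_components.items():
            lines.append(f"  var({factor}) = {var:.4f}  (sd {math.sqrt(max(var, 0)):.4f})")
        if self.singular:
            lines.append("  note: singular fit (a variance component is ~0)")
        if not self.converged:
            lines.append(f"  warning: optimizer did not report convergence ({self.message})")
        return "\n".join(lines)


@dataclass(frozen=True)
class ModelComparison:
    """BIC comparison of two fits of the same data."""

    bic_baseline: float
    bic_alternative: float
    delta_bic: float
    preferred: str  # "baseline" | "alternative"
    decisive: bool
    approx_evidence_ratio: float


TTestResult = namedtuple("TTestResult", ["statistic", "df", "pvalue"])


@dataclass
class VarianceLMMFit:
    """Gaussian LMM (ML) for per-record binomial variances."""

    coefficients: dict[str, float]
    se: dict[str, float]
    variance_components: dict[str, float]
    resid_variance: float
    loglik: float
    n_obs: int
    n_params: int
    bic: float
    converged: bool
    includes_slope: bool

    @property
    def slope(self) -> float | None:
        return self.coefficients.get("n_repetitions")

    @property
    def slope_se(self) -> float | None:
        return self.se.get("n_repetitions")


# ---------------------------------------------------------------------------
# binomial GLMM with crossed random intercepts (profiled Laplace ML)
# ---------------------------------------------------------------------------

class _LaplaceGLMM:
    """Workhorse for the Laplace-approximate marginal likelihood.

    The random-effect vector is integrated out with a Laplace
    approximation around its conditional mode (inner Newton), and the
    outer bounded quasi-Newton optimization runs over the fixed effects
    together with the log random-effect standard deviations -- the same
    scheme as glmer's nAGQ=1 default, where the fixed effects see the
    full Laplace objective including the log-determinant term.
    """

    def __init__(self, X: np.ndarray, Z: np.ndarray, factor_sizes: list[int],
                 k: np.ndarray, n: np.ndarray):
        self.X, self.Z = X, Z
        self.factor_sizes = factor_sizes
        self.k, self.n = k, n
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.binom_const = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
        self.b = np.zeros(self.q)  # warm start across outer evaluations

    def _dvec(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [np.full(sz, math.exp(2.0 * th)) for sz, th in zip(self.factor_sizes, theta)]
        )

    def _pen_loglik(self, eta0: np.ndarray, b: np.ndarray, dvec: np.ndarray) -> float:
        eta = eta0 + self.Z @ b
        return float(self.k @ eta - self.n @ np.logaddexp(0.0, eta) - 0.5 * np.sum(b * b / dvec))

    def mode(self, beta: np.ndarray, dvec: np.ndarray, max_iter: int = 200):
        """Newton ascent for the conditional mode of the random effects."""
        eta0 = self.X @ beta
        b = self.b.copy()
        f = self._pen_loglik(eta0, b, dvec)
        for _ in range(max_iter):
            eta = eta0 + self.Z @ b
            mu = expit(eta)
            w = self.n * mu * (1.0 - mu) + 1e-12
            g = self.Z.T @ (self.k - self.n * mu) - b / dvec
            h = (self.Z.T * w) @ self.Z
            h[np.diag_indices_from(h)] += 1.0 / dvec
            try:
                step = cho_solve(cho_factor(h, lower=True), g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h, g, rcond=None)[0]
            t = 1.0
            cand, fc = b + step, self._pen_loglik(eta0, b + step, dvec)
            while fc < f and t > 1e-8:
                t *= 0.5
                cand = b + t * step
                fc = self._pen_loglik(eta0, cand, dvec)
            improved = fc - f
            moved = float(np.max(np.abs(cand - b)))
            b, f = cand, fc
            if improved < 1e-12 * (1.0 + abs(f)) and moved < 1e-8:
                break
        self.b = b.copy()
        eta = eta0 + self.Z @ b
        mu = expit(eta)
        w = self.n * mu * (1.0 - mu) + 1e-12
        return b, f, w

    def laplace_loglik(self, beta: np.ndarray, theta: np.ndarray):
        dvec = self._dvec(theta)
        b, f_pen, w = self.mode(beta, dvec)
        m = (self.Z.T * w) @ self.Z
        sd = np.sqrt(dvec)
        kmat = np.eye(self.q) + (sd[:, None] * m) * sd[None, :]
        try:
            logdet = 2.0 * float(np.sum(np.log(np.diag(np.linalg.cholesky(kmat)))))
        except np.linalg.LinAlgError:
            sign, logdet = np.linalg.slogdet(kmat)
            if sign <= 0:
                logdet = np.inf
        ll = f_pen - 0.5 * logdet + self.binom_const
        return ll, b, w


def _fit_plain_glm(X: np.ndarray, k: np.ndarray, n: np.ndarray):
    """Newton ML logistic regression on count data (no random effects)."""
    p = X.shape[1]
    beta = np.zeros(p)

    def ll(b):
        eta = X @ b
        return float(k @ eta - n @ np.logaddexp(0.0, eta))

    f = ll(beta)
    for _ in range(200):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1.0 - mu) + 1e-12
        g = X.T @ (k - n * mu)
        h = (X.T * w) @ X
        step = np.linalg.solve(h, g)
        t, cand, fc = 1.0, beta + step, ll(beta + step)
        while fc < f and t > 1e-10:
            t *= 0.5
            cand = beta + t * step
            fc = ll(cand)
        improved = fc - f
        beta, f = cand, fc
        if improved < 1e-12 * (1.0 + abs(f)):
            break
    eta = X @ beta
    mu = expit(eta)
    w = n * mu * (1.0 - mu) + 1e-12
    vcov = np.linalg.inv((X.T * w) @ X)
    const = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    return beta, vcov, f + const


def _agq_loglik(X, groups, n_groups, k, n, beta, log_sd, nodes, weights) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, single random factor."""
    var = math.exp(2.0 * log_sd)
    eta0 = X @ beta
    total = 0.0
    for g in range(n_groups):
        idx = groups == g
        e0, kk, nn = eta0[idx], k[idx], n[idx]

        def l(b):
            eta = e0 + b
            return float(kk @ eta - nn @ np.logaddexp(0.0, eta)) - 0.5 * b * b / var

        # 1-D Newton for the conditional mode
        b = 0.0
        for _ in range(50):
            mu = expit(e0 + b)
            g1 = float(np.sum(kk - nn * mu)) - b / var
            g2 = -float(np.sum(nn * mu * (1 - mu))) - 1.0 / var
            step = -g1 / g2
            b_new = b + step
            if abs(step) < 1e-12:
                b = b_new
                break
            b = b_new
        mu = expit(e0 + b)
        h = float(np.sum(nn * mu * (1 - mu))) + 1.0 / var
        sd_hat = 1.0 / math.sqrt(h)
        pts = b + math.sqrt(2.0) * sd_hat * nodes
        vals = np.array([l(pt) for pt in pts]) + nodes**2
        m = vals.max()
        integral = math.sqrt(2.0) * sd_hat * float(np.sum(weights * np.exp(vals - m)))
        total += m + math.log(integral) - 0.5 * math.log(2.0 * math.pi * var)
    const = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    return total + const


def fit_glmm(
    trials: pd.DataFrame,
    spec: GLMMSpec,
    fix_variance: Mapping[str, float] | None = None,
    n_agq: int = 1,
) -> GLMMFit:
    """Fit a binomial GLMM with crossed Gaussian random intercepts by ML.

    Parameters
    ----------
    trials
        Trial table containing the response, fixed-term and random-factor
        columns (rows not belonging to the analysis must be filtered out
        by the caller).
    spec
        Model specification.
    fix_variance
        Optional mapping factor -> 0.0 pinning that factor's variance at
        zero (the factor is dropped from the random structure); pinning
        all factors reduces the fit to ordinary logistic regression.
    n_agq
        Number of adaptive Gauss-Hermite quadrature nodes. The default 1
        is the Laplace approximation; values > 1 are supported only for a
        single (non-pinned) random factor, as in lme4.

    Notes
    -----
    Deterministic: fixed starting values (coefficients 0, variances 1) and
    a bounded quasi-Newton outer optimization on log standard deviations
    with objective tolerance 1e-8. Complete separation is reported via a
    ConvergenceWarning with finite-but-unstable estimates; a variance
    component shrinking to ~0 is reported as a singular fit, not an error.
    """
    succ_col, tot_col = spec.response
    for col in (succ_col, tot_col, *spec.random):
        if col not in trials.columns:
            raise ValueError(f"trial table is missing required column {col!r}")
    k = np.asarray(trials[succ_col], dtype=float)
    n = np.asarray(trials[tot_col], dtype=float)
    if np.any(n <= 0) or np.any(k < 0) or np.any(k > n):
        raise ValueError("invalid binomial counts (need 0 <= successes <= totals, totals > 0)")
    X, names, term_levels = _build_design(trials, spec)

    fix_variance = dict(fix_variance or {})
    for factor, val in fix_variance.items():
        if factor not in spec.random:
            raise ValueError(f"cannot fix variance of unknown factor {factor!r}")
        if val != 0.0:
            raise ValueError("only fixing a variance at exactly 0 is supported")
    free_factors = [f for f in spec.random if f not in fix_variance]

    factor_codes, factor_levels = [], []
    for f in free_factors:
        codes, levels = pd.factorize(trials[f].astype(str), sort=True)
        if len(levels) < 2:
            raise ValueError(f"random factor {f!r} must have at least 2 levels")
        factor_codes.append(codes)
        factor_levels.append(list(levels))

    n_obs = len(trials)

    if not free_factors:
        beta, vcov, ll = _fit_plain_glm(X, k, n)
        n_params = X.shape[1]
        fit = GLMMFit(
            coefficients=dict(zip(names, beta)),
            se=dict(zip(names, np.sqrt(np.diag(vcov)))),
            vcov=vcov,
            variance_components={f: 0.0 for f in spec.random},
            loglik=ll,
            n_obs=n_obs,
            n_params=n_params,
            bic=n_params * math.log(n_obs) - 2.0 * ll,
            converged=True,
            singular=False,
            message="plain GLM (all variance components fixed at 0)",
            spec=spec,
            term_levels=term_levels,
        )
        _warn_if_separated(fit)
        return fit

    if n_agq > 1:
        if len(free_factors) != 1:
            raise ValueError("n_agq > 1 requires exactly one (non-pinned) random factor")
        return _fit_agq(
            trials, spec, X, names, term_levels, factor_codes[0],
            factor_levels[0], free_factors[0], fix_variance, k, n, n_agq,
        )

    # dense indicator matrix for the random intercepts
    sizes = [len(lv) for lv in factor_levels]
    Z = np.zeros((n_obs, sum(sizes)))
    offset = 0
    for codes, sz in zip(factor_codes, sizes):
        Z[np.arange(n_obs), offset + codes] = 1.0
        offset += sz

    core = _LaplaceGLMM(X, Z, sizes, k, n)
    p = X.shape[1]
    m = len(free_factors)

    def negll(par: np.ndarray) -> float:
        ll, _, _ = core.laplace_loglik(par[:p], par[p:])
        return -ll

    # finite-difference step well above the inner solver's path noise
    res = minimize(
        negll,
        x0=np.zeros(p + m),
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(-8.0, 4.0)] * m,
        options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 1000, "eps": 1e-5},
    )
    beta, theta = res.x[:p], res.x[p:]
    ll, b, w = core.laplace_loglik(beta, theta)
    dvec = core._dvec(theta)

    # Wald covariance of the fixed effects: Schur complement of the joint
    # penalized Hessian at the mode, conditional on the estimated variances
    # (the same conditioning glmer uses).
    hxx = (X.T * w) @ X
    hxz = (X.T * w) @ Z
    hzz = (Z.T * w) @ Z
    hzz[np.diag_indices_from(hzz)] += 1.0 / dvec
    vcov = np.linalg.inv(hxx - hxz @ np.linalg.solve(hzz, hxz.T))

    sds = np.exp(theta)
    variance_components = {f: 0.0 for f in fix_variance}
    variance_components.update({f: float(s**2) for f, s in zip(free_factors, sds)})
    singular = bool(np.any(sds < 1e-3))

    random_modes: dict[str, dict[str, float]] = {}
    offset = 0
    for f, levels, sz in zip(free_factors, factor_levels, sizes):
        random_modes[f] = dict(zip(levels, b[offset:offset + sz].astype(float)))
        offset += sz

    n_params = p + m
    fit = GLMMFit(
        coefficients=dict(zip(names, beta)),
        se=dict(zip(names, np.sqrt(np.diag(vcov)))),
        vcov=vcov,
        variance_components=variance_components,
        loglik=float(ll),
        n_obs=n_obs,
        n_params=n_params,
        bic=n_params * math.log(n_obs) - 2.0 * float(ll),
        converged=bool(res.success),
        singular=singular,
        message=str(res.message),
        spec=spec,
        term_levels=term_levels,
        random_modes=random_modes,
    )
    _warn_if_separated(fit)
    return fit


def _warn_if_separated(fit: GLMMFit) -> None:
    if any(abs(v) > 12.0 for v in fit.coefficients.values()) or any(
        s > 50.0 for s in fit.se.values()
    ):
        warnings.warn(
            "possible complete separation: some estimates are finite but unstable",
            ConvergenceWarning,
            stacklevel=3,
        )


def _fit_agq(trials, spec, X, names, term_levels, codes, levels, factor,
             fix_variance, k, n, n_agq) -> GLMMFit:
    """Adaptive Gauss-Hermite ML for a single random factor."""
    nodes, weights = hermgauss(n_agq)
    p = X.shape[1]
    n_groups = len(levels)

    def negll(par):
        return -_agq_loglik(X, codes, n_groups, k, n, par[:p], par[p], nodes, weights)

    res = minimize(
        negll,
        x0=np.concatenate([np.zeros(p), [0.0]]),
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(-8.0, 4.0)],
        options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500},
    )
    beta, log_sd = res.x[:p], res.x[p]
    # numeric observed information for the fixed effects
    eps = 1e-4
    hess = np.zeros((p, p))
    f0 = negll(res.x)

    def f_beta(bv):
        return negll(np.concatenate([bv, [log_sd]]))

    for i in range(p):
        for j in range(i, p):
            bi = beta.copy(); bi[i] += eps; bi[j] += eps
            bj = beta.copy(); bj[i] += eps; bj[j] -= eps
            bk = beta.copy(); bk[i] -= eps; bk[j] += eps
            bl = beta.copy(); bl[i] -= eps; bl[j] -= eps
            hess[i, j] = hess[j, i] = (
                f_beta(bi) - f_beta(bj) - f_beta(bk) + f_beta(bl)
            ) / (4 * eps * eps)
    vcov = np.linalg.inv(hess)
    ll = -f0
    n_obs = len(trials)
    variance_components = {f: 0.0 for f in fix_variance}
    variance_components[factor] = float(math.exp(2.0 * log_sd))
    n_params = p + 1
    fit = GLMMFit(
        coefficients=dict(zip(names, beta)),
        se=dict(zip(names, np.sqrt(np.abs(np.diag(vcov))))),
        vcov=vcov,
        variance_components=variance_components,
        loglik=float(ll),
        n_obs=n_obs,
        n_params=n_params,
        bic=n_params * math.log(n_obs) - 2.0 * float(ll),
        converged=bool(res.success),
        singular=bool(math.exp(log_sd) < 1e-3),
        message=str(res.message),
        spec=spec,
        term_levels=term_levels,
    )
    _warn_if_separated(fit)
    return fit


# ---------------------------------------------------------------------------
# model comparison and odds-ratio arithmetic
# ---------------------------------------------------------------------------

def compare_models(fit_baseline, fit_alt) -> ModelComparison:
    """BIC comparison; both fits must be on identical data (same n_obs)."""
    if fit_baseline.n_obs != fit_alt.n_obs:
        raise ValueError(
            f"fits are not on the same data (n_obs {fit_baseline.n_obs} vs {fit_alt.n_obs})"
        )
    delta = abs(fit_baseline.bic - fit_alt.bic)
    preferred = "baseline" if fit_baseline.bic <= fit_alt.bic else "alternative"
    return ModelComparison(
        bic_baseline=float(fit_baseline.bic),
        bic_alternative=float(fit_alt.bic),
        delta_bic=float(delta),
        preferred=preferred,
        decisive=bool(delta >= 10.0),
        approx_evidence_ratio=float(math.exp(min(delta / 2.0, 700.0))),
    )


def odds_ratio(p_from: float, p_to: float) -> float:
    """Odds ratio between two proportions: odds(p_to) / odds(p_from)."""
    for name, p in (("p_from", p_from), ("p_to", p_to)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    return (p_to / (1.0 - p_to)) / (p_from / (1.0 - p_from))


def apply_odds_ratio(p_base: float, or_value: float) -> float:
    """Shift a proportion by an odds ratio: expit(logit(p) + ln(OR))."""
    if not (0.0 < p_base < 1.0):
        raise ValueError("p_base must lie strictly in (0, 1)")
    if not (or_value > 0.0 and math.isfinite(or_value)):
        raise ValueError("or_value must be a positive finite real")
    return float(expit(logit(p_base) + math.log(or_value)))


def binomial_variance(n_trials: int, p: float) -> float:
    """Variance of a Binomial(n, p) count: n * p * (1 - p)."""
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    return float(n_trials) * p * (1.0 - p)


# ---------------------------------------------------------------------------
# marginal (population-average) prevalence
# ---------------------------------------------------------------------------

def marginal_expit(lp: float, variances: Sequence[float], n_nodes: int = 20) -> float:
    """E[expit(lp + sum_r u_r)] with u_r ~ N(0, var_r), by Gauss-Hermite.

    Exact (equal to expit(lp)) when all variances are zero.
    """
    variances = [v for v in variances if v > 0]
    if any(v < 0 for v in variances):
        raise ValueError("variances must be nonnegative")
    if not variances:
        return float(expit(lp))
    nodes, weights = hermgauss(n_nodes)
    total = np.array([lp])
    wts = np.array([1.0])
    for v in variances:
        shift = math.sqrt(2.0 * v) * nodes
        total = (total[:, None] + shift[None, :]).ravel()
        wts = (wts[:, None] * (weights / math.sqrt(math.pi))[None, :]).ravel()
    return float(np.sum(wts * expit(total)))


def _linear_predictor(fit: GLMMFit, covariates: Mapping[str, object]) -> float:
    lp = fit.coefficients["intercept"]
    for term in fit.spec.fixed:
        if term.name not in covariates:
            raise ValueError(f"covariates must include a value for {term.name!r}")
        value = covariates[term.name]
        if term.categorical:
            levels = fit.term_levels[term.name]
            lev = str(value)
            if lev not in levels:
                raise ValueError(f"{lev!r} is not a level of {term.name!r} ({levels})")
            if lev != levels[0]:
                lp += fit.coefficients[f"{term.name}[{lev}]"]
        else:
            lp += fit.coefficients[term.name] * float(value)
    return float(lp)


def marginal_prevalence(
    fit: GLMMFit, covariates: Mapping[str, object] | None = None, n_nodes: int = 20
) -> float:
    """Population-average response probability at given covariate values.

    Integrates expit(linear predictor + random intercepts) over the fitted
    Gaussian random-effect distributions with ``n_nodes`` Gauss-Hermite
    nodes per factor; equals the conditional expit exactly when all
    variance components are zero.
    """
    lp = _linear_predictor(fit, covariates or {})
    return marginal_expit(lp, list(fit.variance_components.values()), n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# Gaussian LMM on binomial variances (repetition precision analysis)
# ---------------------------------------------------------------------------

def fit_variance_lmm(
    trials: pd.DataFrame,
    include_repetition_slope: bool,
    repetition_column: str = "condition",
    fix_variance_zero: bool = False,
) -> VarianceLMMFit:
    """Linear mixed model for per-record binomial variances (ML).

    The response is n * p * q per record (p the observed "da/tha"
    proportion); the model has random intercepts for participant and
    stimulus and optionally a linear fixed term in the number of
    repetitions (parsed from ``repetition_column``). Maximum likelihood
    (not REML) is used so BICs of models differing in fixed effects are
    comparable. ``fix_variance_zero`` pins both random variances at zero,
    reducing the fit to ordinary least squares.
    """
    df = trials.copy()
    p_hat = df["n_da_tha"] / df["n_trials"]
    df["_binom_var"] = df["n_trials"] * p_hat * (1.0 - p_hat)
    df["_rep"] = pd.to_numeric(df[repetition_column], errors="raise").astype(float)
    n_obs = len(df)

    names = ["intercept"] + (["n_repetitions"] if include_repetition_slope else [])
    if fix_variance_zero:
        Xcols = [np.ones(n_obs)]
        if include_repetition_slope:
            Xcols.append(df["_rep"].to_numpy())
        X = np.column_stack(Xcols)
        res = sm.OLS(df["_binom_var"].to_numpy(), X).fit()
        coefs = dict(zip(names, res.params))
        ses = dict(zip(names, res.bse))
        ll = float(res.llf)
        n_params = len(names) + 1  # + residual variance
        return VarianceLMMFit(
            coefficients=coefs,
            se=ses,
            variance_components={"participant_id": 0.0, "stimulus_id": 0.0},
            resid_variance=float(res.scale),
            loglik=ll,
            n_obs=n_obs,
            n_params=n_params,
            bic=n_params * math.log(n_obs) - 2.0 * ll,
            converged=True,
            includes_slope=include_repetition_slope,
        )

    df["_all"] = 1
    formula = "_binom_var ~ _rep" if include_repetition_slope else "_binom_var ~ 1"
    vc = {
        "participant": "0 + C(participant_id)",
        "stimulus": "0 + C(stimulus_id)",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            formula, groups="_all", vc_formula=vc, re_formula="0", data=df
        )
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
    params = dict(res.fe_params)
    bse = dict(res.bse_fe)
    coefs = {"intercept": float(params.get("Intercept", 0.0))}
    ses = {"intercept": float(bse.get("Intercept", np.nan))}
    if include_repetition_slope:
        coefs["n_repetitions"] = float(params["_rep"])
        ses["n_repetitions"] = float(bse["_rep"])
    vcomp = {
        "participant_id": float(res.vcomp[0]),
        "stimulus_id": float(res.vcomp[1]),
    }
    ll = float(res.llf)
    n_params = len(coefs) + 2 + 1  # fixed + two variance components + residual
    return VarianceLMMFit(
        coefficients=coefs,
        se=ses,
        variance_components=vcomp,
        resid_variance=float(res.scale),
        loglik=ll,
        n_obs=n_obs,
        n_params=n_params,
        bic=n_params * math.log(n_obs) - 2.0 * ll,
        converged=bool(getattr(res, "converged", True)),
        includes_slope=include_repetition_slope,
    )


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def paired_t_test(a, b) -> TTestResult:
    """Paired t-test; df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test requires two equal-length vectors of length >= 2")
    d = a - b
    if d.std(ddof=1) == 0.0:
        # degenerate case: a constant difference; zero difference gives t = 0
        t = 0.0 if d.mean() == 0.0 else math.copysign(math.inf, d.mean())
        return TTestResult(t, float(len(a) - 1), 1.0 if t == 0.0 else 0.0)
    res = scipy.stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(len(a) - 1), float(res.pvalue))


def independent_t_test(a, b, pooled: bool = True) -> TTestResult:
    """Two-sample t-test; pooled df = n1 + n2 - 2, else Welch-Satterthwaite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("independent t-test requires two vectors of length >= 2")
    res = scipy.stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = float(len(a) + len(b) - 2)
    else:
        df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue))
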