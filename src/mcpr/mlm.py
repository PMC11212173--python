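"""Random-intercept binary logistic regression, fitted by maximum
marginal likelihood with adaptive Gauss-Hermite quadrature.

The model for woman i in district (cluster) j is

    logit P(y_ij = 1) = x_ij' beta + u_j,      u_j ~ N(0, sigma_u^2),

with the cluster effects integrated out of the likelihood:

    l = sum_j log  Int  prod_i Bernoulli(y_ij | expit(x_ij' beta + u))
                        * phi(u; 0, sigma_u^2) du.

The integral is evaluated per cluster by Gauss-Hermite quadrature centred
and scaled at the mode of the integrand (adaptive GHQ, 7 nodes by
default).  Optimisation is quasi-Newton (BFGS) on (beta, log sigma_u),
started from the fixed-effects-only logistic fit; a second documented
start at a larger variance guards against poor local starts.  Standard
errors come from the inverse observed information (numeric Hessian); the
variance CI is formed on the log-sigma scale and back-transformed.

The latent-scale intraclass correlation is sigma_u^2/(sigma_u^2 + pi^2/3);
average marginal effects are discrete changes in the population-averaged
probability, averaged over the sample, with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .descriptives import REFERENCE_LEVELS, build_design
from .errors import FitError, McprError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "RandomInterceptLogit",
    "log_likelihood",
    "fit_model",
    "icc",
    "run_model_sequence",
    "average_marginal_effects",
    "likelihood_ratio_test",
]

_SIGMA_FLOOR = 1e-8  # below this the model is treated as a plain logit


def icc(sigma_u2: float) -> float:
    """Latent-scale intraclass correlation sigma^2 / (sigma^2 + pi^2/3)."""
    if sigma_u2 < 0:
        raise McprError(f"sigma_u2 must be >= 0, got {sigma_u2}")
    return sigma_u2 / (sigma_u2 + np.pi**2 / 3.0)


def _plain_logistic_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _cluster_modes(off, y, idx, J, sigma, u0=None, max_iter=100, tol=1e-11):
    """Per-cluster mode and curvature of the integrand exponent.

    Newton iterations, vectorised across clusters.  The exponent
    h_j(u) = sum_i [y eta - log(1+e^eta)] - u^2/(2 sigma^2) is strictly
    concave in u, so undamped Newton with a step clip converges.
    """
    u = np.zeros(J) if u0 is None else u0.copy()
    inv_s2 = 1.0 / sigma**2
    h2 = None
    for _ in range(max_iter):
        eta = off + u[idx]
        p = special.expit(eta)
        g = np.bincount(idx, weights=y - p, minlength=J) - u * inv_s2
        h2 = -np.bincount(idx, weights=p * (1.0 - p), minlength=J) - inv_s2
        step = g / h2
        step = np.clip(step, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(step)) < tol:
            break
    eta = off + u[idx]
    p = special.expit(eta)
    h2 = -np.bincount(idx, weights=p * (1.0 - p), minlength=J) - inv_s2
    return u, h2


def _marginal_loglik(beta, sigma, X, y, idx, J, n_quad):
    """Adaptive GHQ marginal log-likelihood; overflow-guarded throughout."""
    if sigma < _SIGMA_FLOOR:
        return _plain_logistic_loglik(beta, X, y)
    off = X @ beta
    u_hat, h2 = _cluster_modes(off, y, idx, J, sigma)
    tau = 1.0 / np.sqrt(-h2)
    z, w = hermgauss(n_quad)
    U = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    gj = np.empty((J, n_quad))
    for k in range(n_quad):
        eta_k = off + U[idx, k]
        contrib = y * eta_k - np.logaddexp(0.0, eta_k)
        gj[:, k] = np.bincount(idx, weights=contrib, minlength=J)
    log_phi = -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * (U / sigma) ** 2
    log_integrand = np.log(w)[None, :] + z[None, :] ** 2 + gj + log_phi
    lj = special.logsumexp(log_integrand, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
    return float(np.sum(lj))


def log_likelihood(beta, sigma_u, X, y, groups, n_quad_points: int = 7) -> float:
    """Marginal log-likelihood at (beta, sigma_u).

    ``sigma_u = 0`` gives the ordinary logistic log-likelihood exactly
    (degenerate integral).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    codes, _ = pd.factorize(np.asarray(groups), sort=True)
    J = codes.max() + 1
    return _marginal_loglik(np.asarray(beta, float), float(sigma_u), X, y, codes, J,
                            n_quad_points)


def _logistic_irls(X, y, max_iter=50, ridge=1e-8):
    """Fixed-effects-only Newton fit used for starting values."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        W = mu * (1.0 - mu) + 1e-10
        H = (X * W[:, None]).T @ X + ridge * np.eye(p)
        g = X.T @ (y - mu)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _numeric_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


class RandomInterceptLogit(BaseEstimator):
    """Two-level random-intercept logistic regression (scikit-learn style).

    Parameters
    ----------
    n_quad : int
        Adaptive Gauss-Hermite quadrature nodes per cluster integral.
    fit_intercept : bool
        Prepend a constant column to the design.
    sigma_zero : bool
        Fix the cluster variance at zero (ordinary logistic regression,
        used for degenerate-limit checks).
    compute_se : bool
        Invert the observed information for standard errors; switch off in
        tight simulation loops where only point estimates are needed.

    Fitted attributes (trailing underscore): ``coef_``, ``intercept_``,
    ``sigma_u2_``, ``sigma_u2_ci_``, ``icc_``, ``loglik_``, ``aic_``,
    ``se_``, ``cov_params_``, ``converged_``, ``n_obs_``, ``n_clusters_``,
    ``n_params_``.
    """

    def __init__(self, n_quad: int = 7, fit_intercept: bool = True,
                 sigma_zero: bool = False, compute_se: bool = True,
                 start_sigmas: tuple = (0.3, 1.0), max_iter: int = 200,
                 gtol: float = 1e-5):
        self.n_quad = n_quad
        self.fit_intercept = fit_intercept
        self.sigma_zero = sigma_zero
        self.compute_se = compute_se
        self.start_sigmas = start_sigmas
        self.max_iter = max_iter
        self.gtol = gtol

    # ---- estimator API -------------------------------------------------

    def fit(self, X, y, groups=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or len(X) != len(y):
            raise McprError("X must be 2-D and aligned with y")
        if not np.isin(y, (0.0, 1.0)).all():
            raise McprError("outcome must be binary 0/1")
        if self.fit_intercept:
            X = np.hstack([np.ones((len(X), 1)), X])
        if groups is None:
            raise McprError("groups (cluster ids) are required")
        codes, uniques = pd.factorize(np.asarray(groups), sort=True)
        J = len(uniques)
        if not self.sigma_zero and J < 2:
            raise FitError("need at least 2 clusters for a random intercept")
        p = X.shape[1]

        beta0 = _logistic_irls(X, y)
        if self.sigma_zero:
            self._finalize_sigma_zero(X, y, codes, J, beta0)
            return self

        def nll(theta):
            beta, zeta = theta[:-1], theta[-1]
            if not np.all(np.isfinite(beta)) or not np.isfinite(zeta):
                return 1e12
            sigma = np.exp(np.clip(zeta, -20.0, 5.0))
            return -_marginal_loglik(beta, sigma, X, y, codes, J, self.n_quad)

        best = None
        for s0 in self.start_sigmas:
            x0 = np.concatenate([beta0, [np.log(s0)]])
            res = optimize.minimize(
                nll, x0, method="BFGS",
                options={"maxiter": self.max_iter, "gtol": self.gtol},
            )
            # BFGS on a finite-difference gradient often reports "precision
            # loss" at an excellent optimum; accept when the gradient is
            # small relative to the log-likelihood scale
            res.converged = bool(
                res.success
                or np.max(np.abs(res.jac)) < 1e-4 * max(1.0, abs(res.fun))
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.converged:
                break
        res = best
        theta = res.x
        if not np.all(np.isfinite(theta)) or nll(theta) >= 1e11:
            raise FitError(f"optimisation failed: {res.message}")
        if np.max(np.abs(theta[:-1])) > 20:
            raise FitError(
                "implausibly large coefficients; data may be separated "
                f"(max |beta| = {np.max(np.abs(theta[:-1])):.1f})"
            )
        self.converged_ = bool(res.converged)
        self.params_ = theta
        self.sigma_u2_ = float(np.exp(2.0 * theta[-1]))
        self.loglik_ = -float(res.fun)
        self.n_params_ = p + 1
        self._finish(X, y, codes, J, nll)
        return self

    def _finalize_sigma_zero(self, X, y, codes, J, beta):
        self.params_ = np.asarray(beta, float)
        self.sigma_u2_ = 0.0
        self.loglik_ = _plain_logistic_loglik(beta, X, y)
        self.n_params_ = X.shape[1]
        self.converged_ = True

        def nll(theta):
            return -_plain_logistic_loglik(theta, X, y)

        self._finish(X, y, codes, J, nll)

    def _finish(self, X, y, codes, J, nll):
        p = X.shape[1]
        theta = self.params_
        self.n_obs_ = len(y)
        self.n_clusters_ = int(J)
        self.aic_ = 2.0 * self.n_params_ - 2.0 * self.loglik_
        self.icc_ = icc(self.sigma_u2_)
        if self.fit_intercept:
            self.intercept_ = float(theta[0])
            self.coef_ = np.array(theta[1:p])
        else:
            self.intercept_ = 0.0
            self.coef_ = np.array(theta[:p])
        self.beta_ = np.array(theta[:p])
        self.se_ = None
        self.cov_params_ = None
        self.sigma_u2_ci_ = (np.nan, np.nan)
        if self.compute_se:
            H = _numeric_hessian(nll, theta)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
            self.cov_params_ = cov
            with np.errstate(invalid="ignore"):
                self.se_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            if not self.sigma_zero:
                zeta, se_z = theta[-1], self.se_[-1]
                lo = np.clip(2.0 * (zeta - 1.959963984540054 * se_z), -700, 700)
                hi = np.clip(2.0 * (zeta + 1.959963984540054 * se_z), -700, 700)
                self.sigma_u2_ci_ = (float(np.exp(lo)), float(np.exp(hi)))
        return self

    def predict_proba(self, X, marginal: bool = True, n_quad: int = 21):
        """Population-averaged P(y=1 | x): the random intercept is
        integrated out with Gauss-Hermite quadrature (``marginal=True``),
        or set to zero (cluster-median probability) otherwise."""
        X = np.asarray(X, float)
        if self.fit_intercept:
            X = np.hstack([np.ones((len(X), 1)), X])
        eta = X @ self.beta_
        p1 = _pop_averaged_prob(eta, np.sqrt(self.sigma_u2_), n_quad) if marginal \
            else special.expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, **kw):
        return (self.predict_proba(X, **kw)[:, 1] >= 0.5).astype(int)


def _pop_averaged_prob(eta, sigma, n_quad=21):
    if sigma < _SIGMA_FLOOR:
        return special.expit(eta)
    z, w = hermgauss(n_quad)
    nodes = np.sqrt(2.0) * sigma * z
    return (special.expit(eta[:, None] + nodes[None, :]) @ w) / np.sqrt(np.pi)


# ---- model-spec layer ----------------------------------------------------


@dataclass
class ModelSpec:
    """Which terms enter the model and where the cluster sits."""

    outcome: str = "outcome_modern"
    individual_terms: list[str] = field(default_factory=list)
    community_terms: list[str] = field(default_factory=list)
    cluster: str = "district_id"
    references: dict[str, str] | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.individual_terms) + list(self.community_terms)


@dataclass
class ModelFit:
    """Everything reported for one model in the sequence."""

    spec: ModelSpec
    terms: list[str]
    beta: pd.Series
    se_beta: pd.Series | None
    sigma_u2: float
    sigma_u2_ci: tuple
    loglik: float
    aic: float
    icc: float
    wald_chi2: float
    wald_df: int
    wald_p: float
    n_obs: int
    n_clusters: int
    n_params: int
    converged: bool
    cov_params: np.ndarray | None = field(repr=False, default=None)
    estimator: RandomInterceptLogit = field(repr=False, default=None)
    data_index: pd.Index = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se_beta": None if self.se_beta is None
            else {k: float(v) for k, v in self.se_beta.items()},
            "sigma_u2": self.sigma_u2,
            "sigma_u2_ci": list(self.sigma_u2_ci),
            "loglik": self.loglik,
            "aic": self.aic,
            "icc": self.icc,
            "wald_chi2": self.wald_chi2,
            "wald_df": self.wald_df,
            "wald_p": self.wald_p,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "n_params": self.n_params,
            "converged": self.converged,
        }


def fit_model(spec: ModelSpec, data: pd.DataFrame, **estimator_kwargs) -> ModelFit:
    """Fit one random-intercept logit described by ``spec``.

    Rows with a missing outcome or missing terms are dropped (listwise).
    The Wald chi-square tests all non-intercept fixed effects jointly.
    """
    cols = [spec.outcome, spec.cluster] + spec.terms
    sub = data.dropna(subset=cols)
    if len(sub) == 0:
        raise FitError("no complete-case rows to fit on")
    y = sub[spec.outcome].to_numpy(float)
    X = build_design(sub, spec.terms, references=spec.references, add_intercept=True)
    est = RandomInterceptLogit(fit_intercept=False, **estimator_kwargs)
    est.fit(X.to_numpy(float), y, groups=sub[spec.cluster].to_numpy())
    names = list(X.columns)
    beta = pd.Series(est.beta_, index=names)
    se = None
    wald = (np.nan, 0, np.nan)
    if est.se_ is not None:
        se = pd.Series(est.se_[: len(names)], index=names)
        free = [i for i, nm in enumerate(names) if nm != "intercept"]
        if free:
            b = est.beta_[free]
            V = est.cov_params_[np.ix_(free, free)]
            try:
                stat = float(b @ np.linalg.solve(V, b))
                wald = (stat, len(free), float(stats.chi2.sf(stat, len(free))))
            except np.linalg.LinAlgError:
                pass
    return ModelFit(
        spec=spec,
        terms=spec.terms,
        beta=beta,
        se_beta=se,
        sigma_u2=est.sigma_u2_,
        sigma_u2_ci=est.sigma_u2_ci_,
        loglik=est.loglik_,
        aic=est.aic_,
        icc=est.icc_,
        wald_chi2=wald[0],
        wald_df=wald[1],
        wald_p=wald[2],
        n_obs=est.n_obs_,
        n_clusters=est.n_clusters_,
        n_params=est.n_params_,
        converged=est.converged_,
        cov_params=est.cov_params_,
        estimator=est,
        data_index=sub.index,
    )


def run_model_sequence(
    data: pd.DataFrame,
    individual_terms: list[str],
    community_terms: list[str],
    cluster: str = "district_id",
    outcome: str = "outcome_modern",
    **estimator_kwargs,
):
    """The four-model sequence.

    Model 1: empty (intercept + random intercept).  Model 2: individual
    terms.  Model 3: community terms.  Model 4: both.  A failing model is
    recorded as its exception; the sequence continues.  Returns
    ``(fits, best)`` where ``best`` is the lowest-AIC successful model
    number.
    """
    specs = {
        1: ModelSpec(outcome, [], [], cluster),
        2: ModelSpec(outcome, individual_terms, [], cluster),
        3: ModelSpec(outcome, [], community_terms, cluster),
        4: ModelSpec(outcome, individual_terms, community_terms, cluster),
    }
    fits: dict[int, object] = {}
    for m, spec in specs.items():
        try:
            fits[m] = fit_model(spec, data, **estimator_kwargs)
        except Exception as exc:  # propagate per-model, keep going
            fits[m] = exc
    ok = {m: f for m, f in fits.items() if isinstance(f, ModelFit)}
    best = min(ok, key=lambda m: ok[m].aic) if ok else None
    return fits, best


def average_marginal_effects(fit: ModelFit, data: pd.DataFrame,
                             n_quad: int = 21) -> pd.DataFrame:
    """Discrete-change average marginal effects with delta-method SEs.

    For each non-reference category c of each covariate, every woman's
    covariate is counterfactually set to c and then to the reference; the
    AME is the sample mean of the difference of the two population-averaged
    probabilities (random intercept integrated out by quadrature).
    """
    spec = fit.spec
    sub = data.loc[fit.data_index]
    X = build_design(sub, spec.terms, references=spec.references, add_intercept=True)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    theta = (np.concatenate([fit.beta.to_numpy(), [0.5 * np.log(max(fit.sigma_u2, 1e-300))]])
             if fit.sigma_u2 > 0 else fit.beta.to_numpy())
    has_sigma = fit.sigma_u2 > 0

    refs = spec.references or REFERENCE_LEVELS

    def ame_vector(th):
        beta = th[: len(names)]
        sigma = np.exp(th[-1]) if has_sigma else 0.0
        out = []
        for term in spec.terms:
            cats = [nm.split(":", 1)[1] for nm in names if nm.startswith(term + ":")]
            cols = [names.index(f"{term}:{c}") for c in cats]
            X_ref = Xv.copy()
            X_ref[:, cols] = 0.0
            eta_ref = X_ref @ beta
            p_ref = _pop_averaged_prob(eta_ref, sigma, n_quad)
            for c, col in zip(cats, cols):
                X_c = X_ref.copy()
                X_c[:, col] = 1.0
                p_c = _pop_averaged_prob(X_c @ beta, sigma, n_quad)
                out.append(np.mean(p_c - p_ref))
        return np.array(out)

    ames = ame_vector(theta)
    ses = np.full(len(ames), np.nan)
    if fit.cov_params is not None:
        k = len(theta)
        G = np.empty((len(ames), k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = 1e-5 * (1.0 + abs(theta[i]))
            G[:, i] = (ame_vector(theta + e) - ame_vector(theta - e)) / (2.0 * e[i])
        V = fit.cov_params[:k, :k]
        ses = np.sqrt(np.clip(np.einsum("ik,kl,il->i", G, V, G), 0.0, None))

    rows = []
    i = 0
    for term in spec.terms:
        cats = [nm.split(":", 1)[1] for nm in names if nm.startswith(term + ":")]
        for c in cats:
            ame, se = float(ames[i]), float(ses[i])
            z = ame / se if se and np.isfinite(se) and se > 0 else np.nan
            pv = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            stars = "***" if pv < 0.01 else "**" if pv < 0.05 else "*" if pv < 0.10 else ""
            rows.append({"term": term, "category": c, "reference": refs.get(term),
                         "ame": ame, "se": se, "p": pv, "stars": stars})
            i += 1
    return pd.DataFrame(rows)


def likelihood_ratio_test(fit_restricted: ModelFit, fit_full: ModelFit):
    """LR = 2 (l_full - l_restricted), chi-square upper-tail p-value.

    The restricted model's terms must be a subset of the full model's and
    both must be fitted on the same rows.
    """
    if not set(fit_restricted.terms) <= set(fit_full.terms):
        raise McprError("models are not nested")
    if fit_restricted.n_obs != fit_full.n_obs:
        raise McprError("models were fitted on different row sets")
    lr = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    df = fit_full.n_params - fit_restricted.n_params
    if df < 0:
        raise McprError("full model has fewer parameters than restricted")
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return float(lr), int(df), p
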