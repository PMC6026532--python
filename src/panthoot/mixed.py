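"""Maximum-likelihood mixed models with independent variance components.

Every model in this package shares one random-effects structure: a random
intercept for the subject (caller or focal male) plus independent random
slopes for each fixed-effect column, with factor columns entered as
mean-centered dummies.  For a grouping factor with ``G`` levels and ``T``
such terms the random-effect design ``Z`` has ``q = T * G`` columns and the
covariance of the stacked effects is diagonal, one variance per term.

Two fitting routes are provided, both plain ML (never REML) so that
likelihood-ratio tests between nested fits are valid:

* :func:`fit_gaussian_lmm` — the marginal likelihood of
  ``y ~ N(X b, s^2 (I + Z L^2 Z'))`` is profiled over the fixed effects and
  the residual variance, leaving a bounded optimization over the
  per-term ratios ``L`` of random-effect SD to residual SD.  Cross-products
  of ``X``, ``Z`` and ``y`` are precomputed once, so each objective
  evaluation costs ``O(q^3)`` independent of the number of rows.
* :func:`fit_count_glmm` — Poisson or negative-binomial (NB2) response with
  a log link and optional offset.  The random effects are integrated out by
  a Laplace approximation at the conditional mode, found by a damped Newton
  solve in the spherical parameterization ``u = L v`` (well behaved at
  variance-component boundaries).  The outer optimization runs over fixed
  effects, per-term SDs and, for NB2, the inverse shape (so the
  equidispersed limit is a boundary, not a flat direction at infinity).

A two-step fallback ladder (alternate optimizer, then intercept-only
random effects) is applied when an optimizer reports failure; fits carry a
``converged`` flag and a description of any fallback instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

__all__ = [
    "MixedModelFit",
    "TestResult",
    "build_random_design",
    "fit_gaussian_lmm",
    "fit_count_glmm",
    "likelihood_ratio_test",
]

_ETA_MAX = 30.0  # linear predictors are clipped before exponentiation


@dataclass
class MixedModelFit:
    """Result of one mixed-model fit."""

    family: str
    coef_names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    fallback: str = ""
    re_names: list = field(default_factory=list)
    re_sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma: float | None = None
    nb_theta: float | None = None
    mu_hat: np.ndarray | None = None  # conditional fitted means (count fits)
    n_fixef: int = 0
    opt_x: np.ndarray | None = None  # raw optimizer vector, reusable as a start

    @property
    def coefficients(self) -> dict:
        return {
            name: (float(b), float(s))
            for name, b, s in zip(self.coef_names, self.beta, self.se)
        }


@dataclass(frozen=True)
class TestResult:
    """A likelihood-ratio chi-square test."""

    statistic: float
    df: int
    p_value: float

    @staticmethod
    def from_loglik(ll_full: float, ll_null: float, df: int) -> "TestResult":
        stat = 2.0 * (ll_full - ll_null)
        # optimizer noise can leave a tiny negative difference on nested fits
        stat = max(stat, 0.0)
        if df == 0:  # vacuous comparison: no constraints tested
            return TestResult(stat, 0, 1.0)
        return TestResult(stat, df, float(chi2.sf(stat, df)))


def likelihood_ratio_test(full: MixedModelFit, null: MixedModelFit, df: int) -> TestResult:
    if full.n_obs != null.n_obs:
        raise ValueError(
            f"non-comparable fits: {full.n_obs} vs {null.n_obs} rows"
        )
    return TestResult.from_loglik(full.loglik, null.loglik, df)


def build_random_design(groups: np.ndarray, slopes: dict) -> tuple:
    """Build the random-effect design for intercept + independent slopes.

    Parameters
    ----------
    groups : array of int codes in ``0..G-1``, length n.
    slopes : mapping ``name -> column`` of slope covariates; each column is
        mean-centered here (centered-dummy coding for factors).

    Returns
    -------
    Z : (n, T*G) array, term-major (intercept block first).
    term_of_col : (T*G,) int array mapping each column to its term.
    term_names : list of T term names.
    """
    groups = np.asarray(groups)
    n = groups.shape[0]
    G = int(groups.max()) + 1 if n else 0
    ind = np.zeros((n, G))
    ind[np.arange(n), groups] = 1.0
    blocks = [ind]
    names = ["intercept"]
    for name, col in slopes.items():
        c = np.asarray(col, dtype=float)
        c = c - c.mean()  # exact mean-centering on the fitted rows
        blocks.append(ind * c[:, None])
        names.append(name)
    Z = np.hstack(blocks)
    term_of_col = np.repeat(np.arange(len(names)), G)
    return Z, term_of_col, names


# ---------------------------------------------------------------------------
# Gaussian LMM, profiled ML


def _lmm_profile(lam, term_of_col, XtX, XtY, ZtZ, ZtX, Zty, yty, n, want_grad=False):
    """Profiled quantities at variance ratios ``lam`` (one per term).

    Returns (neg2ll, beta, XtVinvX, sigma2, ok[, grad]).  The gradient of
    the profiled deviance in ``lam`` uses the envelope theorem over the
    profiled fixed effects and residual variance.
    """
    lam_col = lam[term_of_col]
    Lc = lam_col[:, None]
    M = np.eye(len(lam_col)) + (Lc * ZtZ) * lam_col[None, :]
    try:
        cf = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        out = (np.inf, None, None, None, False)
        return out + (None,) if want_grad else out
    logdetM = 2.0 * np.log(np.diag(cf[0])).sum()
    LB = Lc * ZtX            # q x p
    Lc1 = lam_col * Zty      # q
    MiLB = cho_solve(cf, LB)
    MiLc = cho_solve(cf, Lc1)
    XtVinvX = XtX - LB.T @ MiLB
    XtVinvy = XtY - LB.T @ MiLc
    ytViny = yty - Lc1 @ MiLc
    try:
        beta = np.linalg.solve(XtVinvX, XtVinvy)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(XtVinvX, XtVinvy, rcond=None)
    qform = float(ytViny - XtVinvy @ beta)
    sigma2 = max(qform / n, 1e-12)
    neg2ll = n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetM
    if not want_grad:
        return neg2ll, beta, XtVinvX, sigma2, True
    # w = Z' Vinv r  and  d = diag(Z' Vinv Z), from the same cross-products
    MiLA = cho_solve(cf, Lc * ZtZ)
    ZtVinvZ_diag = np.diag(ZtZ) - np.einsum("ij,ji->i", ZtZ * lam_col[None, :], MiLA)
    w = (Zty - ZtZ @ (lam_col * MiLc)) - (ZtX - ZtZ @ (Lc * MiLB)) @ beta
    grad = np.zeros(len(lam))
    for k in range(len(lam)):
        cols = term_of_col == k
        grad[k] = 2.0 * lam[k] * (
            ZtVinvZ_diag[cols].sum() - (w[cols] ** 2).sum() / sigma2
        )
    return neg2ll, beta, XtVinvX, sigma2, True, grad


def fit_gaussian_lmm(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    term_of_col: np.ndarray,
    coef_names: list,
    re_names: list,
    start: np.ndarray | None = None,
) -> MixedModelFit:
    """ML fit of a Gaussian linear mixed model (identity link).

    ``start`` optionally seeds the variance-ratio search (warm starts across
    near-identical refits).  The profiled deviance can hold spurious local
    minima where a ratio sticks to its zero boundary, so after the first
    solve the search is restarted from the solution bumped off every
    boundary until no further improvement appears.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    T = int(term_of_col.max()) + 1
    XtX, XtY = X.T @ X, X.T @ y
    ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ X, Z.T @ y
    yty = float(y @ y)

    def obj(lam):
        out = _lmm_profile(
            lam, term_of_col, XtX, XtY, ZtZ, ZtX, Zty, yty, n, want_grad=True
        )
        if not out[4]:
            return np.inf, np.zeros(T)
        return out[0], out[5]

    def solve(x0):
        return optimize.minimize(
            obj,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, 50.0)] * T,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )

    fallback = ""
    x0 = np.full(T, 1.0) if start is None else np.clip(np.asarray(start, float), 0.0, 50.0)
    best = solve(x0)
    for _ in range(3):  # bump off boundaries and re-solve while it helps
        res = solve(best.x + 0.25)
        if np.isfinite(res.fun) and res.fun < best.fun - 1e-7:
            best = res
        else:
            break
    converged = bool(np.isfinite(best.fun))
    if not best.success and converged:
        res = optimize.minimize(
            lambda x: obj(x)[0], best.x, method="Powell",
            bounds=[(0.0, 50.0)] * T, options={"xtol": 1e-10, "ftol": 1e-13},
        )
        if res.fun <= best.fun:
            best = res
        fallback = "alternate optimizer (Powell)"
        converged = bool(np.isfinite(best.fun))

    lam = np.asarray(best.x, float)
    neg2ll, beta, XtVinvX, sigma2, ok = _lmm_profile(
        lam, term_of_col, XtX, XtY, ZtZ, ZtX, Zty, yty, n
    )
    if not ok:
        return MixedModelFit(
            "gaussian", coef_names, np.full(p, np.nan), np.full(p, np.nan),
            -np.inf, n, False, "profile evaluation failed", re_names,
            np.full(T, np.nan), None, None, None, p,
        )
    sigma = float(np.sqrt(sigma2))
    try:
        cov = sigma2 * np.linalg.inv(XtVinvX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return MixedModelFit(
        family="gaussian",
        coef_names=list(coef_names),
        beta=np.asarray(beta, float),
        se=se,
        loglik=-0.5 * float(neg2ll),
        n_obs=n,
        converged=converged,
        fallback=fallback,
        re_names=list(re_names),
        re_sd=lam * sigma,
        sigma=sigma,
        n_fixef=p,
        opt_x=lam,
    )


# ---------------------------------------------------------------------------
# Count GLMM, Laplace approximation


def _poisson_parts(y, eta):
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    ll = float(np.sum(y * eta - mu - special.gammaln(y + 1.0)))
    return ll, y - mu, mu, mu


def _negbin_parts(y, eta, theta):
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    ll = float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * (np.clip(eta, -_ETA_MAX, _ETA_MAX) - np.log(theta + mu))
        )
    )
    grad = y - mu * (y + theta) / (mu + theta)
    W = theta * mu * (y + theta) / (mu + theta) ** 2
    return ll, grad, W, mu


def _family_parts(family, y, eta, theta):
    if family == "poisson":
        return _poisson_parts(y, eta)
    return _negbin_parts(y, eta, theta)


def _laplace_loglik(y, eta_fixed, Zl, family, theta, v0, tol=1e-8, max_iter=60):
    """Laplace log-likelihood; inner damped Newton for the spherical mode."""
    q = Zl.shape[1]
    v = v0 if v0 is not None and v0.shape == (q,) else np.zeros(q)
    ll, grad_eta, W, _ = _family_parts(family, y, eta_fixed + Zl @ v, theta)
    g = ll - 0.5 * v @ v
    for _ in range(max_iter):
        grad = Zl.T @ grad_eta - v
        if np.max(np.abs(grad)) < tol:
            break
        H = (Zl * W[:, None]).T @ Zl + np.eye(q)
        try:
            step = cho_solve(cho_factor(H, lower=True), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t, accepted = 1.0, False
        for _ in range(25):
            v_new = v + t * step
            ll_new, grad_eta_new, W_new, _ = _family_parts(
                family, y, eta_fixed + Zl @ v_new, theta
            )
            g_new = ll_new - 0.5 * v_new @ v_new
            if np.isfinite(g_new) and g_new >= g - 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        gain = g_new - g
        v, g, grad_eta, W = v_new, g_new, grad_eta_new, W_new
        if gain < 1e-12:  # stalled at numerical precision
            break
    H = (Zl * W[:, None]).T @ Zl + np.eye(q)
    sign, logdetH = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, v
    return g - 0.5 * logdetH, v


def _init_beta_glm(y, X, offset, family):
    """Cheap unpenalized IRLS start for the fixed effects."""
    n, p = X.shape
    eta = np.log(np.clip(y, 0.5, None)) - offset
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    for _ in range(12):
        mu = np.exp(np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX))
        W = np.clip(mu, 1e-8, None)
        z = (offset + X @ beta) + (y - mu) / W - offset
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X + 1e-10 * np.eye(p), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def fit_count_glmm(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    term_of_col: np.ndarray,
    coef_names: list,
    re_names: list,
    family: str = "poisson",
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    _allow_fallback: bool = True,
) -> MixedModelFit:
    """ML fit of a Poisson or negative-binomial GLMM (log link, Laplace)."""
    if family not in ("poisson", "negative_binomial"):
        raise ValueError(f"unsupported family {family!r}")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    T = int(term_of_col.max()) + 1
    offset = np.zeros(n) if offset is None else np.asarray(offset, float)
    estimate_theta = family == "negative_binomial"

    beta0 = _init_beta_glm(y, X, offset, family)
    mu0 = np.exp(np.clip(offset + X @ beta0, -_ETA_MAX, _ETA_MAX))
    if estimate_theta:
        # moment start for the shape, parameterized as psi = 1/theta so the
        # equidispersed (Poisson) limit is a nearby boundary, not a flat
        # direction at infinity
        excess = np.mean((y - mu0) ** 2 - mu0)
        theta0 = float(np.clip(np.mean(mu0**2) / max(excess, 1e-6), 0.2, 50.0))
        x0 = np.concatenate([beta0, np.full(T, 0.3), [1.0 / theta0]])
    else:
        x0 = np.concatenate([beta0, np.full(T, 0.3)])
    bounds = (
        [(None, None)] * p
        + [(0.0, 15.0)] * T
        + ([(1e-4, 50.0)] if estimate_theta else [])
    )
    if start is not None and np.shape(start) == np.shape(x0):
        x0 = np.clip(
            np.asarray(start, float),
            [b[0] if b[0] is not None else -np.inf for b in bounds],
            [b[1] if b[1] is not None else np.inf for b in bounds],
        )

    warm = {"v": None}

    def obj(x):
        beta = x[:p]
        lam = x[p : p + T]
        theta = 1.0 / x[-1] if estimate_theta else None
        Zl = Z * lam[term_of_col][None, :]
        ll, v = _laplace_loglik(y, offset + X @ beta, Zl, family, theta, warm["v"])
        warm["v"] = v
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        obj, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 400, "eps": 1e-6},
    )
    fallback = ""
    if (not res.success or not np.isfinite(res.fun)) and _allow_fallback:
        res2 = optimize.minimize(
            obj, res.x if np.all(np.isfinite(res.x)) else x0,
            method="Powell", bounds=bounds,
            options={"xtol": 1e-9, "ftol": 1e-12, "maxiter": 4000},
        )
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
            fallback = "alternate optimizer (Powell)"
    converged = bool(res.success or (np.isfinite(res.fun) and fallback))
    if not converged and _allow_fallback and T > 1:
        # final rung: random intercept only
        G = Z.shape[1] // T
        sub = fit_count_glmm(
            y, X, Z[:, :G], term_of_col[:G], coef_names, re_names[:1],
            family=family, offset=offset, _allow_fallback=False,
        )
        sub.fallback = "random intercept only"
        sub.re_names = list(re_names)
        sub.re_sd = np.concatenate([sub.re_sd, np.zeros(T - 1)])
        return sub

    x = res.x
    beta = x[:p].copy()
    lam = x[p : p + T].copy()
    theta = float(1.0 / x[-1]) if estimate_theta else None
    Zl = Z * lam[term_of_col][None, :]
    ll, v_hat = _laplace_loglik(y, offset + X @ beta, Zl, family, theta, warm["v"])
    mu_hat = np.exp(np.clip(offset + X @ beta + Zl @ v_hat, -_ETA_MAX, _ETA_MAX))

    se = _wald_se_beta(obj, x, p, lam_interior=lam > 1e-3)
    return MixedModelFit(
        family=family,
        coef_names=list(coef_names),
        beta=beta,
        se=se,
        loglik=float(ll),
        n_obs=n,
        converged=converged,
        fallback=fallback,
        re_names=list(re_names),
        re_sd=lam,
        nb_theta=theta,
        mu_hat=mu_hat,
        n_fixef=p,
        opt_x=x.copy(),
    )


def _wald_se_beta(obj, x_opt, p, lam_interior=None):
    """Fixed-effect SEs from the observed information at the optimum.

    The numerical Hessian is taken over the fixed effects together with any
    *interior* variance parameters (and the NB shape), and the fixed-effect
    block of its inverse gives the covariance — the full ML covariance
    rather than the narrower variance-conditional one.  Variance components
    estimated on their zero boundary are held fixed, where a two-sided
    second derivative is not defined.
    """
    d = len(x_opt)
    free = list(range(p))
    for j in range(p, d):
        interior = True
        if lam_interior is not None and j - p < len(lam_interior):
            interior = bool(lam_interior[j - p])
        if interior:
            free.append(j)
    m = len(free)
    h = 1e-4 * (1.0 + np.abs(x_opt[free]))
    H = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            i, j = free[a], free[b]
            xpp = x_opt.copy(); xpp[i] += h[a]; xpp[j] += h[b]
            xpm = x_opt.copy(); xpm[i] += h[a]; xpm[j] -= h[b]
            xmp = x_opt.copy(); xmp[i] -= h[a]; xmp[j] += h[b]
            xmm = x_opt.copy(); xmm[i] -= h[a]; xmm[j] -= h[b]
            H[a, b] = H[b, a] = (obj(xpp) - obj(xpm) - obj(xmp) + obj(xmm)) / (
                4.0 * h[a] * h[b]
            )
    for use in (H, H[:p, :p]):  # fall back to the conditional block if needed
        try:
            cov = np.linalg.inv(use)
            diag = np.diag(cov)[:p]
            if np.all(diag > 0):
                return np.sqrt(diag)
        except np.linalg.LinAlgError:
            continue
    return np.full(p, np.nan)
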