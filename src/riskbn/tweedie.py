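"""Compound Poisson-gamma (Tweedie, 1 < p < 2) numerics.

The skin-conductance indicators are zero-inflated positive quantities: a
participant may show no response at all in a trial (an exact zero) or a
positive, continuous response.  The Tweedie family with power parameter
1 < p < 2 captures exactly this: a random variable

    Y = X_1 + ... + X_N,   N ~ Poisson(lambda),   X_i ~ Gamma(alpha, scale)

has an atom at zero of mass exp(-lambda) and a continuous density on
(0, inf).  In mean/dispersion form the law is parameterised by (mu, phi, p)
with E[Y] = mu and Var[Y] = phi * mu**p, and the compound-Poisson
parameters are

    lambda = mu**(2-p) / (phi * (2-p))
    alpha  = (2-p) / (p-1)
    scale  = phi * (p-1) * mu**(p-1)

This module provides the exact density through the Poisson-gamma mixture
series, sampling, and a log-link GLM fitted by IRLS with the dispersion phi
estimated by maximum likelihood and the power p by profile likelihood over
a grid with local refinement.  The estimator follows the scikit-learn
protocol so it composes with pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "DEFAULT_P_GRID",
    "zero_probability",
    "to_compound_poisson",
    "from_compound_poisson",
    "sample_tweedie",
    "log_density",
    "TweedieFit",
    "fit_glm",
    "TweedieGLM",
]

#: Default profile-likelihood grid for the power parameter.
DEFAULT_P_GRID: tuple[float, ...] = tuple(
    round(1.1 + 0.1 * i, 1) for i in range(9)
)

_SERIES_RTOL = 1e-10
_MAX_TERMS = 16384


def _check_params(mu, phi, p):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if not phi > 0:
        raise ValueError("phi must be positive")
    if not 1.0 < p < 2.0:
        raise ValueError("p must lie strictly in (1, 2)")
    return mu, float(phi), float(p)


def zero_probability(mu, phi: float = 1.0, p: float = 1.5):
    """Exact probability of an exact zero, exp(-mu^(2-p) / (phi (2-p)))."""
    mu, phi, p = _check_params(mu, phi, p)
    out = np.exp(-(mu ** (2.0 - p)) / (phi * (2.0 - p)))
    return out if out.ndim else float(out)


def to_compound_poisson(mu: float, phi: float, p: float):
    """Map (mu, phi, p) to (lambda, gamma shape, gamma scale)."""
    mu, phi, p = _check_params(mu, phi, p)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    if lam.ndim:
        return lam, shape, scale
    return float(lam), float(shape), float(scale)


def from_compound_poisson(lam: float, shape: float, scale: float):
    """Inverse of :func:`to_compound_poisson`."""
    if lam <= 0 or shape <= 0 or scale <= 0:
        raise ValueError("lambda, shape and scale must be positive")
    p = (shape + 2.0) / (shape + 1.0)
    mu = lam * shape * scale
    phi = scale / ((p - 1.0) * mu ** (p - 1.0))
    return mu, phi, p


def sample_tweedie(mu, phi: float, p: float, size=None, rng=None):
    """Draw compound Poisson-gamma variates.

    ``mu`` may be an array (one mean per draw); ``size`` is only needed for
    scalar ``mu``.
    """
    rng = np.random.default_rng(rng)
    mu, phi, p = _check_params(mu, phi, p)
    lam, shape, scale = to_compound_poisson(mu, phi, p)
    if size is None:
        size = np.shape(mu) if np.ndim(mu) else None
    n = rng.poisson(lam=np.broadcast_to(lam, size) if size else lam, size=size)
    n = np.asarray(n)
    y = np.zeros(n.shape, dtype=float)
    pos = n > 0
    if np.any(pos):
        sc = np.broadcast_to(scale, n.shape)[pos] if np.ndim(scale) else scale
        y[pos] = rng.gamma(shape=n[pos] * shape, scale=sc)
    return y if y.ndim else float(y)


def log_density(y, mu, phi: float = 1.0, p: float = 1.5):
    """Exact Tweedie log-density (log-pmf at zero, log-pdf for y > 0).

    Evaluated through the Poisson-gamma mixture series

        f(y) = sum_{j>=1} P(N = j) * Gamma(y; j*alpha, scale)

    with the terms summed in log space.  The truncation point starts past
    the index of the largest term (approximately y^(2-p) / (phi (2-p)),
    Dunn & Smyth's heuristic) and is doubled until the last retained term
    is below 1e-10 of the running sum.
    """
    y = np.asarray(y, dtype=float)
    mu, phi, p = _check_params(mu, phi, p)
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    y_b, mu_b = np.broadcast_arrays(y, mu)
    out = np.empty(y_b.shape, dtype=float)

    zero = y_b == 0
    if np.any(zero):
        out[zero] = -(mu_b[zero] ** (2.0 - p)) / (phi * (2.0 - p))
    pos = ~zero
    if np.any(pos):
        out[pos] = _log_density_positive(y_b[pos], mu_b[pos], phi, p)
    return out if out.ndim else float(out)


def _log_density_positive(y, mu, phi, p):
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)

    log_lam = np.log(lam)
    log_y = np.log(y)
    log_scale = np.log(scale)
    base = -lam - y / scale - log_y  # j-independent part

    j_hat = float(np.max(y ** (2.0 - p))) / (phi * (2.0 - p))
    n_terms = max(16, int(j_hat + 12.0 * np.sqrt(j_hat) + 24.0))
    while True:
        j = np.arange(1, n_terms + 1, dtype=float)
        ja = j * alpha
        # log of term j for each observation: Poisson pmf * gamma pdf
        logw = (
            base[:, None]
            + j[None, :] * log_lam[:, None]
            - gammaln(j + 1.0)[None, :]
            + ja[None, :] * (log_y[:, None] - log_scale[:, None])
            - gammaln(ja)[None, :]
        )
        total = logsumexp(logw, axis=1)
        tail_ok = np.all(logw[:, -1] <= np.log(_SERIES_RTOL) + total)
        if tail_ok or n_terms >= _MAX_TERMS:
            return total
        n_terms *= 2


# --------------------------------------------------------------------------
# Log-link GLM
# --------------------------------------------------------------------------

@dataclass
class TweedieFit:
    """Result of a Tweedie log-link regression fit."""

    coef: np.ndarray          # includes the intercept as the first entry
    bse: np.ndarray           # asymptotic standard errors
    phi: float
    p: float
    loglik: float
    k: int                    # free parameters: len(coef) + 2 (phi, p)
    n: int
    converged: bool
    profile: dict = field(default_factory=dict)  # p -> profile loglik

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coef],
            "bse": [float(s) for s in self.bse],
            "phi_hat": self.phi,
            "p_hat": self.p,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "converged": self.converged,
        }


_ETA_CLIP = 30.0


def _irls(y, X, p, beta0=None, max_iter=100, tol=1e-10):
    """MLE of the log-link coefficients at fixed p (phi-free score)."""
    n = y.shape[0]
    if beta0 is None:
        mu = np.full(n, max(float(np.mean(y)), 1e-8))
        eta = np.log(mu)
        beta = None
    else:
        beta = np.asarray(beta0, dtype=float)
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = mu ** (2.0 - p)
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        if beta is not None and np.max(np.abs(beta_new - beta)) < tol * (
            1.0 + np.max(np.abs(beta))
        ):
            beta = beta_new
            converged = True
            break
        beta = beta_new
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    return beta, converged


def _phi_loglik_factory(y, mu, p, phi_lo):
    """Log-likelihood in phi at fixed (y, mu, p), with the phi-independent
    part of the mixture series precomputed.

    Writing lambda_i = A_i / phi and gamma-scale_i = phi * B_i, the series
    term matrix depends on phi only through -(1 + alpha) * log(phi) * j,
    so a single matrix of gammaln evaluations serves every phi.  The
    truncation length is sized for the smallest phi the optimiser may
    visit (``phi_lo``).
    """
    alpha = (2.0 - p) / (p - 1.0)
    A = mu ** (2.0 - p) / (2.0 - p)          # lambda_i * phi
    pos = y > 0
    ypos, mpos = y[pos], mu[pos]
    B = (p - 1.0) * mpos ** (p - 1.0)        # scale_i / phi
    if ypos.size == 0:
        return lambda phi: -float(np.sum(A)) / phi, 0
    j_hat = float(np.max(ypos ** (2.0 - p))) / (phi_lo * (2.0 - p))
    n_terms = min(
        max(16, int(j_hat + 8.0 * np.sqrt(j_hat) + 16.0)), _MAX_TERMS
    )
    j = np.arange(1, n_terms + 1, dtype=float)
    ja = j * alpha
    M = (
        np.outer(np.log(A[pos]), j)
        + np.outer(np.log(ypos) - np.log(B), ja)
        - gammaln(j + 1.0)[None, :]
        - gammaln(ja)[None, :]
    )
    const = -float(np.sum(np.log(ypos)))
    sum_A = float(np.sum(A))
    ratio = ypos / B

    def loglik(phi):
        t = -(1.0 + alpha) * np.log(phi)
        series = float(np.sum(logsumexp(M + t * j[None, :], axis=1)))
        return const + series - sum_A / phi - float(np.sum(ratio)) / phi

    return loglik, n_terms


def _profile_phi(y, mu, p, phi0=None):
    """ML estimate of phi at fixed (mu, p); returns (phi_hat, loglik)."""
    n = y.shape[0]
    pearson = float(np.sum((y - mu) ** 2 / mu ** p)) / n
    if not np.isfinite(pearson) or pearson < 1e-12:
        raise ValueError(
            "dispersion is not identifiable: responses fit the mean exactly"
        )
    start = float(np.log(phi0 if phi0 else pearson))
    # The Pearson estimate is a good starting point; the series length is
    # sized for a phi somewhat below it and the factory is rebuilt
    # transparently if the optimiser walks lower still.
    state = {"phi_lo": float(np.exp(start - 0.8))}
    state["f"] = _phi_loglik_factory(y, mu, p, phi_lo=state["phi_lo"])[0]

    def obj(lp):
        phi = float(np.exp(lp))
        if phi < state["phi_lo"]:
            state["phi_lo"] = phi / 2.0
            state["f"] = _phi_loglik_factory(
                y, mu, p, phi_lo=state["phi_lo"]
            )[0]
        return -state["f"](phi)

    # walk downhill until the minimum is bracketed (the profile in log phi
    # is unimodal), then polish with Brent
    step = 0.4
    a, b, c = start - step, start, start + step
    fa, fb, fc = obj(a), obj(b), obj(c)
    for _ in range(80):
        if fb <= fa and fb <= fc:
            break
        if fa < fc:
            c, fc = b, fb
            b, fb = a, fa
            step *= 1.6
            a = b - step
            fa = obj(a)
        else:
            a, fa = b, fb
            b, fb = c, fc
            step *= 1.6
            c = b + step
            fc = obj(c)
    res = minimize_scalar(
        obj, bracket=(a, b, c), method="brent", options={"xtol": 2e-3}
    )
    phi = float(np.exp(res.x))
    return phi, -float(res.fun)


def fit_glm(
    y,
    X,
    p_grid=DEFAULT_P_GRID,
    refine: bool = True,
    refine_tol: float = 0.01,
) -> TweedieFit:
    """Fit a Tweedie log-link GLM with profile likelihood over p.

    ``X`` must already contain an intercept column if one is wanted.  At
    each candidate p the coefficients are exact MLEs (the score equations
    for the mean do not involve phi), phi is then maximised against the
    exact series likelihood, and the profile optimum over p is refined by
    bounded local search around the best grid point.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per response")
    if np.any(y < 0):
        raise ValueError("responses must be nonnegative")
    if not np.any(y > 0):
        raise ValueError("all responses are zero: Tweedie fit undefined")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    p_grid = sorted(float(p) for p in p_grid)
    if not all(1.0 < p < 2.0 for p in p_grid):
        raise ValueError("p grid must lie strictly in (1, 2)")

    state: dict[float, tuple] = {}
    warm = {"beta": None, "phi": None}

    def profile(p):
        beta, conv = _irls(y, X, p, beta0=warm["beta"])
        mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        phi, ll = _profile_phi(y, mu, p, phi0=warm["phi"])
        warm["beta"], warm["phi"] = beta, phi
        state[round(p, 6)] = (beta, phi, ll, conv)
        return ll

    prof = {p: profile(p) for p in p_grid}
    p_best = max(prof, key=prof.get)

    if refine and len(p_grid) > 1:
        i = p_grid.index(p_best)
        lo = p_grid[max(i - 1, 0)]
        hi = p_grid[min(i + 1, len(p_grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda p: -profile(p),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": refine_tol},
            )
            if -res.fun > prof[p_best]:
                p_best = float(res.x)

    beta, phi, ll, conv = state[round(p_best, 6)]
    mu = np.exp(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
    w = mu ** (2.0 - p_best)
    cov = phi * np.linalg.inv(X.T @ (X * w[:, None]))
    bse = np.sqrt(np.diag(cov))
    return TweedieFit(
        coef=beta,
        bse=bse,
        phi=phi,
        p=p_best,
        loglik=ll,
        k=X.shape[1] + 2,
        n=y.shape[0],
        converged=bool(conv),
        profile={round(p, 6): float(l) for p, l in prof.items()},
    )


class TweedieGLM(RegressorMixin, BaseEstimator):
    """Log-link compound Poisson-gamma regression, scikit-learn style.

    Parameters
    ----------
    p_grid : sequence of float, default: 1.1 .. 1.9 in steps of 0.1
        Candidate power parameters for the profile likelihood.  A
        single-element grid fixes p.
    refine : bool, default True
        Locally refine the profile optimum between grid neighbours.
    fit_intercept : bool, default True

    Attributes
    ----------
    coef_ : ndarray of slope coefficients (log scale)
    intercept_ : float
    phi_ : fitted dispersion
    power_ : fitted p
    loglik_ : maximised log-likelihood
    bse_ : standard errors (intercept first if fitted)
    """

    def __init__(self, p_grid=DEFAULT_P_GRID, refine=True, fit_intercept=True):
        self.p_grid = p_grid
        self.refine = refine
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        M = np.column_stack([np.ones(len(y)), X]) if self.fit_intercept else X
        res = fit_glm(y, M, p_grid=self.p_grid, refine=self.refine)
        if self.fit_intercept:
            self.intercept_ = float(res.coef[0])
            self.coef_ = res.coef[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = res.coef
        self.bse_ = res.bse
        self.phi_ = res.phi
        self.power_ = res.p
        self.loglik_ = res.loglik
        self.k_ = res.k
        self.converged_ = res.converged
        self.fit_result_ = res
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.exp(
            np.clip(self.intercept_ + X @ self.coef_, -_ETA_CLIP, _ETA_CLIP)
        )
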