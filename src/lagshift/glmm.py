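"""A compact mixed-model engine: Gaussian LMMs and Poisson GLMMs with
independent scalar random effects, estimated by maximum likelihood.

The model is g(E[y]) = X beta + Z b with b ~ N(0, D), D diagonal with one
variance per random term (each term contributes a block of i.i.d. scalar
effects: random intercepts, an observation-level intercept, or a
within-group random slope). For a fixed set of variance parameters the
conditional mode of (beta, b) is found by penalized iteratively reweighted
least squares (PIRLS) on sparse matrices; the marginal likelihood is the
Laplace approximation at that mode (exact for the Gaussian family). The
variance parameters are profiled by a derivative-free Nelder-Mead search on
the log-standard-deviation scale.

Wald standard errors come from the fixed-effect block of the inverse
penalized information matrix at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import gammaln

log = logging.getLogger(__name__)

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-4), np.log(20.0)
_ETA_CLIP = 30.0
#: below this an estimated random-effect SD is reported as 0 (singular fit)
SINGULAR_SD = 1e-3


@dataclass
class RandomTerm:
    """One scalar random-effect term: a name and its n x q indicator matrix."""
    name: str
    Z: sp.csr_matrix

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class GLMMFit:
    """Maximum-likelihood fit of a mixed model."""
    family: str
    coef: np.ndarray
    se: np.ndarray
    coef_names: list
    vcomp: dict                       # term name -> estimated SD
    resid_sd: Optional[float]         # Gaussian only
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    ranef: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _logdet_sparse(M: sp.spmatrix) -> float:
    lu = splu(M.tocsc(), permc_spec="MMD_AT_PLUS_A",
              options=dict(SymmetricMode=True))
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _penalty_diag(p: int, terms, sds) -> np.ndarray:
    parts = [np.zeros(p)]
    for term, sd in zip(terms, sds):
        parts.append(np.full(term.q, 1.0 / sd**2))
    return np.concatenate(parts)


class _Objective:
    """Profiled negative marginal log-likelihood over log-SD parameters."""

    def __init__(self, X, y, terms, family):
        self.X = sp.csr_matrix(X)
        self.y = np.asarray(y, dtype=float)
        self.terms = list(terms)
        self.family = family
        self.p = self.X.shape[1]
        self.q = sum(t.q for t in self.terms)
        mats = [self.X] + [t.Z for t in self.terms]
        self.A = sp.hstack(mats, format="csr")
        self.x = np.zeros(self.p + self.q)    # warm start across evaluations
        if family == "poisson":
            self.x[0] = np.log(self.y.mean() + 0.1)
        else:
            self.x[0] = self.y.mean()
        self._const_pois = -float(np.sum(gammaln(self.y + 1.0)))

    # -- conditional mode by PIRLS -----------------------------------------

    def _solve(self, W, z, pen):
        AW = self.A.multiply(W[:, None])
        M = (self.A.T @ AW).tocsc() + sp.diags(pen)
        rhs = self.A.T @ (W * z)
        lu = splu(M, permc_spec="MMD_AT_PLUS_A",
                  options=dict(SymmetricMode=True))
        return lu.solve(rhs), M

    def _pirls_poisson(self, pen, max_iter=50, tol=1e-9):
        x = self.x.copy()
        eta = np.clip(self.A @ x, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        b = x[self.p:]
        pdev = -2 * (self.y @ eta - mu.sum()) + b @ (pen[self.p:] * b)
        M = None
        for _ in range(max_iter):
            W = np.maximum(mu, 1e-10)
            z = eta + (self.y - mu) / W
            x_new, M = self._solve(W, z, pen)
            # step-halving on the penalized deviance
            step = 1.0
            for _ in range(20):
                x_try = x + step * (x_new - x)
                eta_t = np.clip(self.A @ x_try, -_ETA_CLIP, _ETA_CLIP)
                mu_t = np.exp(eta_t)
                b_t = x_try[self.p:]
                pdev_t = -2 * (self.y @ eta_t - mu_t.sum()) \
                    + b_t @ (pen[self.p:] * b_t)
                if pdev_t <= pdev + 1e-12:
                    break
                step *= 0.5
            x, eta, mu = x_try, eta_t, mu_t
            if abs(pdev - pdev_t) < tol * (abs(pdev) + 1.0):
                pdev = pdev_t
                break
            pdev = pdev_t
        self.x = x
        return x, mu, M

    # -- marginal log-likelihood -------------------------------------------

    def loglik(self, theta) -> float:
        theta = np.clip(np.asarray(theta, dtype=float),
                        _LOG_SD_MIN, _LOG_SD_MAX)
        if self.family == "gaussian":
            sds, sigma = np.exp(theta[:-1]), float(np.exp(theta[-1]))
        else:
            sds, sigma = np.exp(theta), None
        pen = _penalty_diag(self.p, self.terms, sds)
        logdet_d = 2.0 * sum(t.q * np.log(sd)
                             for t, sd in zip(self.terms, sds))
        n = self.y.size

        if self.family == "gaussian":
            W = np.full(n, 1.0 / sigma**2)
            x, M = self._solve(W, self.y, pen)
            self.x = x
            r = self.y - self.A @ x
            b = x[self.p:]
            quad = r @ r / sigma**2 + b @ (pen[self.p:] * b)
            if self.q:
                H = M[self.p:, self.p:].tocsc()
                logdet_h = _logdet_sparse(H)
            else:
                logdet_h = 0.0
            ll = -0.5 * (quad + n * np.log(2 * np.pi * sigma**2)
                         + logdet_d + logdet_h)
        else:
            x, mu, M = self._pirls_poisson(pen)
            eta = np.clip(self.A @ x, -_ETA_CLIP, _ETA_CLIP)
            b = x[self.p:]
            ll_cond = self.y @ eta - mu.sum() + self._const_pois
            if self.q:
                H = M[self.p:, self.p:].tocsc()
                logdet_h = _logdet_sparse(H)
            else:
                logdet_h = 0.0
            ll = ll_cond - 0.5 * (b @ (pen[self.p:] * b)
                                  + logdet_d + logdet_h)
        return float(ll)

    def final(self, theta) -> tuple:
        """Coefficients, SEs and random-effect modes at the optimum."""
        ll = self.loglik(theta)
        x = self.x
        theta = np.clip(np.asarray(theta, dtype=float),
                        _LOG_SD_MIN, _LOG_SD_MAX)
        if self.family == "gaussian":
            sds, sigma = np.exp(theta[:-1]), float(np.exp(theta[-1]))
            W = np.full(self.y.size, 1.0 / sigma**2)
        else:
            sds, sigma = np.exp(theta), None
            eta = np.clip(self.A @ x, -_ETA_CLIP, _ETA_CLIP)
            W = np.maximum(np.exp(eta), 1e-10)
        pen = _penalty_diag(self.p, self.terms, sds)
        AW = self.A.multiply(W[:, None])
        M = (self.A.T @ AW).tocsc() + sp.diags(pen)
        lu = splu(M, permc_spec="MMD_AT_PLUS_A",
                  options=dict(SymmetricMode=True))
        E = np.zeros((self.p + self.q, self.p))
        E[:self.p, :] = np.eye(self.p)
        cov_beta = lu.solve(E)[:self.p, :]
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        return ll, x[:self.p], se, x[self.p:], sds, sigma


def fit_mixed(X: np.ndarray, y, terms: Sequence[RandomTerm],
              family: str = "gaussian", coef_names=None,
              maxiter: int = 200) -> GLMMFit:
    """Fit the mixed model by ML (Laplace for Poisson).

    With no random terms this reduces to an ordinary ML GLM fit. Variance
    components whose estimated SD hits the lower boundary are reported as 0
    with a warning (singular fit).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if family not in ("gaussian", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    if family == "poisson" and np.any(y != np.round(y)):
        raise ValueError("Poisson family requires integer counts")
    obj = _Objective(X, y, terms, family)
    p = obj.p

    n_theta = len(terms) + (1 if family == "gaussian" else 0)
    if n_theta == 0 or (family == "gaussian" and not terms):
        # Gaussian with no random terms still profiles the residual SD
        pass

    x0 = np.full(len(terms), np.log(0.3))
    if family == "gaussian":
        resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        x0 = np.append(x0, np.log(max(resid0.std(ddof=0), 1e-3)))

    converged = True
    if x0.size:
        # tolerances far below the statistical uncertainty of the variance
        # parameters; tighter settings only burn likelihood evaluations
        res = minimize(lambda t: -obj.loglik(t), x0, method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=1e-2, fatol=2e-3))
        theta = res.x
        converged = bool(res.success or res.fun < np.inf)
    else:
        theta = x0

    ll, beta, se, ranef, sds, sigma = obj.final(theta)
    vcomp = {}
    for t, sd in zip(terms, sds):
        if sd <= SINGULAR_SD:
            log.warning("random term %r: variance estimated at the boundary, "
                        "reported as 0 (singular fit)", t.name)
            vcomp[t.name] = 0.0
        else:
            vcomp[t.name] = float(sd)
    n_params = p + len(terms) + (1 if family == "gaussian" else 0)
    names = list(coef_names) if coef_names is not None \
        else [f"x{i}" for i in range(p)]
    return GLMMFit(family=family, coef=beta, se=se, coef_names=names,
                   vcomp=vcomp, resid_sd=sigma, loglik=ll,
                   n_params=n_params, n_obs=y.size, converged=converged,
                   ranef=ranef)
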