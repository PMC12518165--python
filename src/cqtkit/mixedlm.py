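"""Restricted maximum likelihood for linear mixed models with one grouping level.

The model, per group (subject) ``i``::

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, Omega),   e_i ~ N(0, sigma2 I)

with ``Omega`` unstructured. Both the fixed effects and the residual variance
are profiled out of the restricted likelihood, leaving an optimization over
the scaled random-effect covariance ``G = Omega / sigma2`` in a log-Cholesky
parameterization (diagonal on the log scale, sub-diagonal free), which keeps
``Omega`` positive semi-definite by construction. The ``Z`` columns are
standardized internally so all optimizer coordinates are O(1).

Writing ``V*_i = I + Z_i G Z_i'`` and using the Woodbury identity, every
quantity the objective needs reduces to per-group cross-products
(``Z_i'Z_i``, ``Z_i'X_i``, ``Z_i'y_i``, ...), computed once, so a likelihood
evaluation costs O(groups) small-matrix operations regardless of the number
of observations. At the profiled optimum::

    -2 l_R = (n-p) (log 2 pi + log sigma2_hat + 1)
             + sum_i log|W_i| + log|sum_i X_i' V*_i^{-1} X_i|

with ``W_i = I + L' Z_i'Z_i L`` and ``sigma2_hat = RSS_GLS / (n - p)``.

Optimization is deterministic: three fixed starts (scaled-identity ``G`` at
small/medium/large magnitude), Nelder-Mead followed by an L-BFGS-B polish,
best criterion wins, ties broken by start order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Fixed multi-start scales for the diagonal of the scaled covariance G.
DEFAULT_STARTS = (0.5, 0.05, 2.0)


class EstimationError(RuntimeError):
    """Raised when the mixed-model fit cannot be computed."""


@dataclass
class MixedLMResult:
    """REML estimates and fit metadata."""

    beta: np.ndarray
    beta_cov: np.ndarray
    omega: np.ndarray
    sigma2: float
    loglik: float
    n_obs: int
    n_groups: int
    n_fixed: int
    theta: np.ndarray
    converged: bool


class REMLProblem:
    """A prepared REML problem: cross-products, objective, and optimizer.

    Parameters
    ----------
    y, X, Z : array-like
        Response (n,), fixed-effect design (n, p), random-effect design (n, q).
    groups : array-like
        Group (subject) labels, one per observation.
    omega_zero : bool
        Constrain ``Omega = 0``; the fit then reduces to ordinary least
        squares with ``sigma2`` the residual mean square.
    """

    def __init__(self, y, X, Z, groups, *, omega_zero: bool = False):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if Z.ndim == 1:
            Z = Z[:, None]
        groups = np.asarray(groups)
        n, p = X.shape
        q = Z.shape[1]
        if not (len(y) == n == Z.shape[0] == len(groups)):
            raise ValueError("y, X, Z and groups must have matching lengths")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("y and X must be finite")
        if n - p <= 0:
            raise EstimationError("fewer observations than fixed effects")
        if np.linalg.matrix_rank(X) < p:
            raise EstimationError(
                "singular fixed-effect design (a column of X is constant or "
                "collinear; e.g. all concentrations equal)"
            )

        self.n, self.p, self.q = n, p, q
        self.omega_zero = omega_zero
        self.n_theta = 0 if omega_zero else q * (q + 1) // 2

        codes, uniques = np.unique(groups, return_inverse=True)
        self.n_groups = len(codes)

        scale = Z.std(axis=0)
        scale[scale == 0] = 1.0
        self._zscale = scale
        Zs = Z / scale

        m = self.n_groups
        self._ZtZ = np.zeros((m, q, q))
        self._ZtX = np.zeros((m, q, p))
        self._Zty = np.zeros((m, q))
        self._XtX = np.zeros((p, p))
        self._Xty = np.zeros(p)
        self._yty = 0.0
        order = np.argsort(uniques, kind="stable")
        starts_idx = np.searchsorted(uniques[order], np.arange(m + 1))
        for g in range(m):
            idx = order[starts_idx[g]:starts_idx[g + 1]]
            Zg, Xg, yg = Zs[idx], X[idx], y[idx]
            self._ZtZ[g] = Zg.T @ Zg
            self._ZtX[g] = Zg.T @ Xg
            self._Zty[g] = Zg.T @ yg
            self._XtX += Xg.T @ Xg
            self._Xty += Xg.T @ yg
            self._yty += yg @ yg

    # -- parameterization ---------------------------------------------------

    def chol_from_theta(self, theta) -> np.ndarray:
        """Lower-triangular Cholesky factor of the scaled covariance G."""
        q = self.q
        theta = np.asarray(theta, dtype=float)
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(theta[:q])
        if q > 1:
            L[np.tril_indices(q, -1)] = theta[q:]
        return L

    def _bounds(self):
        q = self.q
        return [(-12.0, 6.0)] * q + [(-30.0, 30.0)] * (self.n_theta - q)

    # -- profiled restricted likelihood -------------------------------------

    def _profile(self, L):
        q, p = self.q, self.p
        A = np.einsum("ab,gbc,cd->gad", L.T, self._ZtZ, L)
        W = A + np.eye(q)
        sign, logdetW = np.linalg.slogdet(W)
        if np.any(sign <= 0):
            return None
        Winv = np.linalg.inv(W)
        Ux = np.einsum("ab,gbp->gap", L.T, self._ZtX)
        uy = np.einsum("ab,gb->ga", L.T, self._Zty)
        SXX = self._XtX - np.einsum("gap,gab,gbq->pq", Ux, Winv, Ux)
        SXy = self._Xty - np.einsum("gap,gab,gb->p", Ux, Winv, uy)
        Syy = self._yty - np.einsum("ga,gab,gb->", uy, Winv, uy)
        sgn, logdetSXX = np.linalg.slogdet(SXX)
        if sgn <= 0:
            return None
        beta = np.linalg.solve(SXX, SXy)
        rss = max(float(Syy - beta @ SXy), 1e-300)
        df = self.n - p
        sigma2 = rss / df
        crit = (
            df * (_LOG_2PI + np.log(sigma2) + 1.0)
            + float(logdetW.sum())
            + float(logdetSXX)
        )
        return crit, beta, sigma2, SXX

    def criterion(self, theta) -> float:
        """-2 x restricted log-likelihood (profiled) at optimizer coordinates."""
        prof = self._profile(self.chol_from_theta(theta))
        return np.inf if prof is None else prof[0]

    # -- optimization --------------------------------------------------------

    def fit(self, starts=DEFAULT_STARTS, maxiter: int = 2000) -> MixedLMResult:
        if self.omega_zero or self.q == 0:
            theta = np.empty(0)
            L = np.zeros((self.q, self.q))
            converged = True
        else:
            q = self.q
            bounds = self._bounds()
            best = None
            for k, s in enumerate(starts):
                theta0 = np.concatenate(
                    [np.full(q, np.log(s)), np.zeros(self.n_theta - q)]
                )
                res = minimize(
                    self.criterion,
                    theta0,
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
                )
                polish = minimize(
                    self.criterion,
                    res.x,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
                )
                cand = polish if polish.fun <= res.fun else res
                # strict inequality: ties go to the earliest start
                if best is None or cand.fun < best[0]:
                    best = (cand.fun, k, cand)
            if best is None or not np.isfinite(best[0]):
                raise EstimationError("REML optimization failed to converge")
            theta = np.asarray(best[2].x, dtype=float)
            converged = bool(np.isfinite(best[0]))
            L = self.chol_from_theta(theta)

        prof = self._profile(L)
        if prof is None:
            raise EstimationError("REML solution is numerically singular")
        crit, beta, sigma2, SXX = prof
        beta_cov = sigma2 * np.linalg.inv(SXX)
        dinv = 1.0 / self._zscale
        omega = sigma2 * (np.outer(dinv, dinv) * (L @ L.T))
        return MixedLMResult(
            beta=beta,
            beta_cov=beta_cov,
            omega=omega,
            sigma2=sigma2,
            loglik=-0.5 * crit,
            n_obs=self.n,
            n_groups=self.n_groups,
            n_fixed=self.p,
            theta=theta,
            converged=converged,
        )


def reml_fit(y, X, Z, groups, *, omega_zero: bool = False,
             starts=DEFAULT_STARTS) -> MixedLMResult:
    """Fit the mixed model by REML; see :class:`REMLProblem`."""
    return REMLProblem(y, X, Z, groups, omega_zero=omega_zero).fit(starts=starts)
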