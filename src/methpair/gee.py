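"""Gaussian GEE with exchangeable working correlation and sandwich variance.

Marginal linear regression for family-clustered observations, estimated with
generalized estimating equations (GEE) in the Liang–Zeger moment form: iterate
between solving the estimating equations under a block-exchangeable working
covariance and updating the dispersion and working-correlation parameters from
Pearson residuals.  Standard errors come from the robust (sandwich) estimator,
which is consistent even when the working correlation is wrong — the reason
GEE is the field's standard tool for twin-family methylation data.

When every observation is its own cluster the working correlation is vacuous
and the fit reduces exactly to ordinary least squares; on z-scored inputs the
slope of a one-predictor model is then the Pearson correlation.  This identity
is what lets the slope of a pair-mate regression on standardized methylation
values be read as a per-CpG correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import MethpairError

__all__ = ["ExchangeableGEE", "GEEFit", "fit_gee_exchangeable", "ZeroVarianceError"]


class ZeroVarianceError(MethpairError):
    """The predictor has zero variance; the slope is undefined."""


@dataclass
class GEEFit:
    """Result of a single one-predictor exchangeable GEE fit.

    Attributes
    ----------
    intercept, slope : float
        Coefficients of ``y = b0 + b1·x`` (identity link).  On standardized
        inputs the slope is the correlation estimate.
    alpha_working : float
        Exchangeable working correlation (moment estimate, clamped to its
        positive-definiteness range).
    phi : float
        Dispersion: mean squared Pearson residual with denominator N − p.
    robust_se : float
        Liang–Zeger sandwich standard error of the slope.
    naive_se : float
        Model-based standard error of the slope.
    n_iterations : int
        Number of coefficient updates performed.
    converged : bool
        Whether the max coefficient change fell below the tolerance.
    n_clusters, n_obs : int
    alpha_clamped : bool
        True when the moment estimate of alpha fell outside the valid range
        and was clamped.
    """

    intercept: float
    slope: float
    alpha_working: float
    phi: float
    robust_se: float
    naive_se: float
    n_iterations: int
    converged: bool
    n_clusters: int
    n_obs: int
    alpha_clamped: bool = False


class ExchangeableGEE(BaseEstimator, RegressorMixin):
    """Gaussian-family GEE regressor with exchangeable working correlation.

    Parameters
    ----------
    max_iter : int, default 100
        Maximum number of coefficient updates.
    tol : float, default 1e-6
        Convergence tolerance on the max absolute coefficient change.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope coefficients.
    intercept_ : float
    alpha_ : float
        Working exchangeable correlation.
    phi_ : float
        Dispersion estimate.
    cov_robust_, cov_naive_ : ndarray of shape (p, p)
        Sandwich and model-based covariance of (intercept, coefs).
    robust_se_, naive_se_ : ndarray of shape (n_features,)
        Standard errors of the slopes.
    n_iter_ : int
    converged_ : bool
    n_clusters_, n_obs_ : int
    alpha_clamped_ : bool

    Notes
    -----
    The exchangeable working covariance for a cluster of size :math:`n_i` is
    :math:`V_i = \\phi[(1-\\alpha)I + \\alpha J]`, inverted in closed form via
    :math:`V_i^{-1} \\propto I - \\frac{\\alpha}{1+(n_i-1)\\alpha} J`.  All
    per-cluster sums are accumulated with segment operations, so a fit costs
    O(N p²) per iteration regardless of the number of clusters.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, groups=None):
        """Fit the GEE.

        Parameters
        ----------
        X : array-like of shape (n_obs,) or (n_obs, n_features)
        y : array-like of shape (n_obs,)
        groups : array-like of shape (n_obs,), optional
            Cluster labels (e.g. family ids).  ``None`` makes every
            observation its own cluster (reduces to OLS).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        if y.shape[0] != n:
            raise MethpairError(f"X has {n} rows but y has {y.shape[0]}")
        if n < 3:
            raise MethpairError("GEE needs at least 3 observations")
        if np.any(X.std(axis=0) == 0):
            raise ZeroVarianceError("a predictor column has zero variance")

        if groups is None:
            codes = np.arange(n)
        else:
            _, codes = np.unique(np.asarray(groups), return_inverse=True)
        m = int(codes.max()) + 1
        sizes = np.bincount(codes, minlength=m).astype(float)
        max_size = int(sizes.max())

        D = np.column_stack([np.ones(n), X])  # design incl. intercept
        p = k + 1
        # pair count available to the alpha moment estimator
        n_pairs_total = float(np.sum(sizes * (sizes - 1.0) / 2.0))

        # initial fit: independence working correlation (OLS)
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        alpha = 0.0
        phi = 1.0
        clamped = False
        converged = False
        n_iter = 0

        # alpha must keep every V_i positive definite; a small margin keeps
        # the closed-form inverse well conditioned at the boundary
        alpha_lo = -1.0 / (max_size - 1.0) + 1e-3 if max_size > 1 else -1.0 + 1e-3
        alpha_hi = 1.0 - 1e-3

        for n_iter in range(1, self.max_iter + 1):
            e = y - D @ beta
            phi = float(e @ e) / max(n - p, 1)
            if phi <= 0:
                phi = np.finfo(float).tiny
            # moment estimator of alpha from within-cluster residual products
            Se = np.bincount(codes, weights=e, minlength=m)
            Se2 = np.bincount(codes, weights=e * e, minlength=m)
            cross = float(np.sum((Se * Se - Se2) / 2.0))
            denom = phi * max(n_pairs_total - p, 1.0)
            alpha_new = cross / denom if n_pairs_total > 0 else 0.0
            if alpha_new < alpha_lo or alpha_new > alpha_hi:
                clamped = True
            alpha = float(np.clip(alpha_new, alpha_lo, alpha_hi))

            beta_new = self._solve(D, y, codes, m, sizes, alpha)
            delta = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            if delta < self.tol:
                converged = True
                break

        # final residuals / dispersion at the converged coefficients
        e = y - D @ beta
        phi = float(e @ e) / max(n - p, 1)
        if phi <= 0:
            phi = np.finfo(float).tiny

        bread, meat = self._bread_and_meat(D, e, codes, m, sizes, alpha, phi)
        bread_inv = np.linalg.inv(bread)
        cov_robust = bread_inv @ meat @ bread_inv
        cov_naive = bread_inv

        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.alpha_ = alpha
        self.phi_ = phi
        self.cov_robust_ = cov_robust
        self.cov_naive_ = cov_naive
        self.robust_se_ = np.sqrt(np.diag(cov_robust))[1:]
        self.naive_se_ = np.sqrt(np.diag(cov_naive))[1:]
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_clusters_ = m
        self.n_obs_ = n
        self.alpha_clamped_ = clamped
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _cluster_colsums(M: np.ndarray, codes: np.ndarray, m: int) -> np.ndarray:
        """(m, p) matrix of within-cluster column sums of M."""
        out = np.zeros((m, M.shape[1]))
        np.add.at(out, codes, M)
        return out

    def _solve(self, D, y, codes, m, sizes, alpha):
        # b = (Σ D_i' R_i⁻¹ D_i)⁻¹ Σ D_i' R_i⁻¹ y_i ; phi cancels
        g = alpha / (1.0 + (sizes - 1.0) * alpha)  # per-cluster J-weight
        SD = self._cluster_colsums(D, codes, m)
        Sy = np.bincount(codes, weights=y, minlength=m)
        A = D.T @ D - (SD * g[:, None]).T @ SD
        r = D.T @ y - SD.T @ (g * Sy)
        return np.linalg.solve(A, r)

    def _bread_and_meat(self, D, e, codes, m, sizes, alpha, phi):
        g = alpha / (1.0 + (sizes - 1.0) * alpha)
        scale = 1.0 / (phi * (1.0 - alpha))
        SD = self._cluster_colsums(D, codes, m)
        Se = np.bincount(codes, weights=e, minlength=m)
        bread = scale * (D.T @ D - (SD * g[:, None]).T @ SD)
        # u_i = D_i' V_i⁻¹ e_i, accumulated per cluster
        De = self._cluster_colsums(D * e[:, None], codes, m)
        U = scale * (De - SD * (g * Se)[:, None])
        meat = U.T @ U
        return bread, meat


def fit_gee_exchangeable(
    x, y, cluster, max_iter: int = 100, tol: float = 1e-6
) -> GEEFit:
    """Fit ``y = b0 + b1·x`` by exchangeable GEE; thin wrapper over
    :class:`ExchangeableGEE` for the one-predictor case.

    Missing values must already be removed; ``cluster`` carries family labels.
    """
    est = ExchangeableGEE(max_iter=max_iter, tol=tol).fit(
        np.asarray(x, dtype=float), np.asarray(y, dtype=float), groups=cluster
    )
    return GEEFit(
        intercept=est.intercept_,
        slope=float(est.coef_[0]),
        alpha_working=est.alpha_,
        phi=est.phi_,
        robust_se=float(est.robust_se_[0]),
        naive_se=float(est.naive_se_[0]),
        n_iterations=est.n_iter_,
        converged=est.converged_,
        n_clusters=est.n_clusters_,
        n_obs=est.n_obs_,
        alpha_clamped=est.alpha_clamped_,
    )
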