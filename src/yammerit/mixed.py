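"""Single-kinship linear mixed model solved in the eigenspace of K.

Model: y = X b + u + e with u ~ N(0, sigma_g^2 K), e ~ N(0, sigma_e^2 I).
Writing K = U S U' and rotating by U' makes the covariance diagonal,
sigma_g^2 (S + delta) with delta = sigma_e^2 / sigma_g^2, so REML in
delta reduces to weighted least squares — the exact one-dimensional
formulation used by EMMA-class association solvers. The variance ratio
is found on a grid of ln(delta) in [-10, 10] (step 0.1) followed by
bounded local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class KinshipEigen:
    U: np.ndarray
    S: np.ndarray

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipEigen":
        S, U = np.linalg.eigh((K + K.T) / 2.0)
        return cls(U=U, S=np.clip(S, 0.0, None))


def _reml_neg_loglik(log_delta: float, yr: np.ndarray, Xr: np.ndarray, S: np.ndarray) -> float:
    """-2 * restricted log-likelihood (up to a constant) at delta."""
    delta = np.exp(log_delta)
    w = S + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    n, p = Xr.shape
    df = n - p
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return np.inf
    return df * np.log(rss / df) + np.sum(np.log(w)) + logdet_xwx


@dataclass
class RemlFit:
    delta: float
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    eigen: KinshipEigen
    yr: np.ndarray
    Xr: np.ndarray

    @property
    def h2(self) -> float:
        """Proportion of variance attached to the kinship term."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def fit_reml_kinship(
    y: np.ndarray, X: np.ndarray, K: np.ndarray | KinshipEigen
) -> RemlFit:
    """REML estimates of (delta, sigma_g^2, sigma_e^2, beta) for one kinship."""
    eigen = K if isinstance(K, KinshipEigen) else KinshipEigen.from_kinship(K)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    yr = eigen.U.T @ y
    Xr = eigen.U.T @ X

    grid = np.arange(-10.0, 10.0 + 1e-9, 0.1)
    vals = np.array([_reml_neg_loglik(g, yr, Xr, eigen.S) for g in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(yr, Xr, eigen.S), method="bounded"
    )
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid[i])
    delta = float(np.exp(log_delta))

    w = eigen.S + delta
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    n, p = Xr.shape
    sigma_g2 = float(r @ (r / w)) / (n - p)
    sigma_e2 = sigma_g2 * delta
    return RemlFit(
        delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_e2, beta=beta, eigen=eigen, yr=yr, Xr=Xr
    )


def gblup(y: np.ndarray, X: np.ndarray, K: np.ndarray | KinshipEigen) -> tuple[np.ndarray, RemlFit]:
    """Genomic BLUP of the random effect u given one kinship matrix.

    u_hat = K V^{-1} sigma_g^2 (y - X beta) evaluated in the eigenbasis:
    U diag(S / (S + delta)) U' (y - X beta).
    """
    fit = fit_reml_kinship(y, X, K)
    resid_rot = fit.yr - fit.Xr @ fit.beta
    shrink = fit.eigen.S / (fit.eigen.S + fit.delta)
    u_hat = fit.eigen.U @ (shrink * resid_rot)
    return u_hat, fit
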