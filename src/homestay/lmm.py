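"""Linear mixed model with independent variance components, REML.

Random structure: any number of components, each a dense design block
``Z_k`` (e.g. subject indicators, day indicators, subject-grouped slopes)
with its own variance ``sigma2 * gamma_k``; components are mutually
independent with diagonal covariance.  The residual variance is profiled
out analytically and the REML criterion is maximised over the log variance
ratios with Nelder-Mead, using the Woodbury identity so every evaluation is
O(n q^2) for q total random-effect columns.

This is the profiled form of the criterion lme4 optimises for crossed
random intercepts; a general-purpose optimizer over the same likelihood
(statsmodels MixedLM) is used as an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["LMMResult", "fit_reml", "ConvergenceError"]

_GAMMA_FLOOR = -20.0  # log-scale lower clamp for variance ratios


class ConvergenceError(RuntimeError):
    """The REML optimiser failed to converge."""


@dataclass
class LMMResult:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    vcomp: dict[str, float]       # variance per random component
    sigma2: float                 # residual variance
    loglik: float                 # REML log-likelihood
    n_obs: int
    df_resid: int
    singular: bool
    converged: bool
    cov_beta: np.ndarray


def _reml_pieces(x_log_gamma: np.ndarray, y: np.ndarray, X: np.ndarray,
                 Z: np.ndarray, comp_idx: np.ndarray):
    n, p = X.shape
    gamma = np.exp(np.maximum(x_log_gamma, _GAMMA_FLOOR))
    A = Z * np.sqrt(gamma[comp_idx])
    q = A.shape[1]
    K = np.eye(q) + A.T @ A
    cho = linalg.cho_factor(K, lower=True)

    def w_mult(M):
        return M - A @ linalg.cho_solve(cho, A.T @ M)

    WX = w_mult(X)
    Wy = w_mult(y)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    beta = linalg.solve(XtWX, XtWy, assume_a="pos")
    r = y - X @ beta
    q2 = float(r @ w_mult(r))
    sigma2 = q2 / (n - p)
    logdet_k = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    sign, logdet_x = np.linalg.slogdet(XtWX)
    crit = (n - p) * np.log(q2) + logdet_k + logdet_x
    return crit, beta, sigma2, XtWX, gamma, logdet_k, logdet_x


def fit_reml(y: np.ndarray, X: np.ndarray, z_blocks: list[tuple[str, np.ndarray]],
             terms: list[str] | None = None, tol: float = 1e-10,
             maxiter: int = 2000) -> LMMResult:
    """Fit ``y = X beta + sum_k Z_k b_k + e`` by REML.

    Parameters
    ----------
    z_blocks
        ``(name, Z_k)`` pairs; each ``Z_k`` is an (n, q_k) design block whose
        coefficients share one variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    names = [nm for nm, _ in z_blocks]
    Z = np.hstack([np.asarray(b, dtype=float) for _, b in z_blocks])
    comp_idx = np.concatenate([np.full(b.shape[1], k)
                               for k, (_, b) in enumerate(z_blocks)])
    m = len(z_blocks)

    def objective(x):
        try:
            return _reml_pieces(x, y, X, Z, comp_idx)[0]
        except np.linalg.LinAlgError:
            return np.inf

    # variance components started at ~10% of outcome variance (ratio 1/9)
    x0 = np.full(m, np.log(1.0 / 9.0))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": tol,
                                     "maxiter": maxiter, "maxfev": maxiter})
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"REML optimisation failed: {res.message}")
    x_hat = np.maximum(res.x, _GAMMA_FLOOR)
    crit, beta, sigma2, XtWX, gamma, logdet_k, logdet_x = _reml_pieces(
        x_hat, y, X, Z, comp_idx)

    cov_beta = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    dfe = n - p
    loglik = -0.5 * (dfe * (np.log(2.0 * np.pi * sigma2) + 1.0)
                     + logdet_k + logdet_x - p * np.log(sigma2))
    singular = bool(np.any(gamma < 1e-6))
    return LMMResult(
        terms=terms or [f"x{j}" for j in range(p)],
        beta=beta, se=se, z=zstat, p=pvals,
        vcomp={nm: float(sigma2 * g) for nm, g in zip(names, gamma)},
        sigma2=float(sigma2), loglik=float(loglik),
        n_obs=n, df_resid=dfe, singular=singular,
        converged=bool(res.success or np.isfinite(res.fun)),
        cov_beta=cov_beta)
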