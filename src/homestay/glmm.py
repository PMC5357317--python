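"""Mixed-effects logistic regression via the Laplace approximation.

Same random structure as :mod:`homestay.lmm`: independent variance
components over dense design blocks.  For fixed variance parameters the
joint penalised log-likelihood is maximised over (beta, b) with damped
Newton steps; the Laplace-approximate marginal likelihood is then optimised
over the log standard deviations with Nelder-Mead.  Fixed effects are
profiled through the joint mode (the fast scheme lme4 uses as nAGQ=0),
which recovers simulated coefficients well inside the tolerances this
pipeline needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats
from scipy.linalg import LinAlgWarning

__all__ = ["GLMMResult", "fit_laplace_logit", "SeparationError",
           "OneClassError", "ConvergenceError"]

_BETA_LIMIT = 30.0


class SeparationError(RuntimeError):
    """A coefficient diverged, indicating (quasi-)complete separation."""


class OneClassError(ValueError):
    """The outcome contains a single class."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class GLMMResult:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    vcomp: dict[str, float]
    loglik: float                 # Laplace-approximate marginal log-likelihood
    n_obs: int
    singular: bool
    converged: bool
    cov_beta: np.ndarray


def _joint_mode(y, M, p, pen, gamma0, max_newton=80):
    """Maximise the penalised Bernoulli log-likelihood over (beta, b)."""
    n, pq = M.shape
    gamma = gamma0.copy()

    def pen_ll(g):
        eta = M @ g
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * g @ (pen * g))

    cur = pen_ll(gamma)
    for _ in range(max_newton):
        eta = M @ gamma
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = M.T @ (y - mu) - pen * gamma
        H = (M * w[:, None]).T @ M
        H[np.diag_indices_from(H)] += pen
        try:
            with warnings.catch_warnings():
                # near-zero variance components make H ill-conditioned while
                # the optimiser probes the boundary; the damped step handles it
                warnings.simplefilter("ignore", LinAlgWarning)
                step = linalg.solve(H, grad, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite Newton step")
        t = 1.0
        for _ in range(30):
            cand = gamma + t * step
            new = pen_ll(cand)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        gamma = gamma + t * step
        if abs(new - cur) < 1e-10 * (1.0 + abs(cur)):
            cur = new
            break
        cur = new
    return gamma, cur


def fit_laplace_logit(y: np.ndarray, X: np.ndarray,
                      z_blocks: list[tuple[str, np.ndarray]],
                      terms: list[str] | None = None,
                      maxiter: int = 400) -> GLMMResult:
    """Fit a logistic mixed model ``logit P(y=1) = X beta + sum_k Z_k b_k``."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if len(classes) < 2:
        raise OneClassError(f"outcome has a single class ({classes[0]:.0f})")
    names = [nm for nm, _ in z_blocks]
    Z = np.hstack([np.asarray(b, dtype=float) for _, b in z_blocks])
    comp_idx = np.concatenate([np.full(b.shape[1], k)
                               for k, (_, b) in enumerate(z_blocks)])
    q = Z.shape[1]
    M = np.hstack([X, Z])
    term_names = terms or [f"x{j}" for j in range(p)]

    state = {"gamma": np.zeros(p + q)}

    def neg_marginal(theta):
        sd = np.exp(np.clip(theta, -10.0, 5.0))
        d = sd[comp_idx] ** 2                      # prior variances per column
        pen = np.concatenate([np.zeros(p), 1.0 / d])
        gamma, cur = _joint_mode(y, M, p, pen, state["gamma"])
        state["gamma"] = gamma
        b = gamma[p:]
        eta = M @ gamma
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        Hbb = (Z * w[:, None]).T @ Z
        Hbb[np.diag_indices_from(Hbb)] += 1.0 / d
        sign, logdet = np.linalg.slogdet(Hbb)
        if sign <= 0:
            return np.inf
        ll = (float(y @ eta - np.logaddexp(0.0, eta).sum())
              - 0.5 * float(b @ (b / d))
              - 0.5 * float(np.sum(np.log(d)))
              - 0.5 * logdet)
        return -ll

    x0 = np.full(len(z_blocks), np.log(0.5))
    res = optimize.minimize(neg_marginal, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8,
                                     "maxiter": maxiter, "maxfev": maxiter})
    theta = np.clip(res.x, -10.0, 5.0)
    neg_ll = neg_marginal(theta)
    gamma = state["gamma"]
    beta = gamma[:p]
    if np.max(np.abs(beta)) > _BETA_LIMIT:
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"coefficient for term {term_names[j]!r} diverged "
            f"(|beta|={abs(beta[j]):.1f}); data are likely separated")

    sd = np.exp(theta)
    d = sd[comp_idx] ** 2
    eta = M @ gamma
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (M * w[:, None]).T @ M
    H[np.diag_indices_from(H)] += np.concatenate([np.zeros(p), 1.0 / d])
    cov = np.linalg.inv(H)
    cov_beta = cov[:p, :p]
    se = np.sqrt(np.diag(cov_beta))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    vcomp = {nm: float(np.exp(2.0 * th)) for nm, th in zip(names, theta)}
    return GLMMResult(terms=term_names, beta=beta, se=se, z=zstat, p=pvals,
                      vcomp=vcomp, loglik=float(-neg_ll), n_obs=n,
                      singular=bool(np.any(sd < 1e-3)),
                      converged=bool(res.success), cov_beta=cov_beta)
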