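"""Minimal proportional-odds (cumulative logit) likelihood machinery.

Used by the chained-imputation engine, which needs thousands of small
ordered-logit fits per run; a dedicated Newton implementation with analytic
gradient and Hessian keeps that tractable.  Parameterisation:
P(Y <= j | x) = sigmoid(theta_j - x beta).  Equivalence with the reference
ordered-logit implementation is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special


def _pieces(params, X, y_codes, k):
    """Per-observation upper/lower threshold cdf pieces for y's category."""
    n, p = X.shape
    beta, theta = params[:p], params[p:]
    eta = X @ beta
    theta_pad = np.concatenate([[-np.inf], theta, [np.inf]])
    z_u = theta_pad[y_codes + 1] - eta
    z_l = theta_pad[y_codes] - eta
    F_u = special.expit(z_u)
    F_l = special.expit(z_l)
    f_u = np.where(np.isfinite(z_u), F_u * (1.0 - F_u), 0.0)
    f_l = np.where(np.isfinite(z_l), F_l * (1.0 - F_l), 0.0)
    fp_u = np.where(np.isfinite(z_u), f_u * (1.0 - 2.0 * F_u), 0.0)
    fp_l = np.where(np.isfinite(z_l), f_l * (1.0 - 2.0 * F_l), 0.0)
    pi = np.clip(F_u - F_l, 1e-12, None)
    return eta, pi, f_u, f_l, fp_u, fp_l


def neg_loglik_grad_hess(params, X, y_codes, k, ridge=0.0, want_hess=True):
    """Penalised negative log-likelihood with analytic gradient and Hessian."""
    n, p = X.shape
    km1 = k - 1
    _, pi, f_u, f_l, fp_u, fp_l = _pieces(params, X, y_codes, k)
    nll = -float(np.sum(np.log(pi)))

    w_u = f_u / pi
    w_l = f_l / pi
    # gradient
    g_beta = (w_u - w_l) @ X  # d(-ll)/dbeta = sum (f_u - f_l)/pi * x
    g_theta = np.zeros(km1)
    has_u = y_codes <= km1 - 1
    has_l = y_codes >= 1
    np.add.at(g_theta, y_codes[has_u], -w_u[has_u])
    np.add.at(g_theta, y_codes[has_l] - 1, w_l[has_l])
    grad = np.concatenate([g_beta, g_theta])

    if ridge > 0:
        beta = params[:p]
        nll += 0.5 * ridge * float(beta @ beta)
        grad[:p] += ridge * beta
    if not want_hess:
        return nll, grad, None

    # second-derivative pieces of -ll
    d_uu = -(fp_u / pi) + w_u**2            # wrt theta_u twice
    d_ll_ = (fp_l / pi) + w_l**2            # wrt theta_l twice
    d_ul = -(w_u * w_l)                     # theta_u, theta_l cross
    d_ee = -(fp_u - fp_l) / pi + (w_u - w_l) ** 2  # wrt eta twice
    d_eu = (fp_u / pi) - (w_u - w_l) * w_u  # eta, theta_u
    d_el = -(fp_l / pi) + (w_u - w_l) * w_l  # eta, theta_l

    m = p + km1
    H = np.zeros((m, m))
    H[:p, :p] = (X * d_ee[:, None]).T @ X
    # beta-theta blocks: d eta/d beta = x, chain through -x
    B_u = np.zeros((n, km1))
    B_u[has_u, y_codes[has_u]] = 1.0
    B_l = np.zeros((n, km1))
    B_l[has_l, y_codes[has_l] - 1] = 1.0
    H_bt = X.T @ (B_u * d_eu[:, None] + B_l * d_el[:, None])
    H[:p, p:] = H_bt
    H[p:, :p] = H_bt.T
    T = np.zeros((km1, km1))
    np.add.at(T, (y_codes[has_u], y_codes[has_u]), d_uu[has_u])
    np.add.at(T, (y_codes[has_l] - 1, y_codes[has_l] - 1), d_ll_[has_l])
    both = has_u & has_l
    np.add.at(T, (y_codes[both], y_codes[both] - 1), d_ul[both])
    np.add.at(T, (y_codes[both] - 1, y_codes[both]), d_ul[both])
    H[p:, p:] = T
    if ridge > 0:
        H[:p, :p] += ridge * np.eye(p)
    return nll, grad, H


def fit_polr(X: np.ndarray, y_codes: np.ndarray, k: int, ridge: float = 1e-4,
             max_var: float = 25.0, tol: float = 1e-8, maxiter: int = 50):
    """Newton maximum-likelihood fit; returns (params, cov, converged).

    ``params`` stacks (beta, thresholds).  A tiny ridge on the slopes keeps
    near-separated fits bounded.  ``cov`` inverts the analytic Hessian at the
    optimum, eigenvalue-clipped to positive definite with per-direction
    variance capped at ``max_var`` (rare categories leave thresholds nearly
    flat; an unbounded draw there would be meaningless).
    """
    n, p = X.shape
    counts = np.bincount(y_codes, minlength=k)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    params = np.concatenate([np.zeros(p), special.logit(cum)])
    nll, grad, H = neg_loglik_grad_hess(params, X, y_codes, k, ridge)
    converged = False
    for _ in range(maxiter):
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the penalised objective
        scale = 1.0
        for _ in range(30):
            trial = params - scale * step
            theta = trial[p:]
            if np.all(np.diff(theta) > 0) or theta.size < 2:
                t_nll, t_grad, t_H = neg_loglik_grad_hess(trial, X, y_codes, k, ridge)
                if t_nll <= nll + 1e-12:
                    break
            scale *= 0.5
        else:
            break
        params, nll, grad, H = trial, t_nll, t_grad, t_H
        if np.max(np.abs(grad)) < tol * max(1.0, abs(nll)):
            converged = True
            break
    if not converged:
        # fall back to a quasi-Newton polish from the best point so far
        res = optimize.minimize(
            lambda q: neg_loglik_grad_hess(q, X, y_codes, k, ridge, want_hess=False)[:2],
            params, jac=True, method="L-BFGS-B", options={"maxiter": 500},
        )
        params = res.x
        converged = bool(res.success)
        _, _, H = neg_loglik_grad_hess(params, X, y_codes, k, ridge)
    theta = params[p:]
    if not converged or np.any(np.diff(theta) <= 0) or not np.all(np.isfinite(params)):
        raise RuntimeError("proportional-odds fit failed to converge")
    ev, U = np.linalg.eigh(0.5 * (H + H.T))
    var = np.minimum(1.0 / np.maximum(ev, 1.0 / max_var), max_var)
    cov = (U * var) @ U.T
    return params, cov, converged


def predict_probs(params: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Category probabilities (n x k) under the fitted model."""
    p = X.shape[1]
    beta, theta = params[:p], params[p:]
    z = theta[None, :] - (X @ beta)[:, None]
    F = special.expit(z)
    Fpad = np.hstack([np.zeros((X.shape[0], 1)), F, np.ones((X.shape[0], 1))])
    probs = np.diff(Fpad, axis=1)
    probs = np.clip(probs, 1e-12, None)
    return probs / probs.sum(axis=1, keepdims=True)
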