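"""REML fitting by BFGS and standard-error machinery.

The factor loadings are fitted by maximizing the restricted log-likelihood
with a BFGS quasi-Newton iteration and an Armijo backtracking line search.
A trial step at which any eigen-block covariance ``Sigma_j = lam_j V_G + V_E``
is singular is treated as infeasible and backtracked, so every evaluated
point yields positive-semidefinite V_G and V_E and a defined likelihood.

After convergence the observed information (negative Hessian) is formed by
central finite differences of the analytic gradient; its pseudo-inverse is
the parameter covariance, and standard errors of heritabilities and genetic
correlations follow by the delta method with analytic Jacobians through
V = C C'.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg

from .model import (
    CollinearCovariatesError,
    CovariateSet,
    FactorCoefficients,
    LikelihoodUndefinedError,
    PhenotypeSet,
    RotatedModel,
    _tril_indices_colmajor,
    reml_loglik_grad,
    reml_gradient,
)

__all__ = ["FitResult", "initialize", "fit", "parameter_covariance", "delta_se"]


@dataclasses.dataclass
class FitResult:
    theta_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    grad_norm: float
    param_cov: np.ndarray | None = None
    info_clipped: bool = False
    n_traits: int = 0

    @property
    def coefficients(self) -> FactorCoefficients:
        return FactorCoefficients.unpack(self.theta_hat, self.n_traits)


def initialize(ph: PhenotypeSet, cov: CovariateSet) -> FactorCoefficients:
    """Deterministic starting point: split the residual covariance 50/50.

    Phenotypes are residualized on their design per trait; the residual
    covariance S is split equally between the genetic and environmental
    parts, each loaded as chol(S/2 + eps I) with a small ridge so the start
    is strictly positive definite (implied starting h^2 = 1/2 per trait).
    """
    Y = ph.Y.copy()
    for t, X in enumerate(cov.designs):
        if X.shape[1]:
            beta, *_ = np.linalg.lstsq(X, Y[:, t], rcond=None)
            Y[:, t] = Y[:, t] - X @ beta
    S = np.cov(Y, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    eps = 1e-4 * float(np.mean(np.diag(S)))
    try:
        C = np.linalg.cholesky(S / 2.0 + eps * np.eye(S.shape[0]))
    except np.linalg.LinAlgError:
        raise ValueError("residual covariance is not positive definite") from None
    return FactorCoefficients(C_G=C.copy(), C_E=C.copy())


def _safe_eval(rm: RotatedModel, theta: np.ndarray, t: int):
    """Likelihood and gradient, or None for an infeasible point."""
    try:
        ll, g = reml_loglik_grad(rm, FactorCoefficients.unpack(theta, t))
    except (LikelihoodUndefinedError, np.linalg.LinAlgError):
        return None
    if not np.isfinite(ll) or not np.all(np.isfinite(g)):
        return None
    return ll, g


def fit(
    rm: RotatedModel,
    init: FactorCoefficients,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> FitResult:
    """Maximize the restricted log-likelihood over the packed loadings.

    BFGS on -loglik with Armijo backtracking (c1 = 1e-4, shrink 0.5);
    convergence when max|gradient| / (1 + |loglik|) <= tol.  Returns the
    best point seen; hitting ``max_iter`` yields a warning, not an error.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t = init.n_traits
    theta = init.pack()
    ev = _safe_eval(rm, theta, t)
    if ev is None:
        raise ValueError("restricted likelihood is undefined at the starting point")
    ll, g = ev

    p = theta.size
    H = np.eye(p)                     # inverse-Hessian approximation (of -ll)
    best_theta, best_ll, best_g = theta.copy(), ll, g.copy()
    n_iter = 0
    converged = _grad_small(g, ll, tol)

    while not converged and n_iter < max_iter:
        n_iter += 1
        direction = H @ g             # ascent direction
        if g @ direction <= 0:        # curvature lost; reset to steepest ascent
            H = np.eye(p)
            direction = g.copy()
        step = 1.0
        new = None
        for _ in range(60):
            cand = theta + step * direction
            ev = _safe_eval(rm, cand, t)
            if ev is not None and ev[0] >= ll + 1e-4 * step * (g @ direction):
                new = (cand, *ev)
                break
            step *= 0.5
        if new is None:               # no feasible improving step
            break
        theta_new, ll_new, g_new = new
        s = theta_new - theta
        yv = -(g_new - g)             # gradient change of -ll
        sy = s @ yv
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(yv):
            rho = 1.0 / sy
            I = np.eye(p)
            H = (I - rho * np.outer(s, yv)) @ H @ (I - rho * np.outer(yv, s)) \
                + rho * np.outer(s, s)
        theta, ll, g = theta_new, ll_new, g_new
        if ll > best_ll:
            best_theta, best_ll, best_g = theta.copy(), ll, g.copy()
        converged = _grad_small(g, ll, tol)

    if not converged:
        warnings.warn(
            f"REML did not converge in {n_iter} iterations "
            f"(scaled gradient {np.max(np.abs(best_g)) / (1 + abs(best_ll)):.2e})",
            stacklevel=2,
        )
    return FitResult(
        theta_hat=best_theta,
        loglik=best_ll,
        n_iter=n_iter,
        converged=converged,
        grad_norm=float(np.max(np.abs(best_g))),
        n_traits=t,
    )


def _grad_small(g: np.ndarray, ll: float, tol: float) -> bool:
    return float(np.max(np.abs(g))) / (1.0 + abs(ll)) <= tol


def parameter_covariance(
    rm: RotatedModel, fc_hat: FactorCoefficients
) -> tuple[np.ndarray, bool]:
    """Covariance of theta-hat from the observed information.

    The information is the negative Hessian of the restricted log-likelihood,
    formed by central finite differences of the analytic gradient with step
    1e-4 (1 + |theta_p|) per coordinate; the covariance is its pseudo-inverse,
    symmetrized and eigenvalue-clipped to positive semidefinite.  The second
    return value flags an indefinite information matrix.
    """
    t = fc_hat.n_traits
    theta = fc_hat.pack()
    p = theta.size
    Hmat = np.empty((p, p))
    for i in range(p):
        h = 1e-4 * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        gp = reml_gradient(rm, FactorCoefficients.unpack(tp, t))
        gm = reml_gradient(rm, FactorCoefficients.unpack(tm, t))
        Hmat[i] = (gp - gm) / (2.0 * h)
    info = -(Hmat + Hmat.T) / 2.0
    w, Q = np.linalg.eigh(info)
    clipped = bool(w.min() < -1e-6 * max(w.max(), 1e-300))
    if clipped:
        warnings.warn(
            "observed information is indefinite; clipping negative curvature",
            stacklevel=2,
        )
    w_pos = np.where(w > 1e-12 * max(w.max(), 0.0), w, np.inf)
    cov = (Q / w_pos) @ Q.T
    cov = (cov + cov.T) / 2.0
    wc = np.linalg.eigvalsh(cov)
    if wc.min() < 0:
        w2, Q2 = np.linalg.eigh(cov)
        cov = (Q2 * np.clip(w2, 0.0, None)) @ Q2.T
    return cov, clipped


def _dV_dtheta(C: np.ndarray) -> np.ndarray:
    """Jacobian d vec-ish V / d c_ab for V = C C', one T x T slab per parameter."""
    t = C.shape[0]
    rows, cols = _tril_indices_colmajor(t)
    out = np.zeros((len(rows), t, t))
    for p, (a, b) in enumerate(zip(rows, cols)):
        out[p, a, :] += C[:, b]
        out[p, :, a] += C[:, b]
    return out


def delta_se(
    fc_hat: FactorCoefficients, param_cov: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method standard errors of h^2 per trait and of r_g per pair.

    h^2(t) = vG_tt / (vG_tt + vE_tt) and r_g(s,t) = vG_st / sqrt(vG_ss vG_tt);
    Jacobians are chained analytically through V = C C'.  Diagonal r_g SEs
    are zero; traits with vG_tt = 0 get NaN r_g SEs (flagged upstream).
    """
    t = fc_hat.n_traits
    V_G, V_E = fc_hat.V_G, fc_hat.V_E
    half = t * (t + 1) // 2
    dVG = np.zeros((2 * half, t, t))
    dVE = np.zeros((2 * half, t, t))
    dVG[:half] = _dV_dtheta(fc_hat.C_G)
    dVE[half:] = _dV_dtheta(fc_hat.C_E)

    dG = np.diag(V_G)
    dE = np.diag(V_E)
    tot = dG + dE
    if np.any(tot <= 0):
        raise ValueError("degenerate trait with zero total variance")

    # heritabilities
    J_h = (dVG[:, np.arange(t), np.arange(t)] * dE
           - dVE[:, np.arange(t), np.arange(t)] * dG) / tot**2
    se_h2 = np.sqrt(np.maximum(np.einsum("pt,pq,qt->t", J_h, param_cov, J_h), 0.0))

    # genetic correlations
    se_rg = np.zeros((t, t))
    for s in range(t):
        for u in range(s + 1, t):
            if dG[s] <= 0 or dG[u] <= 0:
                se_rg[s, u] = se_rg[u, s] = np.nan
                continue
            denom = np.sqrt(dG[s] * dG[u])
            r = V_G[s, u] / denom
            J = (dVG[:, s, u] / denom
                 - 0.5 * r * (dVG[:, s, s] / dG[s] + dVG[:, u, u] / dG[u]))
            var = float(J @ param_cov @ J)
            se_rg[s, u] = se_rg[u, s] = np.sqrt(max(var, 0.0))
    return se_h2, se_rg
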