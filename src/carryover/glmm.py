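"""Poisson log-link mixed models with a single year random intercept.

Maximum-likelihood fitting via the Laplace approximation to the marginal
likelihood: the year-intercept modes are profiled out by inner Newton
iterations (the per-group objective is strictly concave), and the outer
optimisation runs over (beta, log sigma_u) with a quasi-Newton method.

The candidate set mirrors the eight competing structures of the carry-over
analysis: linear and quadratic standardized mass, standardized detrended
June NAO, and their interactions, always with a year random intercept.

An adaptive Gauss-Hermite evaluator of the same marginal likelihood is
provided (``agq_loglik``) as a higher-order check on the Laplace
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp

__all__ = [
    "ModelSpec",
    "FitResult",
    "GLMMControl",
    "RankDeficientError",
    "build_candidate_set",
    "fit_poisson_glmm",
    "predict_response",
    "agq_loglik",
    "laplace_loglik",
    "TERMS",
]

#: recognised fixed-effect terms, canonical order
TERMS = ("mass", "nao", "mass:nao", "mass2", "mass2:nao")

#: marginality: a term may only appear with these companions present
_MARGINALITY = {
    "mass:nao": {"mass", "nao"},
    "mass2:nao": {"mass", "nao", "mass2"},
}


class RankDeficientError(ValueError):
    """Raised when the fixed-effect design matrix is not full column rank."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure (intercept and year RE implicit).

    ``k`` counts 1 (intercept) + number of terms + 1 (random-effect
    variance), the convention that reproduces the published parameter
    counts.
    """

    name: str
    terms: tuple

    def __post_init__(self):
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        for t, needed in _MARGINALITY.items():
            if t in self.terms and not needed <= set(self.terms):
                raise ValueError(f"{t} requires {sorted(needed)} in the model")
        # canonical order, no duplicates
        ordered = tuple(t for t in TERMS if t in self.terms)
        if ordered != self.terms:
            object.__setattr__(self, "terms", ordered)

    @property
    def k(self) -> int:
        return 1 + len(self.terms) + 1

    @property
    def coef_names(self) -> tuple:
        return ("intercept",) + self.terms

    def design(self, mass_z, nao_z) -> np.ndarray:
        """Fixed-effect design matrix at standardized covariates.

        Squared and interaction columns are built from the standardized main
        effects (standardize-then-square)."""
        m = np.asarray(mass_z, dtype=float)
        n = np.asarray(nao_z, dtype=float)
        cols = {"mass": m, "nao": n, "mass:nao": m * n, "mass2": m**2, "mass2:nao": m**2 * n}
        X = np.column_stack([np.ones_like(m)] + [cols[t] for t in self.terms])
        return X


def build_candidate_set() -> list[ModelSpec]:
    """The eight competing models of the carry-over analysis."""
    return [
        ModelSpec("Mass", ("mass",)),
        ModelSpec("NAO", ("nao",)),
        ModelSpec("Mass + NAO", ("mass", "nao")),
        ModelSpec("Mass * NAO", ("mass", "nao", "mass:nao")),
        ModelSpec("Mass^2", ("mass", "mass2")),
        ModelSpec("Mass^2 + NAO", ("mass", "nao", "mass2")),
        ModelSpec("Mass^2 * NAO", ("mass", "nao", "mass2", "mass2:nao")),
        ModelSpec("Null", ()),
    ]


@dataclass
class GLMMControl:
    """Numerical controls for the Laplace fit."""

    inner_tol: float = 1e-10  # gradient tolerance of the mode-finding Newton
    inner_max_iter: int = 100
    grad_tol: float = 1e-6  # outer gradient tolerance
    max_iter: int = 500
    fd_step: float = 1e-6  # central-difference step for the outer gradient
    sigma_floor: float = 1e-4  # below this, report a boundary fit sigma_u = 0


@dataclass
class FitResult:
    """A fitted candidate model."""

    spec: ModelSpec
    beta: np.ndarray
    se: Optional[np.ndarray]
    sigma_u: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    u_modes: Optional[np.ndarray] = None
    message: str = ""

    @property
    def coef(self) -> dict:
        return dict(zip(self.spec.coef_names, self.beta.tolist()))

    @property
    def coef_se(self) -> dict:
        if self.se is None:
            return {}
        return dict(zip(self.spec.coef_names, self.se.tolist()))


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    return codes.astype(np.int64), len(uniques)


def _poisson_ll_fixed(y, eta):
    return float(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())


def _modes(eta0, y, g, ngroups, sigma2, tol, max_iter, u0=None):
    """Newton solve for the per-group random-intercept modes.

    The joint log-density is strictly concave in u, so damped Newton with a
    step clip converges globally."""
    sy = np.bincount(g, weights=y, minlength=ngroups)
    u = np.zeros(ngroups) if u0 is None else u0.copy()
    exp_eta0_sum = None  # recomputed each step (depends on u)
    for _ in range(max_iter):
        mu = np.exp(eta0 + u[g])
        smu = np.bincount(g, weights=mu, minlength=ngroups)
        grad = sy - smu - u / sigma2
        if np.max(np.abs(grad)) < tol:
            break
        hess = smu + 1.0 / sigma2
        u = u + np.clip(grad / hess, -4.0, 4.0)
    mu = np.exp(eta0 + u[g])
    smu = np.bincount(g, weights=mu, minlength=ngroups)
    return u, sy, smu


def laplace_loglik(beta, sigma_u, y, X, g, ngroups, control: GLMMControl | None = None,
                   u0=None, return_modes=False):
    """Laplace-approximate marginal log-likelihood at (beta, sigma_u).

    ``sigma_u = 0`` is the exact degenerate branch: a plain Poisson
    log-likelihood with the random intercepts pinned at zero.
    """
    control = control or GLMMControl()
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    eta0 = X @ beta
    if sigma_u == 0:
        ll = _poisson_ll_fixed(y, eta0)
        return (ll, np.zeros(ngroups)) if return_modes else ll
    sigma2 = sigma_u**2
    u, sy, smu = _modes(eta0, y, g, ngroups, sigma2, control.inner_tol,
                        control.inner_max_iter, u0=u0)
    joint = (
        y @ (eta0 + u[g])
        - smu.sum()
        - gammaln(y + 1).sum()
        - (u**2).sum() / (2 * sigma2)
    )
    ll = joint - 0.5 * np.log(sigma2 * (smu + 1.0 / sigma2)).sum()
    return (float(ll), u) if return_modes else float(ll)


def agq_loglik(beta, sigma_u, y, X, g, ngroups, n_points: int = 64,
               control: GLMMControl | None = None) -> float:
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Nodes are centred at the Laplace modes and scaled by the curvature there;
    64 points makes this effectively exact for these group sizes, so it
    serves as the reference the Laplace value is compared against.
    """
    control = control or GLMMControl()
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    eta0 = X @ beta
    if sigma_u == 0:
        return _poisson_ll_fixed(y, eta0)
    sigma2 = sigma_u**2
    u, sy, smu = _modes(eta0, y, g, ngroups, sigma2, control.inner_tol,
                        control.inner_max_iter)
    hess = smu + 1.0 / sigma2
    s = 1.0 / np.sqrt(hess)  # per-group adaptive scale

    z, w = np.polynomial.hermite.hermgauss(n_points)
    # per-group sufficient statistics of the integrand
    a = np.bincount(g, weights=y * eta0 - gammaln(y + 1), minlength=ngroups)
    smu0 = np.bincount(g, weights=np.exp(eta0), minlength=ngroups)
    # t_{jk} = u_j + sqrt(2) s_j z_k
    t = u[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]
    f = (
        a[:, None]
        + sy[:, None] * t
        - smu0[:, None] * np.exp(t)
        - t**2 / (2 * sigma2)
    )
    # integral_j = sqrt(2) s_j * sum_k w_k exp(z_k^2) exp(f_jk)
    log_int = logsumexp(f + z[None, :] ** 2 + np.log(w)[None, :], axis=1)
    ll = (log_int + 0.5 * np.log(2.0) + np.log(s)).sum() - ngroups * 0.5 * np.log(
        2 * np.pi * sigma2
    )
    return float(ll)


def _central_diff_grad(fun, x, step):
    grad = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = step
        grad[i] = (fun(x + e) - fun(x - e)) / (2 * step)
    return grad


def _numerical_hessian(fun, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * step**2)
    return H


def fit_poisson_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    control: GLMMControl | None = None,
    fix_sigma_u: float | None = None,
    start_beta: Sequence[float] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    ``data`` needs columns ``mass_z``, ``nao_z``, ``n_offspring`` and
    ``year``.  ``fix_sigma_u`` fits with the random-intercept SD held fixed
    (0 gives a plain Poisson GLM).  A boundary estimate (sigma_u below the
    control floor) is reported as a converged fit with ``sigma_u = 0``.
    """
    control = control or GLMMControl()
    y = data["n_offspring"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    X = spec.design(data["mass_z"].to_numpy(), data["nao_z"].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(f"design for model '{spec.name}' is rank deficient")
    g, ngroups = _group_codes(data["year"])
    if fix_sigma_u is None and ngroups < 2:
        raise ValueError("need >= 2 groups to estimate a random intercept")
    p = X.shape[1]

    if start_beta is not None:
        b0 = np.asarray(start_beta, dtype=float)
    else:
        b0 = np.zeros(p)
        b0[0] = np.log(max(y.mean(), 1e-3))

    if fix_sigma_u is not None:
        def nll(b):
            return -laplace_loglik(b, fix_sigma_u, y, X, g, ngroups, control)

        res = optimize.minimize(
            nll, b0, jac=lambda b: _central_diff_grad(nll, b, control.fd_step),
            method="BFGS",
            options={"gtol": control.grad_tol, "maxiter": control.max_iter},
        )
        beta = res.x
        ll = -res.fun
        H = _numerical_hessian(nll, beta)
        se = _safe_se(H)[:p]
        conv = _converged(res, ll)
        _, modes = laplace_loglik(beta, fix_sigma_u, y, X, g, ngroups, control,
                                  return_modes=True) if fix_sigma_u > 0 else (ll, np.zeros(ngroups))
        return FitResult(spec, beta, se, float(fix_sigma_u), float(ll), conv,
                         len(y), ngroups, u_modes=modes, message=res.message)

    x0 = np.append(b0, np.log(0.3))

    def nll_full(params):
        beta, log_sigma = params[:p], params[-1]
        sigma = float(np.exp(log_sigma))
        return -laplace_loglik(beta, sigma, y, X, g, ngroups, control)

    res = optimize.minimize(
        nll_full, x0, jac=lambda v: _central_diff_grad(nll_full, v, control.fd_step),
        method="BFGS",
        options={"gtol": control.grad_tol, "maxiter": control.max_iter},
    )
    beta = res.x[:p]
    sigma = float(np.exp(res.x[-1]))
    ll = -float(res.fun)
    conv = _converged(res, ll)

    if sigma < control.sigma_floor:
        # boundary: refit with sigma_u pinned at 0 (plain Poisson GLM)
        sub = fit_poisson_glmm(data, spec, control, fix_sigma_u=0.0, start_beta=beta)
        if sub.loglik >= ll - 1e-8:
            return sub

    H = _numerical_hessian(nll_full, res.x)
    se = _safe_se(H)[:p]
    _, modes = laplace_loglik(beta, sigma, y, X, g, ngroups, control, return_modes=True)
    return FitResult(spec, beta, se, sigma, ll, conv, len(y), ngroups,
                     u_modes=modes, message=res.message)


def _converged(res, ll: float) -> bool:
    """Scale-aware convergence: BFGS reports precision loss when the
    finite-difference gradient can no longer be driven below gtol, so accept
    the optimum when the gradient is small relative to the objective."""
    if res.success:
        return True
    grad = np.linalg.norm(res.jac, np.inf)
    return bool(grad < max(1e-4, 1e-7 * abs(ll)))


def _safe_se(H: np.ndarray) -> np.ndarray:
    """SEs from the observed information; NaN where inversion fails."""
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(H.shape[0], np.nan)


def predict_response(fit: FitResult, mass_z, nao_z):
    """Population-level expected offspring count (random intercept at 0)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    X = fit.spec.design(np.atleast_1d(mass_z), np.atleast_1d(nao_z))
    out = np.exp(X @ fit.beta)
    return float(out[0]) if np.isscalar(mass_z) and np.isscalar(nao_z) else out


def fit_candidate_set(data: pd.DataFrame, control: GLMMControl | None = None) -> list[FitResult]:
    """Fit all eight candidate models."""
    return [fit_poisson_glmm(data, spec, control) for spec in build_candidate_set()]
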