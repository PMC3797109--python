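"""Bayesian layers: MCMC refit of the top model and the bivariate trait model.

Two samplers, both adaptive Metropolis-within-Gibbs (proposal scales adapt
toward a target acceptance rate during burn-in only, then freeze, preserving
detailed balance for the stored draws):

* :func:`mcmc_top_model` refits the selected Poisson random-intercept model,
  producing posterior means and 95% credible intervals for predicted
  offspring counts over a grid of standardized mass under "good" (mean of
  negative detrended-NAO years) and "poor" (mean of positive) scenarios.

* :func:`mcmc_bivariate` fits the bivariate latent trait model: raw mass
  Gaussian on a quadratic day-of-cycle polynomial and skull, offspring count
  Poisson (with a latent log-scale residual) on June NAO, with an
  unstructured 2x2 observation-level residual covariance.  The posterior
  correlation derived from that covariance is the carry-over statistic.

Default priors (configurable): Normal(0, 1e8) on fixed effects, half-Cauchy
with scale 5 on the year-intercept SD, inverse-Wishart (identity scale,
df = 3) on the residual covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .glmm import ModelSpec, RankDeficientError, _group_codes

__all__ = [
    "MCMCControl",
    "PosteriorChain",
    "PredictionGrid",
    "mcmc_top_model",
    "mcmc_bivariate",
    "predict_grid",
    "posterior_correlation",
    "nao_scenarios",
    "make_prediction_grid",
]


@dataclass
class MCMCControl:
    """Chain-length bookkeeping and adaptation settings.

    Defaults are the published run settings: 250000 iterations after a
    50000-iteration burn-in, thinning every 50 draws, i.e. 4000 stored
    samples.
    """

    n_iter: int = 250000
    burn_in: int = 50000
    thin: int = 50
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1 or (self.n_iter - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iter - burn_in) must be a multiple of thin")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Stored MCMC samples (one row per stored iteration)."""

    samples: pd.DataFrame
    control: MCMCControl
    kind: str  # "top_model" or "bivariate"
    spec: Optional[ModelSpec] = None
    acceptance: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return len(self.samples)

    def ess(self) -> dict:
        """Effective sample size per parameter (bulk ESS)."""
        import arviz as az

        return {
            c: float(az.ess(self.samples[c].to_numpy()[None, :]))
            for c in self.samples.columns
        }


def _halfcauchy_logpdf(sigma: float, scale: float = 5.0) -> float:
    return -np.log1p((sigma / scale) ** 2)


def _adapt(scale: float, acc: int, tries: int, batch: int, target: float) -> float:
    step = min(0.25, 1.0 / np.sqrt(batch + 1.0))
    rate = acc / max(tries, 1)
    return float(scale * np.exp(step * (rate - target)))


def mcmc_top_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    control: MCMCControl | None = None,
    seed: int = 0,
    prior_beta_var: float = 1e8,
    prior_sigma_scale: float = 5.0,
) -> PosteriorChain:
    """Posterior sampling for a Poisson random-intercept candidate model.

    Component-wise random-walk Metropolis on the fixed effects and
    log(sigma_u), a vectorised per-group Metropolis update for the year
    intercepts.  Stored columns: the coefficient names of ``spec`` plus
    ``sigma_u``.
    """
    control = control or MCMCControl()
    rng = np.random.default_rng(seed)
    y = data["n_offspring"].to_numpy(dtype=float)
    X = spec.design(data["mass_z"].to_numpy(), data["nao_z"].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(f"design for model '{spec.name}' is rank deficient")
    g, G = _group_codes(data["year"])
    n, p = X.shape
    sy = np.bincount(g, weights=y, minlength=G)

    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-3))
    u = np.zeros(G)
    log_sigma = np.log(0.3)
    eta = X @ beta + u[g]
    exp_eta = np.exp(eta)

    sc_b = np.full(p, 0.1)
    sc_u = 0.2
    sc_s = 0.3
    acc_b = np.zeros(p)
    try_b = np.zeros(p)
    acc_u = 0
    try_u = 0
    acc_s = 0
    try_s = 0

    stored = np.empty((control.n_stored, p + 1))
    idx = 0
    const_prior = -0.5 / prior_beta_var

    for it in range(control.n_iter):
        # fixed effects, one at a time
        for j in range(p):
            d = sc_b[j] * rng.standard_normal()
            eta_new = eta + X[:, j] * d
            exp_new = np.exp(eta_new)
            dll = (
                y @ (eta_new - eta)
                - (exp_new.sum() - exp_eta.sum())
                + const_prior * ((beta[j] + d) ** 2 - beta[j] ** 2)
            )
            try_b[j] += 1
            if np.log(rng.random()) < dll:
                beta[j] += d
                eta, exp_eta = eta_new, exp_new
                acc_b[j] += 1

        # year intercepts, vectorised over groups
        sigma2 = np.exp(2 * log_sigma)
        d = sc_u * rng.standard_normal(G)
        smu_old = np.bincount(g, weights=exp_eta, minlength=G)
        smu_new = smu_old * np.exp(d)
        dll_g = sy * d - (smu_new - smu_old) - ((u + d) ** 2 - u**2) / (2 * sigma2)
        accept = np.log(rng.random(G)) < dll_g
        try_u += 1
        if accept.any():
            u = np.where(accept, u + d, u)
            eta = eta + (d * accept)[g]
            exp_eta = np.exp(eta)
        acc_u += accept.mean()

        # log sigma_u
        ls_new = log_sigma + sc_s * rng.standard_normal()
        s2n = np.exp(2 * ls_new)
        su2 = (u**2).sum()
        dll = (
            -su2 / 2 * (1 / s2n - 1 / sigma2)
            - G * (ls_new - log_sigma)
            + _halfcauchy_logpdf(np.exp(ls_new), prior_sigma_scale)
            - _halfcauchy_logpdf(np.exp(log_sigma), prior_sigma_scale)
            + (ls_new - log_sigma)  # Jacobian of sigma -> log sigma
        )
        try_s += 1
        if np.log(rng.random()) < dll:
            log_sigma = ls_new
            acc_s += 1

        if not np.all(np.isfinite(eta)):
            raise FloatingPointError(
                f"divergent chain at iteration {it}: non-finite linear predictor"
            )

        if it < control.burn_in and (it + 1) % control.adapt_interval == 0:
            batch = (it + 1) // control.adapt_interval
            for j in range(p):
                sc_b[j] = _adapt(sc_b[j], acc_b[j], try_b[j], batch, control.target_accept)
            sc_u = _adapt(sc_u, acc_u, try_u, batch, control.target_accept)
            sc_s = _adapt(sc_s, acc_s, try_s, batch, control.target_accept)
            acc_b[:] = 0
            try_b[:] = 0
            acc_u = try_u = acc_s = try_s = 0

        if it >= control.burn_in and (it - control.burn_in + 1) % control.thin == 0:
            stored[idx, :p] = beta
            stored[idx, p] = np.exp(log_sigma)
            idx += 1

    assert idx == control.n_stored
    samples = pd.DataFrame(stored, columns=list(spec.coef_names) + ["sigma_u"])
    return PosteriorChain(samples=samples, control=control, kind="top_model", spec=spec)


@dataclass
class PredictionGrid:
    """Grid of standardized mass values by NAO scenario.

    ``scenarios`` maps a scenario name to the standardized NAO value used
    for prediction; after :func:`predict_grid` the ``table`` holds posterior
    mean and 2.5/97.5 percentiles of the expected offspring count per cell.
    """

    mass_z: np.ndarray
    scenarios: dict
    table: Optional[pd.DataFrame] = None


def nao_scenarios(nao_values) -> dict:
    """"Good" and "poor" breeding-condition scenarios from detrended NAO.

    Good years have negative NAO residuals; the scenario values are the mean
    of the negative residuals and the mean of the positive residuals.
    """
    x = np.asarray(nao_values, dtype=float)
    neg, pos = x[x < 0], x[x > 0]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("need both negative and positive NAO residuals for scenarios")
    return {"good": float(neg.mean()), "poor": float(pos.mean())}


def make_prediction_grid(nao_values, half_width: float = 1.5, n_points: int = 31) -> PredictionGrid:
    """Grid spanning +/- ``half_width`` SD of mass with good/poor scenarios."""
    return PredictionGrid(
        mass_z=np.linspace(-half_width, half_width, n_points),
        scenarios=nao_scenarios(nao_values),
    )


def predict_grid(chain: PosteriorChain, grid: PredictionGrid) -> PredictionGrid:
    """Posterior of the population-level expected count per grid cell."""
    if chain.n_stored == 0:
        raise ValueError("chain is empty")
    if chain.spec is None:
        raise ValueError("chain carries no model specification")
    B = chain.samples[list(chain.spec.coef_names)].to_numpy()
    rows = []
    for name, nao_val in grid.scenarios.items():
        Xg = chain.spec.design(grid.mass_z, np.full_like(grid.mass_z, nao_val))
        lam = np.exp(B @ Xg.T)  # (samples, cells)
        lo, hi = np.percentile(lam, [2.5, 97.5], axis=0)
        for i, mz in enumerate(grid.mass_z):
            rows.append(
                {
                    "mass_z": float(mz),
                    "scenario": name,
                    "mean": float(lam[:, i].mean()),
                    "lo95": float(lo[i]),
                    "hi95": float(hi[i]),
                }
            )
    return PredictionGrid(mass_z=grid.mass_z, scenarios=grid.scenarios, table=pd.DataFrame(rows))


def _draw_mvn(rng, mean, prec_chol):
    z = rng.standard_normal(len(mean))
    return mean + np.linalg.solve(prec_chol.T, z)


def mcmc_bivariate(
    data: pd.DataFrame,
    control: MCMCControl | None = None,
    seed: int = 0,
    prior_beta_var: float = 1e8,
    prior_cov_df: float = 3.0,
    prior_cov_scale: np.ndarray | None = None,
) -> PosteriorChain:
    """Bivariate Gaussian/Poisson latent trait model.

    Mass equation: raw mass ~ intercept + centred day + centred day^2 +
    centred skull (Gaussian).  Offspring equation: count ~ intercept + June
    NAO, Poisson with a latent log-scale residual.  The two residuals share
    an unstructured 2x2 covariance (conjugate inverse-Wishart update); the
    Gaussian-side coefficients are conjugate draws, the Poisson-side
    coefficients and latent residuals are adaptive Metropolis updates.

    Stored columns: mass_intercept, mass_day, mass_day2, mass_skull,
    juv_intercept, juv_nao, var_mass, cov_mass_juv, var_juv.
    """
    control = control or MCMCControl()
    rng = np.random.default_rng(seed)
    mass = data["mass_g"].to_numpy(dtype=float)
    ycol = "n_offspring" if "n_offspring" in data else "n_offspring_next_winter"
    y = data[ycol].to_numpy(dtype=float)
    day = data["day_of_cycle"].to_numpy(dtype=float)
    skull = data["skull_mm"].to_numpy(dtype=float)
    nao = data["june_nao"].to_numpy(dtype=float)
    n = len(mass)

    dc = day - day.mean()
    Xm = np.column_stack([np.ones(n), dc, dc**2 - (dc**2).mean(), skull - skull.mean()])
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise RankDeficientError("mass-equation design is rank deficient")
    Xj = np.column_stack([np.ones(n), nao])

    Psi = np.eye(2) if prior_cov_scale is None else np.asarray(prior_cov_scale, float)

    a, *_ = np.linalg.lstsq(Xm, mass, rcond=None)
    e_m = mass - Xm @ a
    b = np.array([np.log(max(y.mean(), 1e-3)), 0.0])
    e_j = np.zeros(n)
    Sigma = np.array([[max(np.var(e_m), 1.0), 0.0], [0.0, 0.3]])

    XtX = Xm.T @ Xm
    prior_prec = np.eye(Xm.shape[1]) / prior_beta_var
    lgy = gammaln(y + 1)

    sc_b = np.full(2, 0.1)
    sc_e = 0.5
    acc_b = np.zeros(2)
    try_b = np.zeros(2)
    acc_e = 0.0
    try_e = 0

    ncol = 4 + 2 + 3
    stored = np.empty((control.n_stored, ncol))
    idx = 0

    for it in range(control.n_iter):
        Vm, Vj = Sigma[0, 0], Sigma[1, 1]
        C = Sigma[0, 1]

        # Gaussian-side coefficients: conjugate draw given e_j and Sigma
        v = Vm - C**2 / Vj
        ytil = mass - (C / Vj) * e_j
        P = XtX / v + prior_prec
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, Xm.T @ ytil / v)
        a = _draw_mvn(rng, mean, L)
        e_m = mass - Xm @ a

        # latent Poisson residuals, vectorised Metropolis
        mu_c = (C / Vm) * e_m
        v_c = Vj - C**2 / Vm
        eta_j = Xj @ b + e_j
        d = sc_e * rng.standard_normal(n)
        eta_new = eta_j + d
        dll = (
            y * d
            - (np.exp(eta_new) - np.exp(eta_j))
            - ((e_j + d - mu_c) ** 2 - (e_j - mu_c) ** 2) / (2 * v_c)
        )
        accept = np.log(rng.random(n)) < dll
        e_j = np.where(accept, e_j + d, e_j)
        acc_e += accept.mean()
        try_e += 1

        # Poisson-side coefficients, component Metropolis
        eta_j = Xj @ b + e_j
        exp_eta = np.exp(eta_j)
        for jj in range(2):
            dlt = sc_b[jj] * rng.standard_normal()
            eta_new = eta_j + Xj[:, jj] * dlt
            exp_new = np.exp(eta_new)
            dll = (
                y @ (eta_new - eta_j)
                - (exp_new.sum() - exp_eta.sum())
                - ((b[jj] + dlt) ** 2 - b[jj] ** 2) / (2 * prior_beta_var)
            )
            try_b[jj] += 1
            if np.log(rng.random()) < dll:
                b[jj] += dlt
                eta_j, exp_eta = eta_new, exp_new
                acc_b[jj] += 1

        # residual covariance: conjugate inverse-Wishart
        E = np.column_stack([e_m, e_j])
        S = E.T @ E
        Sigma = stats.invwishart.rvs(df=prior_cov_df + n, scale=Psi + S, random_state=rng)

        if it < control.burn_in and (it + 1) % control.adapt_interval == 0:
            batch = (it + 1) // control.adapt_interval
            for jj in range(2):
                sc_b[jj] = _adapt(sc_b[jj], acc_b[jj], try_b[jj], batch, control.target_accept)
            sc_e = _adapt(sc_e, acc_e, try_e, batch, control.target_accept)
            acc_b[:] = 0
            try_b[:] = 0
            acc_e = 0.0
            try_e = 0

        if it >= control.burn_in and (it - control.burn_in + 1) % control.thin == 0:
            stored[idx, :4] = a
            stored[idx, 4:6] = b
            stored[idx, 6:9] = (Sigma[0, 0], Sigma[0, 1], Sigma[1, 1])
            idx += 1

    assert idx == control.n_stored
    cols = [
        "mass_intercept",
        "mass_day",
        "mass_day2",
        "mass_skull",
        "juv_intercept",
        "juv_nao",
        "var_mass",
        "cov_mass_juv",
        "var_juv",
    ]
    samples = pd.DataFrame(stored, columns=cols)
    return PosteriorChain(samples=samples, control=control, kind="bivariate")


def posterior_correlation(chain: PosteriorChain, min_samples: int = 100):
    """Posterior of the latent mass-offspring correlation.

    Per stored sample, r = cov / sqrt(var_mass * var_juv); returns the
    kernel-density posterior mode (Gaussian kernel, Silverman bandwidth) and
    the equal-tailed 95% interval.  A constant chain returns the exact ratio
    with a zero-width interval.
    """
    df = chain.samples
    needed = {"var_mass", "cov_mass_juv", "var_juv"}
    if not needed <= set(df.columns):
        raise ValueError("chain does not store a 2x2 residual covariance")
    if len(df) < min_samples:
        raise ValueError(f"need >= {min_samples} stored samples")
    vm = df["var_mass"].to_numpy()
    vj = df["var_juv"].to_numpy()
    c = df["cov_mass_juv"].to_numpy()
    if np.any(vm <= 0) or np.any(vj <= 0) or np.any(vm * vj - c**2 < -1e-10 * vm * vj):
        raise ValueError("a stored covariance matrix is not positive definite")
    r = c / np.sqrt(vm * vj)
    if np.ptp(r) < 1e-12:
        val = float(r[0])
        return val, val, val
    kde = stats.gaussian_kde(r, bw_method="silverman")
    grid = np.linspace(r.min(), r.max(), 1024)
    mode = float(grid[np.argmax(kde(grid))])
    lo, hi = np.percentile(r, [2.5, 97.5])
    return mode, float(lo), float(hi)
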