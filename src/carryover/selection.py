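"""Information-theoretic model selection and averaging.

AICc ranking, Akaike weights, the Δ6 candidate set, the nesting rule (drop a
Δ6 model if a simpler model nested within it sits higher in the table), and
model-averaged coefficients by both the natural-averages and the zeroes
(shrinkage) methods, with relative variable importance and unconditional
standard errors.  Also the marginal R² of a Poisson mixed model
(fixed-effect variance over fixed + random + distribution-specific
variance, the log-link distribution variance being ln(1 + 1/λ̄)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

from .glmm import FitResult, ModelSpec

__all__ = [
    "SelectionTable",
    "AveragedEstimates",
    "aicc",
    "rank_and_weight",
    "is_nested",
    "apply_nesting_rule",
    "model_average",
    "marginal_r2",
]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion:
    AICc = -2ℓ + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class SelectionTable:
    """Candidate models ranked by AICc.

    ``table`` columns: name, k, loglik, aicc, delta, weight, in_delta6,
    retained.  ``fits`` is aligned with the rows.  Weights sum to one over
    all rows; they are renormalized over the retained set at averaging time.
    """

    table: pd.DataFrame
    fits: list
    n: int
    delta_threshold: float = 6.0

    @property
    def retained(self) -> list:
        return [f for f, keep in zip(self.fits, self.table["retained"]) if keep]

    def __str__(self) -> str:  # human-readable ranking
        df = self.table.copy()
        df["aicc"] = df["aicc"].round(1)
        df["delta"] = df["delta"].round(2)
        df["weight"] = df["weight"].round(3)
        return df.to_string(index=False)


def rank_and_weight(fits: list, n: int, delta_threshold: float = 6.0) -> SelectionTable:
    """Rank fitted candidates by AICc and attach Akaike weights.

    Ties in AICc are broken by smaller k, then model name, so output order is
    deterministic.  ``retained`` is initialised to Δ-set membership; apply
    the nesting rule to refine it.
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        rows.append(
            {
                "name": f.spec.name,
                "k": f.spec.k,
                "loglik": f.loglik,
                "aicc": aicc(f.loglik, f.spec.k, n),
            }
        )
    df = pd.DataFrame(rows)
    order = np.lexsort((df["name"], df["k"], df["aicc"]))
    df = df.iloc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    df["delta"] = df["aicc"] - df["aicc"].iloc[0]
    rel = np.exp(-0.5 * df["delta"].to_numpy())
    df["weight"] = rel / rel.sum()
    df["in_delta6"] = df["delta"] <= delta_threshold
    df["retained"] = df["in_delta6"]
    return SelectionTable(table=df, fits=fits, n=n, delta_threshold=delta_threshold)


def is_nested(a: ModelSpec, b: ModelSpec) -> bool:
    """True iff a's term set is a strict subset of b's."""
    return set(a.terms) < set(b.terms)


def apply_nesting_rule(table: SelectionTable, delta_threshold: float | None = None) -> SelectionTable:
    """Drop Δ-set models that are more complex versions of better-ranked
    simpler models.

    A Δ-set model is removed iff some model with strictly lower AICc is
    nested within it.  The top-ranked model can never be dropped.
    """
    thr = table.delta_threshold if delta_threshold is None else delta_threshold
    df = table.table.copy()
    df["in_delta6"] = df["delta"] <= thr
    retained = []
    for i, fit in enumerate(table.fits):
        if not df["in_delta6"].iloc[i]:
            retained.append(False)
            continue
        drop = any(
            is_nested(table.fits[j].spec, fit.spec)
            and df["aicc"].iloc[j] < df["aicc"].iloc[i]
            for j in range(len(table.fits))
        )
        retained.append(not drop)
    df["retained"] = retained
    return SelectionTable(table=df, fits=table.fits, n=table.n, delta_threshold=thr)


@dataclass
class AveragedEstimates:
    """Model-averaged coefficients over the retained set.

    One row per term: natural average (over models containing the term),
    unconditional SE, shrinkage average (absent terms count as zero) and
    relative importance (sum of renormalized weights of models containing
    the term)."""

    table: pd.DataFrame  # index: term; columns natural_avg, unconditional_se, shrinkage_avg, importance

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def model_average(table: SelectionTable) -> AveragedEstimates:
    """Average coefficients over the retained (post-nesting) models.

    Weights are renormalized over the retained set before averaging and
    importance calculation.  The unconditional SE combines within-model SE
    and between-model spread (squared-term combination); it is NaN when the
    retained fits carry no SEs.
    """
    keep = table.table["retained"].to_numpy()
    if not keep.any():
        raise ValueError("retained set is empty")
    fits = [f for f, k in zip(table.fits, keep) if k]
    w = table.table["weight"].to_numpy()[keep]
    w = w / w.sum()

    terms = ["intercept"]
    for f in fits:
        for t in f.spec.terms:
            if t not in terms:
                terms.append(t)

    rows = {}
    for t in terms:
        present = np.array([t in f.spec.coef_names for f in fits])
        betas = np.array([f.coef.get(t, 0.0) for f in fits])
        ses = np.array(
            [f.coef_se.get(t, np.nan) if f.se is not None else np.nan for f in fits]
        )
        wt = w[present]
        nat = float((wt * betas[present]).sum() / wt.sum())
        shr = float((w * betas).sum())  # absent terms contribute 0
        imp = float(wt.sum())
        if np.all(np.isfinite(ses[present])):
            se_unc = float(
                (wt / wt.sum() * np.sqrt(ses[present] ** 2 + (betas[present] - nat) ** 2)).sum()
            )
        else:
            se_unc = float("nan")
        rows[t] = {
            "natural_avg": nat,
            "unconditional_se": se_unc,
            "shrinkage_avg": shr,
            "importance": imp,
        }
    return AveragedEstimates(table=pd.DataFrame(rows).T[
        ["natural_avg", "unconditional_se", "shrinkage_avg", "importance"]
    ])


def marginal_r2(fit: FitResult, data: pd.DataFrame) -> float:
    """Marginal R² of a Poisson log-link mixed model.

    R²m = σ²_f / (σ²_f + σ²_u + σ²_d) where σ²_f is the variance of the
    fixed-effect linear predictor over the data, σ²_u the year-intercept
    variance, and σ²_d = ln(1 + 1/λ̄) the log-link Poisson
    distribution-specific variance with λ̄ the observed mean count.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    X = fit.spec.design(data["mass_z"].to_numpy(), data["nao_z"].to_numpy())
    eta = X @ fit.beta
    sigma2_f = float(np.var(eta))
    lam_bar = float(np.mean(data["n_offspring"]))
    if lam_bar <= 0:
        raise ValueError("mean count must be positive")
    sigma2_d = log(1.0 + 1.0 / lam_bar)
    total = sigma2_f + fit.sigma_u**2 + sigma2_d
    if total == 0:
        raise ValueError("total variance is zero")
    return sigma2_f / total
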