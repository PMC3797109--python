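"""Synthetic data generation for the carry-over analysis.

The field data behind the original brent-goose study are not deposited, so
every downstream stage of this package is exercised on simulated datasets
that share the statistical structure the analysis assumes:

* skull lengths drawn around a reference length, with raw body mass tied to
  skull by an allometric power law plus a quadratic within-season (staging)
  mass trajectory and individual condition noise;
* a yearly June NAO series with a quadratic temporal trend plus residuals;
* next-winter offspring counts that are Poisson on the log scale, driven by
  standardized condition (mass) and standardized detrended NAO, their
  interactions, and a year-level random intercept;
* a resighting table from which breeding status can be (re-)assigned by the
  winter resighting rule.

Day-of-annual-cycle convention: cycle day 1 = 1 July, so the spring staging
window (April--May) falls on days ~275--335.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "SimConfigError",
    "generate_dataset",
    "generate_resightings",
    "generate_bivariate_dataset",
    "write_csvs",
    "study_scale_config",
]

#: linear-predictor terms recognised by the generator, in canonical order
TERM_ORDER = ("mass", "nao", "mass:nao", "mass2", "mass2:nao")

BIRDS_COLUMNS = [
    "bird_id",
    "year",
    "day_of_cycle",
    "mass_g",
    "skull_mm",
    "n_offspring_next_winter",
    "adult_associate_flag",
]
NAO_COLUMNS = ["year", "june_nao"]
RESIGHT_COLUMNS = ["bird_id", "year", "n_records_no_juv", "n_records_with_juv"]


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _default_beta() -> dict:
    # coefficients of the best-supported quadratic mass x NAO model,
    # on the standardized log-link scale
    return {
        "intercept": -0.09,
        "mass": 0.11,
        "nao": -0.58,
        "mass:nao": 0.0,
        "mass2": -0.14,
        "mass2:nao": -0.27,
    }


@dataclass
class SimConfig:
    """Generative parameters for a carry-over dataset.

    Defaults emulate the original study conditions: 6 breeding cycles,
    ~213 females total, mean skull 89.6 mm, mean staging mass 1464.2 g,
    allometric exponent 3.4, and log-link coefficients from the
    best-supported model of the published candidate set.
    """

    n_years: int = 6
    n_birds_per_year: int = 36
    start_year: int = 2005
    skull_mean_mm: float = 89.6
    skull_sd_mm: float = 2.5
    allometric_exponent: float = 3.4
    baseline_mass_g: float = 1464.2
    #: (linear, quadratic) g/day coefficients on day centred at window middle
    seasonal_coeffs: tuple = (5.0, -0.05)
    #: SD of individual condition noise around the structural mass (g)
    mass_resid_sd_g: float = 95.0
    #: inclusive day-of-cycle capture window (spring staging)
    capture_window: tuple = (275, 335)
    #: (intercept, linear, quadratic) NAO trend over (year - start_year)
    nao_trend_coeffs: tuple = (0.4, -0.05, 0.0008)
    nao_resid_sd: float = 1.0
    #: log-link coefficients keyed by term name (see TERM_ORDER)
    beta: dict = field(default_factory=_default_beta)
    year_intercept_sd: float = 0.3
    #: expected resighting records per bird in the winter after capture
    resight_rate: float = 6.0
    #: probability a bird is recorded with an adult associate at capture
    associate_prob: float = 0.9
    #: optional hard cap on offspring counts (biological clutch range);
    #: default off because the fitted model is plain Poisson
    offspring_cap: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise SimConfigError("n_years must be >= 2")
        if self.n_birds_per_year < 2:
            raise SimConfigError("n_birds_per_year must be >= 2")
        if self.skull_sd_mm <= 0:
            raise SimConfigError("skull_sd_mm must be > 0")
        for name in ("mass_resid_sd_g", "nao_resid_sd", "year_intercept_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.allometric_exponent <= 0:
            raise SimConfigError("allometric_exponent must be > 0")
        if self.baseline_mass_g <= 0:
            raise SimConfigError("baseline_mass_g must be > 0")
        if not (0 <= self.associate_prob <= 1):
            raise SimConfigError("associate_prob must be in [0, 1]")
        if self.resight_rate < 0:
            raise SimConfigError("resight_rate must be >= 0")
        lo, hi = self.capture_window
        if not (1 <= lo <= hi <= 366):
            raise SimConfigError("capture_window must satisfy 1 <= lo <= hi <= 366")
        unknown = set(self.beta) - ({"intercept"} | set(TERM_ORDER))
        if unknown:
            raise SimConfigError(f"beta has unknown terms: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """A simulated dataset plus the truth that generated it.

    ``birds`` carries, besides the observable columns, the true standardized
    covariates (``mass_z_true``, ``nao_z_true``) and the true Poisson mean
    (``lambda_true``) so that inference engines can be validated against the
    exact design they were simulated from.
    """

    birds: pd.DataFrame
    nao: pd.DataFrame
    truth: SimConfig
    year_effects: pd.Series  # true random intercepts indexed by year


def _rngs(seed: int, n: int = 8) -> list[np.random.Generator]:
    """Independent substreams so one component's draw count never perturbs
    another's (master seed spawns per-component children)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


def linear_predictor(beta: dict, mass_z, nao_z):
    """Evaluate the log-link linear predictor at standardized covariates."""
    mass_z = np.asarray(mass_z, dtype=float)
    nao_z = np.asarray(nao_z, dtype=float)
    eta = np.full(np.broadcast(mass_z, nao_z).shape, beta.get("intercept", 0.0))
    eta = eta + beta.get("mass", 0.0) * mass_z
    eta = eta + beta.get("nao", 0.0) * nao_z
    eta = eta + beta.get("mass:nao", 0.0) * mass_z * nao_z
    eta = eta + beta.get("mass2", 0.0) * mass_z**2
    eta = eta + beta.get("mass2:nao", 0.0) * mass_z**2 * nao_z
    return eta


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate one capture season per bird and next-winter offspring counts.

    Deterministic given ``config.seed``: repeated calls with the same config
    return byte-identical tables.
    """
    rng_skull, rng_day, rng_mass, rng_nao, rng_year, rng_off, _, rng_assoc = _rngs(
        config.seed
    )
    n = config.n_years * config.n_birds_per_year
    years = np.repeat(
        np.arange(config.start_year, config.start_year + config.n_years),
        config.n_birds_per_year,
    )

    skull = rng_skull.normal(config.skull_mean_mm, config.skull_sd_mm, size=n)
    lo, hi = config.capture_window
    day = rng_day.integers(lo, hi + 1, size=n)
    day_c = day - (lo + hi) / 2.0
    c1, c2 = config.seasonal_coeffs
    seasonal = c1 * day_c + c2 * day_c**2
    condition = rng_mass.normal(0.0, config.mass_resid_sd_g, size=n)
    structural = config.baseline_mass_g * (
        skull / config.skull_mean_mm
    ) ** config.allometric_exponent
    mass = structural + seasonal + condition

    # yearly June NAO: quadratic trend + residual
    t = np.arange(config.n_years, dtype=float)
    a0, a1, a2 = config.nao_trend_coeffs
    trend = a0 + a1 * t + a2 * t**2
    resid = rng_nao.normal(0.0, config.nao_resid_sd, size=config.n_years)
    june_nao = trend + resid
    year_index = years - config.start_year

    # standardized covariates, observation level (matches the preprocessing
    # convention downstream)
    mass_z = _zscore(condition)
    nao_z_rows = _zscore(resid[year_index])

    u = rng_year.normal(0.0, config.year_intercept_sd, size=config.n_years)
    eta = linear_predictor(config.beta, mass_z, nao_z_rows) + u[year_index]
    offspring = rng_off.poisson(np.exp(eta))
    if config.offspring_cap is not None:
        offspring = np.minimum(offspring, config.offspring_cap)
    associate = rng_assoc.random(n) < config.associate_prob

    birds = pd.DataFrame(
        {
            "bird_id": [f"B{i:05d}" for i in range(n)],
            "year": years,
            "day_of_cycle": day,
            "mass_g": mass,
            "skull_mm": skull,
            "n_offspring_next_winter": offspring,
            "adult_associate_flag": associate,
            # truth columns (not part of the observable CSV schema)
            "mass_z_true": mass_z,
            "nao_z_true": nao_z_rows,
            "lambda_true": np.exp(eta),
        }
    )
    nao = pd.DataFrame(
        {
            "year": np.arange(config.start_year, config.start_year + config.n_years),
            "june_nao": june_nao,
            "nao_trend_true": trend,
            "nao_resid_true": resid,
        }
    )
    year_effects = pd.Series(u, index=nao["year"], name="year_effect")
    return SyntheticDataset(birds=birds, nao=nao, truth=config, year_effects=year_effects)


def generate_resightings(dataset: SyntheticDataset, config: SimConfig) -> pd.DataFrame:
    """Simulate winter resighting record counts for the breeder filter.

    Construction guarantees (when ``resight_rate > 0``) that every true
    breeder has at least one record with juveniles, so true breeding status
    is recoverable from the table; with ``resight_rate == 0`` every bird has
    zero records and the downstream filter excludes everyone.
    """
    if dataset.birds.empty:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[6])
    n = len(dataset.birds)
    offspring = dataset.birds["n_offspring_next_winter"].to_numpy()
    if config.resight_rate == 0:
        no_juv = np.zeros(n, dtype=int)
        with_juv = np.zeros(n, dtype=int)
    else:
        half = config.resight_rate / 2.0
        is_breeder = offspring > 0
        with_juv = np.where(is_breeder, 1 + rng.poisson(half, size=n), 0)
        no_juv = np.where(
            is_breeder, rng.poisson(half, size=n), rng.poisson(config.resight_rate, size=n)
        )
    return pd.DataFrame(
        {
            "bird_id": dataset.birds["bird_id"].to_numpy(),
            "year": dataset.birds["year"].to_numpy(),
            "n_records_no_juv": no_juv,
            "n_records_with_juv": with_juv,
        }
    )


def generate_bivariate_dataset(
    n: int,
    mass_coeffs: tuple = (1464.2, 5.0, -0.05, 22.0),
    juv_coeffs: tuple = (-0.3, -0.6),
    sigma: np.ndarray | None = None,
    latent_correlation: float | None = None,
    mass_sd: float = 95.0,
    juv_latent_sd: float = 0.5,
    skull_mean_mm: float = 89.6,
    skull_sd_mm: float = 2.5,
    capture_window: tuple = (275, 335),
    nao_sd: float = 1.0,
    n_years: int = 6,
    start_year: int = 2005,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw directly from the bivariate Gaussian/Poisson latent trait model.

    Each bird has a pair of residuals ``(e_mass, e_juv)`` from a bivariate
    normal with covariance ``sigma``; raw mass is Gaussian around a
    day-polynomial + skull regression and the offspring count is Poisson with
    a latent log-scale residual (log-normal Poisson).  Used to validate the
    bivariate sampler against a known latent mass-offspring correlation.

    Either pass ``sigma`` (2x2) or a ``latent_correlation`` which, combined
    with ``mass_sd`` and ``juv_latent_sd``, defines it.
    """
    if sigma is None:
        if latent_correlation is None:
            latent_correlation = 0.0
        c = latent_correlation * mass_sd * juv_latent_sd
        sigma = np.array([[mass_sd**2, c], [c, juv_latent_sd**2]])
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (2, 2) or not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(sigma)[0] < 0:
        raise ValueError("sigma must be positive semi-definite")

    rng_sk, rng_day, rng_nao, rng_e, rng_y, *_ = _rngs(seed)
    skull = rng_sk.normal(skull_mean_mm, skull_sd_mm, size=n)
    lo, hi = capture_window
    day = rng_day.integers(lo, hi + 1, size=n)
    years = np.arange(start_year, start_year + n_years)
    nao_by_year = rng_nao.normal(0.0, nao_sd, size=n_years)
    year = years[np.arange(n) % n_years]
    nao = nao_by_year[np.arange(n) % n_years]

    e = rng_e.multivariate_normal(np.zeros(2), sigma, size=n)
    day_c = day - (lo + hi) / 2.0
    b0, b1, b2, b_skull = mass_coeffs
    mass = b0 + b1 * day_c + b2 * day_c**2 + b_skull * (skull - skull_mean_mm) + e[:, 0]
    g0, g_nao = juv_coeffs
    lam = np.exp(g0 + g_nao * nao + e[:, 1])
    offspring = rng_y.poisson(lam)
    return pd.DataFrame(
        {
            "bird_id": [f"B{i:05d}" for i in range(n)],
            "year": year,
            "day_of_cycle": day,
            "mass_g": mass,
            "skull_mm": skull,
            "june_nao": nao,
            "n_offspring_next_winter": offspring,
            "e_mass_true": e[:, 0],
            "e_juv_true": e[:, 1],
        }
    )


def write_csvs(dataset: SyntheticDataset, outdir, resightings: pd.DataFrame | None = None):
    """Write birds.csv / nao.csv (and resightings.csv) with the documented schemas."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.birds[BIRDS_COLUMNS].to_csv(outdir / "birds.csv", index=False)
    dataset.nao[NAO_COLUMNS].to_csv(outdir / "nao.csv", index=False)
    if resightings is not None:
        resightings[RESIGHT_COLUMNS].to_csv(outdir / "resightings.csv", index=False)
    return outdir


def study_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """Convenience: a config at the original study's scale (6 years, ~213 birds)."""
    cfg = SimConfig(seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
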