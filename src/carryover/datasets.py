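"""Published reference values from the original brent-goose field study.

The raw field data are not deposited, but the study's printed fit statistics
(per-model log-likelihoods, parameter counts and coefficient estimates for
the eight candidate models, over n = 213 females) are sufficient inputs to
exercise and validate the whole selection layer.  This module freezes those
published numbers as data.
"""

from __future__ import annotations

import numpy as np

from .glmm import FitResult, build_candidate_set

__all__ = [
    "SKULL_REFERENCE_MM",
    "MEAN_FEMALE_MASS_G",
    "LOG_OLS_SLOPE",
    "LOG_PEARSON_R",
    "N_FEMALES",
    "published_candidate_fits",
    "published_top_model_coefficients",
]

#: mean skull length of the 468 staging females (mm), the SMI reference L0
SKULL_REFERENCE_MM = 89.6
#: mean seasonally-corrected female mass (g) added back to SMI residuals
MEAN_FEMALE_MASS_G = 1464.2
#: OLS slope of log(mass) on log(skull) in the allometry sample
LOG_OLS_SLOPE = 1.003
#: Pearson correlation of log(mass) and log(skull)
LOG_PEARSON_R = 0.29
#: analysis sample size (females with assignable breeding status)
N_FEMALES = 213

# per-model published statistics: name -> (loglik, {term: coefficient})
_PUBLISHED = {
    "Mass^2 * NAO": (
        -169.018,
        {"intercept": -0.09, "mass": 0.11, "nao": -0.58, "mass2": -0.14, "mass2:nao": -0.27},
    ),
    "Mass * NAO": (
        -170.293,
        {"intercept": -0.21, "mass": -0.01, "nao": -0.79, "mass:nao": -0.29},
    ),
    "NAO": (-174.799, {"intercept": -0.21, "nao": -0.79}),
    "Mass + NAO": (-173.832, {"intercept": -0.22, "mass": 0.10, "nao": -0.81}),
    "Mass^2 + NAO": (
        -173.625,
        {"intercept": -0.18, "mass": 0.12, "nao": -0.80, "mass2": -0.03},
    ),
    "Null": (-182.591, {"intercept": -0.45}),
    "Mass": (-181.778, {"intercept": -0.46, "mass": 0.09}),
    "Mass^2": (-181.503, {"intercept": -0.41, "mass": 0.12, "mass2": -0.04}),
}


def published_candidate_fits() -> list[FitResult]:
    """The eight candidate models with their published logLik and
    coefficients, wrapped as :class:`FitResult` objects (no SEs: the study
    did not print per-model standard errors)."""
    fits = []
    for spec in build_candidate_set():
        loglik, coefs = _PUBLISHED[spec.name]
        beta = np.array([coefs[name] for name in spec.coef_names])
        fits.append(
            FitResult(
                spec=spec,
                beta=beta,
                se=None,
                sigma_u=float("nan"),
                loglik=loglik,
                converged=True,
                n_obs=N_FEMALES,
                n_groups=6,
            )
        )
    return fits


def published_top_model_coefficients() -> dict:
    """Coefficients of the best-supported model (quadratic mass x NAO)."""
    return dict(_PUBLISHED["Mass^2 * NAO"][1])
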