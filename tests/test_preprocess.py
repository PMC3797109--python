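"""Scaled mass index, seasonal correction, NAO detrending, breeder rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carryover as co
from carryover.preprocess import DegenerateDataError, inverse_z


class TestSmaSlope:
    def test_reference_quotient(self):
        # the conventional inputs give 3.4586..., not the rounded 3.4
        assert co.compute_sma_slope(1.003, 0.29) == pytest.approx(1.003 / 0.29)
        assert round(co.compute_sma_slope(1.003, 0.29), 1) == 3.5

    def test_exact_arithmetic(self):
        assert co.compute_sma_slope(2.0, 0.5) == 4.0

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(derandomize=True, max_examples=25)
    def test_perfect_correlation_returns_ols_slope(self, b):
        assert co.compute_sma_slope(b, 1.0) == b

    def test_zero_correlation_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            co.compute_sma_slope(1.0, 0.0)


class TestScaledMassIndex:
    def test_identity_at_reference_length(self):
        assert co.scaled_mass_index(1500.0, 89.6, 89.6, 3.4) == pytest.approx(1500.0)

    @given(st.floats(10, 200))
    @settings(derandomize=True, max_examples=25)
    def test_linear_scaling_with_unit_exponent(self, L):
        assert co.scaled_mass_index(1000.0, 2 * L, L, 1.0) == pytest.approx(500.0)

    def test_closed_form(self):
        expected = 1464.2 * (89.6 / 95.0) ** 3.4
        assert co.scaled_mass_index(1464.2, 95.0, 89.6, 3.4) == pytest.approx(expected)

    @given(
        st.floats(500, 3000),
        st.floats(500, 3000),
        st.floats(70, 89.5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_mass_and_above_raw_mass_for_small_birds(self, m1, m2, L):
        """SMI increases with mass, and exceeds raw mass when L < L0, b > 0."""
        lo, hi = sorted([m1, m2])
        s_lo = co.scaled_mass_index(lo, L, 89.6, 3.4)
        s_hi = co.scaled_mass_index(hi, L, 89.6, 3.4)
        assert s_lo <= s_hi
        assert s_hi >= hi

    def test_domain_error(self):
        with pytest.raises(DegenerateDataError):
            co.scaled_mass_index(-1.0, 89.6, 89.6, 3.4)


class TestFitAllometry:
    def test_noiseless_power_law_recovered_exactly(self):
        rng = np.random.default_rng(0)
        skull = rng.uniform(80, 100, 50)
        mass = 2.0 * skull**3.4
        fit = co.fit_allometry(mass, skull)
        assert fit.ols_slope == pytest.approx(3.4, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.sma_slope == pytest.approx(3.4, abs=1e-9)

    def test_sma_consistent_under_proportional_errors_in_variables(self):
        """When log-scale noise variances satisfy the SMA ratio (var_y/var_x
        = b^2), the SMA slope is a consistent estimator of the exponent."""
        rng = np.random.default_rng(1)
        n = 10_000
        b = 3.4
        latent = rng.normal(0.0, 0.05, n)
        log_skull = np.log(89.6) + latent + rng.normal(0, 0.02, n)
        log_mass = np.log(1464.2) + b * latent + rng.normal(0, b * 0.02, n)
        fit = co.fit_allometry(np.exp(log_mass), np.exp(log_skull))
        # MC error of the sd ratio ~ b * sqrt(2/n)
        assert abs(fit.sma_slope - b) < 3 * b * np.sqrt(2.0 / n)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            co.fit_allometry([1500, 1600], [89, 90])  # < 3 records
        with pytest.raises(DegenerateDataError):
            co.fit_allometry([1500, 1600, 1700], [89, 89, 89])  # zero variance


class TestSeasonalCorrect:
    def test_constant_smi_passes_through(self):
        days = np.array([280, 290, 300, 310, 320])
        corrected, fit = co.seasonal_correct(np.full(5, 1464.2), days)
        assert np.allclose(corrected, 1464.2)

    def test_exactly_quadratic_collapses_to_sample_mean(self):
        days = np.arange(275, 335)
        smi = 1400 + 3.0 * days - 0.004 * days**2
        corrected, fit = co.seasonal_correct(smi, days)
        assert np.allclose(corrected, smi.mean())
        assert fit.r_squared == pytest.approx(1.0)

    def test_mean_preserved_and_coeffs_recovered(self):
        rng = np.random.default_rng(2)
        days = rng.integers(275, 336, 2000)
        truth = (800.0, 4.5, -0.007)
        smi = truth[0] + truth[1] * days + truth[2] * days**2 + rng.normal(0, 50, 2000)
        corrected, fit = co.seasonal_correct(smi, days)
        assert corrected.mean() == pytest.approx(smi.mean())
        # oracle: statsmodels OLS on the raw quadratic basis gives the SEs
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([days, days**2.0]))
        ols = sm.OLS(smi, X).fit()
        for est, tr, se in zip(fit.poly_coeffs, truth, ols.bse):
            assert abs(est - tr) < 3 * se
        assert np.allclose(fit.poly_coeffs, ols.params, rtol=1e-6)
        assert fit.df == (2, 1997)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        days = rng.integers(275, 336, 200)
        smi = 1464 + 2 * days - 0.003 * days**2 + rng.normal(0, 40, 200)
        corrected, _ = co.seasonal_correct(smi, days)
        again, _ = co.seasonal_correct(corrected, days)
        assert np.allclose(again, corrected)

    def test_identical_days_are_collinear(self):
        with pytest.raises(DegenerateDataError):
            co.seasonal_correct([1.0, 2.0, 3.0, 4.0], [300, 300, 300, 300])


class TestDetrendNao:
    def test_perfect_quadratic_leaves_zero_residuals(self):
        years = np.arange(1950, 2010)
        nao = 0.3 - 0.02 * (years - 1950) + 0.001 * (years - 1950) ** 2
        series = co.detrend_nao(years, nao)
        assert np.allclose(series.residuals, 0.0, atol=1e-9)

    def test_outlier_response_equals_hat_matrix_projection(self):
        """Adding d at one year perturbs the residuals by (I - H) e_j d,
        computed independently from the explicit OLS projection."""
        years = np.arange(1990, 2010).astype(float)
        base = 0.1 + 0.05 * (years - 2000) - 0.002 * (years - 2000) ** 2
        d = 1.7
        bumped = base.copy()
        bumped[7] += d
        series = co.detrend_nao(years.astype(int), bumped)
        yc = years - years.mean()  # centred basis keeps the oracle well conditioned
        X = np.column_stack([np.ones_like(yc), yc, yc**2])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        expected = (np.eye(len(years)) - H)[:, 7] * d
        assert np.allclose(series.residuals, expected, atol=1e-8)

    def test_residuals_orthogonal_to_design_and_recentring_invariant(self):
        rng = np.random.default_rng(4)
        years = np.arange(1950, 2013)
        nao = 0.2 + 0.01 * years % 7 + rng.normal(0, 1.0, len(years))
        series = co.detrend_nao(years, nao)
        for col in (np.ones_like(years), years, years**2):
            assert abs(series.residuals @ col.astype(float)) < 1e-6 * np.abs(col).sum()
        shifted = co.detrend_nao(years - 1980, nao)
        assert np.allclose(series.residuals, shifted.residuals, atol=1e-8)

    def test_residual_sd_recovered_from_generator(self):
        cfg = co.SimConfig(n_years=60, nao_resid_sd=1.0, seed=5)
        ds = co.generate_dataset(cfg)
        series = co.detrend_nao(ds.nao["year"], ds.nao["june_nao"])
        sd = np.std(series.residuals, ddof=3)
        se = 1.0 / np.sqrt(2 * (60 - 3))
        assert abs(sd - cfg.nao_resid_sd) < 3 * se

    def test_too_few_years(self):
        with pytest.raises(DegenerateDataError):
            co.detrend_nao([2005, 2006, 2007], [0.1, 0.2, 0.3])


@pytest.mark.parametrize(
    "offspring, associate, no_juv, with_juv, expected",
    [
        (0, True, 2, 0, "excluded"),  # too few juvenile-free records
        (0, False, 3, 0, "excluded"),  # no adult associate
        (0, True, 5, 0, "non_breeder"),
        (0, True, 3, 0, "non_breeder"),  # threshold is inclusive
        (2, True, 0, 1, "breeder"),
        (1, False, 10, 2, "breeder"),  # any juvenile sighting wins
    ],
)
def test_breeder_rule_branches(offspring, associate, no_juv, with_juv, expected):
    assert co.assign_breeder_status(offspring, associate, no_juv, with_juv) == expected


def test_breeder_rule_never_calls_juvenile_sighting_non_breeder():
    for no_juv in range(6):
        for associate in (True, False):
            assert (
                co.assign_breeder_status(1, associate, no_juv, 1) == "breeder"
            )


class TestZTransform:
    def test_basic_and_roundtrip(self):
        z, mean, sd = co.z_transform([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert np.allclose(inverse_z(z, mean, sd), [1, 2, 3], atol=1e-12)

    def test_location_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        z1, *_ = co.z_transform(x)
        z2, *_ = co.z_transform(x + 100.0)
        assert np.allclose(z1, z2)

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            co.z_transform([2.0, 2.0, 2.0])


class TestPreprocessDataset:
    def test_output_schema_and_standardisation(self, preprocessed):
        df = preprocessed.data
        for col in ["smi_g", "corrected_mass_g", "mass_z", "nao_resid", "nao_z", "status"]:
            assert col in df.columns
        assert abs(df["mass_z"].mean()) < 1e-10
        assert df["mass_z"].std(ddof=1) == pytest.approx(1.0)
        assert df["nao_z"].std(ddof=1) == pytest.approx(1.0)
        assert set(df["status"]) <= {"breeder", "non_breeder"}

    def test_corrected_mass_mean_equals_smi_mean(self, study_dataset):
        ds, rs, _ = study_dataset
        prep = co.preprocess_dataset(ds.birds, ds.nao, rs, sma_slope=3.4)
        full = ds.birds  # seasonal fit runs on the full capture table
        smi = co.scaled_mass_index(
            full["mass_g"], full["skull_mm"], prep.allometry.reference_length_mm, 3.4
        )
        assert prep.seasonal.sample_mean_mass_g == pytest.approx(np.mean(smi))

    def test_missing_morphometrics_are_dropped_with_count(self, study_dataset):
        ds, rs, _ = study_dataset
        birds = ds.birds.copy()
        birds.loc[birds.index[:5], "mass_g"] = np.nan
        prep = co.preprocess_dataset(birds, ds.nao, rs, sma_slope=3.4)
        assert prep.n_dropped_missing == 5

    def test_standardized_covariates_track_generator_truth(self):
        """With enough years for the NAO trend to be estimable, the derived
        standardized covariates closely track the generating ones.  (At only
        6 years the quadratic detrend absorbs about half the NAO residual
        variance by construction, so fidelity is checked at 30 years.)"""
        ds = co.generate_dataset(co.SimConfig(n_years=30, n_birds_per_year=50, seed=77))
        prep = co.preprocess_dataset(ds.birds, ds.nao, sma_slope=3.4)
        sub = ds.birds.set_index("bird_id").loc[prep.data["bird_id"]]
        r_mass = np.corrcoef(prep.data["mass_z"], sub["mass_z_true"])[0, 1]
        r_nao = np.corrcoef(prep.data["nao_z"], sub["nao_z_true"])[0, 1]
        assert r_mass > 0.95
        assert r_nao > 0.95
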