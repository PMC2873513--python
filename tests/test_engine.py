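import numpy as np
import pytest

from lcsem import (
    CovarianceSummary,
    CovEdge,
    Edge,
    Fixed,
    Free,
    IdentificationError,
    ModelSpec,
    OptimOptions,
    fit_ml,
    implied_covariance,
    ml_discrepancy,
    standard_errors,
    standardize,
    wald_interval,
)
from lcsem.models import longitudinal_structural_spec

from conftest import make_cov


class TestImpliedCovariance:
    def test_two_indicator_hand_expansion(self, toy_factor_spec):
        sigma = implied_covariance(toy_factor_spec, {})
        np.testing.assert_allclose(sigma, [[2, 2], [2, 5]])

    def test_zero_loadings_give_residual_diagonal(self, free_factor_spec):
        theta = {"l2": 0, "l3": 0, "l4": 0, "e1": 1.5, "e2": 2.5, "e3": 3.5, "e4": 4.5, "psi": 7}
        sigma = implied_covariance(free_factor_spec, theta)
        # x1 still carries the fixed loading 1: var = psi + e1
        np.testing.assert_allclose(sigma, np.diag([8.5, 2.5, 3.5, 4.5]))

    def test_longitudinal_spec_implied_is_pd(self, male_params):
        sigma = male_params.implied_analysis_covariance()
        assert sigma.shape == (11, 11)
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_missing_label_errors(self, free_factor_spec):
        with pytest.raises(ValueError, match="missing labels"):
            implied_covariance(free_factor_spec, {"l2": 1})


class TestMLDiscrepancy:
    def test_identity_at_equal_matrices(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        S = X.T @ X / 40
        assert ml_discrepancy(S, S.copy()) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_case(self):
        val = ml_discrepancy(np.array([[2.0]]), np.array([[1.0]]))
        assert val == pytest.approx(np.log(1) + 2 - np.log(2) - 1, abs=1e-12)
        assert val == pytest.approx(0.30685, abs=1e-5)

    def test_nonnegative_over_random_pd_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.integers(2, 6)
            a = rng.normal(size=(p + 3, p))
            b = rng.normal(size=(p + 3, p))
            S = a.T @ a / (p + 3)
            sig = b.T @ b / (p + 3)
            assert ml_discrepancy(S, sig) >= -1e-10

    def test_non_pd_input_errors(self):
        from lcsem import NotPositiveDefiniteError

        with pytest.raises(NotPositiveDefiniteError):
            ml_discrepancy(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestFitML:
    def test_saturated_recovery_identity(self, free_factor_spec):
        theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
                  "e3": 2.0, "e4": 0.9, "psi": 2.5}
        sigma = implied_covariance(free_factor_spec, theta0)
        cov = make_cov(free_factor_spec.observed, sigma, n=500)
        fit = fit_ml(free_factor_spec, cov)
        assert fit.converged
        assert fit.F_ML < 1e-10
        for k, v in theta0.items():
            assert fit.estimates[k] == pytest.approx(v, abs=1e-6)

    def test_triad_closed_form_oracle(self):
        """Just-identified 3-indicator factor model matches method of moments."""
        spec = ModelSpec(
            variables=["x1", "x2", "x3", "f"],
            latents={"f"},
            edges=[
                Edge("f", "x1", Fixed(1.0)),
                Edge("f", "x2", Free("l2")),
                Edge("f", "x3", Free("l3")),
            ],
            covs=[
                CovEdge("x1", "x1", Free("e1")),
                CovEdge("x2", "x2", Free("e2")),
                CovEdge("x3", "x3", Free("e3")),
                CovEdge("f", "f", Free("psi")),
            ],
        )
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1.3, size=4000)
        X = np.column_stack(
            [
                f + rng.normal(0, 0.9, 4000),
                0.7 * f + rng.normal(0, 0.8, 4000),
                1.5 * f + rng.normal(0, 1.1, 4000),
            ]
        )
        S = np.cov(X, rowvar=False, ddof=1)
        fit = fit_ml(spec, make_cov(["x1", "x2", "x3"], S, 4000))
        assert fit.converged and fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        # triad relations: psi = s12 s13 / s23, l2 = s12/psi, l3 = s13/psi
        psi = S[0, 1] * S[0, 2] / S[1, 2]
        assert fit.estimates["psi"] == pytest.approx(psi, abs=1e-6)
        assert fit.estimates["l2"] == pytest.approx(S[0, 1] / psi, abs=1e-6)
        assert fit.estimates["l3"] == pytest.approx(S[0, 2] / psi, abs=1e-6)
        assert fit.estimates["e1"] == pytest.approx(S[0, 0] - psi, abs=1e-5)

    def test_unscaled_latents_not_identified(self):
        spec = ModelSpec(
            variables=["x1", "x2", "x3", "x4", "f", "g"],
            latents={"f", "g"},
            edges=[
                Edge("f", "x1", Free("a1")),
                Edge("f", "x2", Free("a2")),
                Edge("g", "x3", Free("b1")),
                Edge("g", "x4", Free("b2")),
            ],
            covs=[CovEdge(v, v, Free(f"e_{v}")) for v in ["x1", "x2", "x3", "x4"]]
            + [CovEdge("f", "f", Free("pf")), CovEdge("g", "g", Free("pg"))],
        )
        with pytest.raises(IdentificationError, match="not identified"):
            spec.validate()

    def test_equality_constraint_nesting_inequality(self, male_params):
        from lcsem.models import latent_change_measurement_spec
        from lcsem import derive_analysis_dataset, sample_covariance, simulate
        from lcsem.models import BASELINE_INDICATORS, CHANGE_INDICATORS

        table = simulate(male_params, seed=99, n=400)
        ds = derive_analysis_dataset(table, "male")
        cov = sample_covariance(ds)
        idx = [cov.labels.index(v) for v in BASELINE_INDICATORS + CHANGE_INDICATORS]
        sub = make_cov(
            BASELINE_INDICATORS + CHANGE_INDICATORS, cov.S[np.ix_(idx, idx)], cov.n
        )
        f_con = fit_ml(latent_change_measurement_spec(constrained=True), sub).F_ML
        f_unc = fit_ml(latent_change_measurement_spec(constrained=False), sub).F_ML
        assert f_con >= f_unc - 1e-10

    def test_chi_square_multiplier_is_n_minus_one(self, free_factor_spec):
        theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
                  "e3": 2.0, "e4": 0.9, "psi": 2.5}
        sigma = implied_covariance(free_factor_spec, theta0)
        sigma_perturbed = sigma + 0.05 * np.eye(4)
        cov = make_cov(free_factor_spec.observed, sigma_perturbed, n=101)
        fit = fit_ml(free_factor_spec, cov)
        assert fit.chi_square == pytest.approx(100 * fit.F_ML, rel=1e-12)


@pytest.fixture(scope="module")
def fitted(free_factor_spec):
    theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
              "e3": 2.0, "e4": 0.9, "psi": 2.5}
    rng = np.random.default_rng(21)
    sigma = implied_covariance(free_factor_spec, theta0)
    X = rng.multivariate_normal(np.zeros(4), sigma, size=800)
    S = np.cov(X, rowvar=False, ddof=1)
    return fit_ml(free_factor_spec, make_cov(free_factor_spec.observed, S, 800))


class TestStandardErrors:

    def test_se_scaling_law(self, fitted):
        se_800 = dict(fitted.se)
        standard_errors(fitted, n=1600)
        factor = np.sqrt(799 / 1599)
        for k in se_800:
            assert fitted.se[k] == pytest.approx(se_800[k] * factor, rel=1e-9)
        standard_errors(fitted, n=800)  # restore

    def test_se_calibration_against_monte_carlo(self, free_factor_spec):
        """Empirical SD of estimates across replicates matches reported SEs."""
        theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
                  "e3": 2.0, "e4": 0.9, "psi": 2.5}
        sigma = implied_covariance(free_factor_spec, theta0)
        rng = np.random.default_rng(8)
        ests, ses = [], []
        for _ in range(500):
            X = rng.multivariate_normal(np.zeros(4), sigma, size=2000)
            S = np.cov(X, rowvar=False, ddof=1)
            fit = fit_ml(free_factor_spec, make_cov(free_factor_spec.observed, S, 2000))
            if fit.converged:
                ests.append([fit.estimates[k] for k in theta0])
                ses.append([fit.se[k] for k in theta0])
        ests, ses = np.array(ests), np.array(ses)
        emp_sd = ests.std(axis=0, ddof=1)
        mean_se = ses.mean(axis=0)
        assert np.all(np.abs(emp_sd - mean_se) / mean_se < 0.15)

    def test_collinear_information_detected(self):
        # two loadings stacked on the same indicator are not separable
        spec = ModelSpec(
            variables=["x1", "x2", "x3", "f"],
            latents={"f"},
            edges=[
                Edge("f", "x1", Fixed(1.0)),
                Edge("f", "x2", Free("l2")),
                Edge("f", "x3", Free("a")),
                Edge("f", "x3", Free("b")),
            ],
            covs=[
                CovEdge("x1", "x1", Free("e1")),
                CovEdge("x2", "x2", Free("e2")),
                CovEdge("x3", "x3", Free("e3")),
                CovEdge("f", "f", Fixed(1.0)),
            ],
        )
        sigma = np.array([[2.0, 0.8, 1.2], [0.8, 1.6, 0.9], [1.2, 0.9, 2.5]])
        with pytest.raises(IdentificationError, match="singular information"):
            fit_ml(spec, make_cov(["x1", "x2", "x3"], sigma, 200))


class TestWaldInterval:
    @pytest.mark.parametrize(
        "est,se,lo,hi",
        [(0.438, 0.134, 0.18, 0.70), (0.577, 0.183, 0.22, 0.94)],
    )
    def test_printed_intervals(self, est, se, lo, hi):
        lower, upper, t = wald_interval(est, se, 0.95)
        assert round(lower, 2) == lo
        assert round(upper, 2) == hi
        assert t == pytest.approx(est / se)

    def test_zero_estimate_symmetric(self):
        lower, upper, _ = wald_interval(0.0, 1.7, 0.95)
        assert lower == -upper

    def test_nonpositive_se_errors(self):
        with pytest.raises(ValueError):
            wald_interval(1.0, 0.0)


class TestStandardize:
    def test_toy_hand_computation(self, free_factor_spec):
        theta0 = {"l2": 2.0, "l3": 0.5, "l4": 0.9, "e1": 1.0, "e2": 1.0,
                  "e3": 1.0, "e4": 1.0, "psi": 1.0}
        sigma = implied_covariance(free_factor_spec, theta0)
        fit = fit_ml(free_factor_spec, make_cov(free_factor_spec.observed, sigma, 300))
        std = standardize(fit)
        # indicator 2: var = 4 + 1 = 5, standardized loading 2/sqrt(5)
        assert std.coefficients[("f", "x2")] == pytest.approx(2 / np.sqrt(5), abs=1e-6)
        assert std.r_squared["x2"] == pytest.approx(0.80, abs=1e-6)

    def test_scale_invariance_after_refit(self, free_factor_spec):
        theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
                  "e3": 2.0, "e4": 0.9, "psi": 2.5}
        sigma = implied_covariance(free_factor_spec, theta0)
        cov = make_cov(free_factor_spec.observed, sigma, 300)
        std1 = standardize(fit_ml(free_factor_spec, cov))
        D = np.diag([1.0, 10.0, 1.0, 1.0])
        cov10 = make_cov(free_factor_spec.observed, D @ sigma @ D, 300)
        std10 = standardize(fit_ml(free_factor_spec, cov10))
        assert std10.coefficients[("f", "x2")] == pytest.approx(
            std1.coefficients[("f", "x2")], abs=1e-6
        )

    def test_r2_equals_squared_loading_for_single_factor(self, free_factor_spec):
        theta0 = {"l2": 0.8, "l3": 1.4, "l4": 0.5, "e1": 1.0, "e2": 0.7,
                  "e3": 2.0, "e4": 0.9, "psi": 2.5}
        sigma = implied_covariance(free_factor_spec, theta0)
        fit = fit_ml(free_factor_spec, make_cov(free_factor_spec.observed, sigma, 300))
        std = standardize(fit)
        for x in ["x1", "x2", "x3", "x4"]:
            assert std.r_squared[x] == pytest.approx(
                std.coefficients[("f", x)] ** 2, abs=1e-8
            )

    def test_constrained_loading_yields_two_standardized_values(self, male_params):
        from lcsem import derive_analysis_dataset, sample_covariance, simulate

        table = simulate(male_params, seed=5, n=3000)
        ds = derive_analysis_dataset(table, "male")
        fit = fit_ml(longitudinal_structural_spec(), sample_covariance(ds))
        std = standardize(fit)
        b = std.coefficients[("A0", "log_bmi0")]
        c = std.coefficients[("A1", "d_log_bmi")]
        assert b != pytest.approx(c, abs=1e-3)  # same raw loading, two scales
        assert abs(b) <= 1 and abs(c) <= 1.0 + 1e-9


def test_model_spec_serialization_round_trip():
    spec = longitudinal_structural_spec()
    clone = type(spec).from_json(spec.to_json())
    assert clone.to_dict() == spec.to_dict()
    assert clone.free_labels == spec.free_labels
    assert clone.df() == spec.df()
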