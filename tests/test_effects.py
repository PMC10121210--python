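import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nof1steps.design import TrialDesign
from nof1steps.effects import (
    MASSAGE_VS_UC,
    MASSAGE_VS_YOGA,
    NEGATIVE,
    NO_EFFECT,
    POSITIVE,
    YOGA_VS_UC,
    Ar1Model,
    FeasibleGlsResult,
    RankDeficiencyError,
    RegressionProblem,
    analyze_participant,
    ar1_correlation,
    ar1_covariance,
    build_design,
    classify_effect,
    contrasts,
    estimate_ar1,
    feasible_gls,
    gls_fit,
    ols_fit,
)
from nof1steps.simulate import SimulationParams, generate_daily_series


def daily_series_from_design(design, sequence_index=0, totals=None):
    labels = design.day_labels(sequence_index)
    n = len(labels)
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": "P001",
            "day_index": np.arange(n),
            "block": labels,
            "total_steps": totals if totals is not None else rng.normal(7000, 500, n),
            "fraction_imputed": 0.0,
            "weekday": 1,
            "temperature_f": 60.0,
        }
    )


def random_problem(rng, n=20, p=3):
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    y = rng.normal(size=n)
    cols = ["intercept"] + [f"x{i}" for i in range(1, p)]
    return RegressionProblem(y=y, X=X, columns=cols, day_index=np.arange(n))


class TestBuildDesign:
    def test_default_shape(self, design):
        problem = build_design(daily_series_from_design(design))
        assert problem.X.shape == (84, 3)
        assert problem.X[:, 1].sum() == 28  # yoga days
        assert problem.X[:, 2].sum() == 28  # massage days
        assert problem.columns == ["intercept", "yoga", "massage"]

    def test_include_baseline(self, design):
        problem = build_design(daily_series_from_design(design), include_baseline=True)
        assert problem.n == 98
        baseline_rows = problem.X[:14]
        assert (baseline_rows[:, 1:] == 0).all()

    def test_carryover_column_count(self, design):
        # oracle: direct scan of block boundaries in sequence A
        lag = 2
        series = daily_series_from_design(design, 0)
        problem = build_design(series, carryover_lag_days=lag)
        labels = design.day_labels(0)[14:]  # analysis days
        expected = 0
        for i, lbl in enumerate(labels):
            block_idx = i // design.block_days
            day_in_block = i % design.block_days
            if block_idx > 0 and day_in_block < lag:
                prev = design.sequences[0][block_idx - 1]
                if prev in ("YOGA", "MASSAGE"):
                    expected += 1
        assert problem.X[:, 3].sum() == expected == 6

    def test_missing_treatment_raises(self, design):
        series = daily_series_from_design(design)
        series.loc[series["block"] == "MASSAGE", "block"] = "USUAL_CARE"
        with pytest.raises(RankDeficiencyError, match="MASSAGE"):
            build_design(series)


class TestOls:
    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        problem = RegressionProblem(
            y=y, X=np.ones((4, 1)), columns=["intercept"], day_index=np.arange(4)
        )
        beta, resid = ols_fit(problem)
        assert beta[0] == pytest.approx(3.0)
        np.testing.assert_allclose(resid, y - 3.0, atol=1e-12)

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        problem = random_problem(rng, n=12, p=3)
        b = np.array([2.0, -1.0, 0.5])
        problem.y = problem.X @ b
        beta, resid = ols_fit(problem)
        np.testing.assert_allclose(beta, b, atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        problem = random_problem(rng, n=10, p=3)
        beta, _ = ols_fit(problem)
        X, y = problem.X, problem.y
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(beta, oracle, atol=1e-10)


class TestEstimateAr1:
    def test_perfect_alternation_near_minus_one(self):
        model = estimate_ar1(np.array([1.0, -1.0] * 3))
        assert model.rho == pytest.approx(-5 / 6)
        long = estimate_ar1(np.array([1.0, -1.0] * 50))
        assert long.rho == pytest.approx(-0.99, abs=0.01)
        assert long.rho > -0.999  # clamp bound respected

    def test_iid_null(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=10_000)
        model = estimate_ar1(e)
        assert abs(model.rho) < 3 / np.sqrt(len(e))

    def test_sigma2_dof_correction(self):
        e = np.array([1.0, -1.0, 2.0, -2.0, 1.0])
        model = estimate_ar1(e, n_params=2)
        assert model.sigma2 == pytest.approx((e @ e) / 3)

    def test_zero_variance_residuals(self):
        with pytest.warns(RuntimeWarning):
            model = estimate_ar1(np.zeros(10))
        assert model.rho == 0.0

    def test_small_sample_bias_band(self):
        # oracle: empirical distribution of the estimator on AR(1) paths
        rng = np.random.default_rng(4)
        n, rho = 84, 0.3
        estimates = []
        for _ in range(2000):
            e = np.empty(n)
            e[0] = rng.normal(0, 1)
            for i in range(1, n):
                e[i] = rho * e[i - 1] + rng.normal(0, np.sqrt(1 - rho**2))
            estimates.append(estimate_ar1(e).rho)
        mean_rho = np.mean(estimates)
        assert 0.24 < mean_rho < 0.30  # known small-sample negative bias


class TestAr1Covariance:
    def test_independent_case(self):
        V = ar1_covariance(Ar1Model(rho=0.0, sigma2=4.0), 3)
        np.testing.assert_allclose(V, np.diag([4.0, 4.0, 4.0]))

    def test_direct_entries(self):
        V = ar1_covariance(Ar1Model(rho=0.5, sigma2=1.0), 3)
        expected = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        np.testing.assert_allclose(V, expected)

    @given(
        rho=st.floats(min_value=-0.95, max_value=0.95),
        sigma2=st.floats(min_value=0.01, max_value=100.0),
        n=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_positive_definite(self, rho, sigma2, n):
        V = ar1_covariance(Ar1Model(rho=rho, sigma2=sigma2), n)
        eigvals = np.linalg.eigvalsh(V)
        assert (eigvals > 0).all()

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            Ar1Model(rho=1.0, sigma2=1.0)


class TestGls:
    def test_identity_v_equals_ols(self):
        rng = np.random.default_rng(5)
        problem = random_problem(rng)
        beta_gls, _ = gls_fit(problem, np.eye(problem.n))
        beta_ols, _ = ols_fit(problem)
        np.testing.assert_allclose(beta_gls, beta_ols, atol=1e-10)

    def test_precision_weighted_mean(self):
        rng = np.random.default_rng(6)
        n = 15
        y = rng.normal(size=n)
        V = ar1_covariance(Ar1Model(rho=0.4, sigma2=2.0), n)
        problem = RegressionProblem(
            y=y, X=np.ones((n, 1)), columns=["intercept"], day_index=np.arange(n)
        )
        beta, _ = gls_fit(problem, V)
        ones = np.ones(n)
        Vinv = np.linalg.inv(V)
        expected = (ones @ Vinv @ y) / (ones @ Vinv @ ones)
        assert beta[0] == pytest.approx(expected, abs=1e-10)

    def test_whitening_matches_direct_inverse(self):
        # oracle: explicit dense-inverse evaluation of the GLS formula
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(8, 50))
            problem = random_problem(rng, n=n, p=3)
            rho = float(rng.uniform(-0.9, 0.9))
            V = ar1_covariance(Ar1Model(rho=rho, sigma2=float(rng.uniform(0.5, 4))), n)
            beta, _ = gls_fit(problem, V)
            Vinv = np.linalg.inv(V)
            direct = np.linalg.inv(problem.X.T @ Vinv @ problem.X) @ (
                problem.X.T @ Vinv @ problem.y
            )
            assert np.max(np.abs(beta - direct)) < 1e-8

    def test_non_positive_definite_rejected(self):
        rng = np.random.default_rng(8)
        problem = random_problem(rng, n=5)
        V = -np.eye(5)
        with pytest.raises(Exception):
            gls_fit(problem, V)


class TestFeasibleGls:
    def test_null_rho_converges_near_ols(self, design):
        params = SimulationParams(
            treatment_daily_effect={"YOGA": 0.0, "MASSAGE": 0.0},
            ar1_rho=0.0,
            daily_sd=800.0,
        )
        series = generate_daily_series(params, design, 0, seed=9)
        problem = build_design(series)
        result = feasible_gls(problem)
        beta_ols, _ = ols_fit(problem)
        assert result.converged
        assert abs(result.ar1.rho) < 0.2
        np.testing.assert_allclose(result.beta, beta_ols, rtol=0.05, atol=40.0)

    def test_noiseless_exact(self):
        rng = np.random.default_rng(10)
        problem = random_problem(rng, n=20, p=3)
        b = np.array([5.0, 1.0, -2.0])
        problem.y = problem.X @ b
        with pytest.warns(RuntimeWarning):  # zero-variance residuals
            result = feasible_gls(problem)
        np.testing.assert_allclose(result.beta, b, atol=1e-8)

    def test_location_equivariance(self):
        rng = np.random.default_rng(11)
        problem = random_problem(rng, n=30, p=3)
        shifted = RegressionProblem(
            y=problem.y + 123.0,
            X=problem.X.copy(),
            columns=list(problem.columns),
            day_index=problem.day_index.copy(),
        )
        r1 = feasible_gls(problem)
        r2 = feasible_gls(shifted)
        np.testing.assert_allclose(r2.beta[0], r1.beta[0] + 123.0, atol=1e-6)
        np.testing.assert_allclose(r2.beta[1:], r1.beta[1:], atol=1e-6)

    def test_parameter_recovery_smoke(self, design):
        params = SimulationParams(
            treatment_daily_effect={"YOGA": 1500.0, "MASSAGE": 500.0},
            ar1_rho=0.3,
            daily_sd=2000.0,
        )
        betas = []
        for rep in range(50):
            series = generate_daily_series(params, design, rep % 2, seed=500 + rep)
            estimates, _ = analyze_participant(series)
            betas.append([e.beta_hat for e in estimates])
        mean = np.mean(betas, axis=0)
        se = np.std(betas, axis=0, ddof=1) / np.sqrt(50)
        for m, s, truth in zip(mean, se, (1500.0, 500.0, -1000.0)):
            assert abs(m - truth) < 4 * s


class TestClassifyAndContrasts:
    def test_positive(self):
        assert classify_effect(200.0, 800.0) == POSITIVE

    def test_negative(self):
        assert classify_effect(-600.0, -50.0) == NEGATIVE

    def test_no_effect(self):
        assert classify_effect(-100.0, 300.0) == NO_EFFECT

    def _result(self, beta, cov, n=30):
        p = len(beta)
        rng = np.random.default_rng(12)
        X = np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]
        )[:, :p]
        problem = RegressionProblem(
            y=np.zeros(n),
            X=X,
            columns=["intercept", "yoga", "massage"][:p],
            day_index=np.arange(n),
        )
        return FeasibleGlsResult(
            beta=np.asarray(beta, dtype=float),
            cov=np.asarray(cov, dtype=float),
            ar1=Ar1Model(rho=0.0, sigma2=1.0),
            converged=True,
            n_iter=1,
            problem=problem,
        )

    def test_equal_betas_zero_contrast(self):
        result = self._result([0.0, 300.0, 300.0], np.eye(3) * 100.0)
        ests = {e.contrast: e for e in contrasts(result)}
        assert ests[MASSAGE_VS_YOGA].beta_hat == pytest.approx(0.0)

    def test_independent_ses_combine(self):
        cov = np.diag([1.0, 100.0, 100.0])
        result = self._result([0.0, 10.0, 20.0], cov)
        ests = {e.contrast: e for e in contrasts(result)}
        assert ests[MASSAGE_VS_YOGA].se == pytest.approx(np.sqrt(200.0))
        assert ests[YOGA_VS_UC].se == pytest.approx(10.0)
        assert ests[MASSAGE_VS_UC].se == pytest.approx(10.0)

    def test_contrast_variance_quadratic_form_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + 0.1 * np.eye(3)
            result = self._result([0.0, 1.0, 2.0], cov)
            ests = {e.contrast: e for e in contrasts(result)}
            c = np.array([0.0, -1.0, 1.0])
            assert ests[MASSAGE_VS_YOGA].se == pytest.approx(
                np.sqrt(c @ cov @ c), rel=1e-12
            )

    def test_labels_consistent_with_cis(self):
        cov = np.diag([1.0, 4.0, 4.0])
        result = self._result([0.0, 500.0, -500.0], cov)
        ests = {e.contrast: e for e in contrasts(result)}
        assert ests[YOGA_VS_UC].label == POSITIVE
        assert ests[MASSAGE_VS_UC].label == NEGATIVE
        for e in ests.values():
            assert e.ci_low < e.ci_high
            assert e.label == classify_effect(e.ci_low, e.ci_high)
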