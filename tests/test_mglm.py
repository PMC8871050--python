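"""MGLM core: OLS against the normal equations, SSCP identities, Wilks /
Bartlett / Rao values computed by hand, canonical vectors, invariances,
and a cross-check against an independent MANOVA implementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from massmva import (
    DesignMatrix,
    HypothesisContrast,
    bartlett_chi2,
    build_design,
    canonical_vectors,
    chi2_upper_tail,
    fit_mglm,
    hypothesis_sscp,
    rao_f,
    region_test,
    wilks_lambda,
)
from tests.conftest import cohort_frame, random_design


def _design(X, roles):
    return DesignMatrix(X, roles)


def _random_instance(rng, n=20, p=3, n_confounds=2):
    X, roles = random_design(rng, n, n_confounds)
    Y = rng.standard_normal((n, p))
    return Y, _design(X, roles), HypothesisContrast(
        np.eye(X.shape[1])[1:2]
    )


class TestFit:
    def test_intercept_only_is_column_mean(self):
        """OLS with only an intercept is the column mean; E is the centered
        sum of squares (2.25 + 0.25 + 0.25 + 2.25 = 5)."""
        from types import SimpleNamespace

        Xi = SimpleNamespace(matrix=np.ones((4, 1)), n=4, rank=1)
        fit = fit_mglm(np.array([[1.0], [2.0], [3.0], [4.0]]), Xi)
        assert fit.B[0, 0] == pytest.approx(2.5)
        assert fit.E[0, 0] == pytest.approx(5.0)
        assert fit.error_df == 3

    def test_noiseless_data_gives_zero_residual_sscp(self, rng):
        X, roles = random_design(rng, 12, 2)
        B0 = rng.standard_normal((4, 3))
        fit = fit_mglm(X @ B0, _design(X, roles))
        assert np.allclose(fit.E, 0, atol=1e-10)
        assert np.allclose(fit.B, B0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        """B must equal the explicit (X'X)^-1 X'Y solution."""
        X, roles = random_design(rng, 8, 1)
        Y = rng.standard_normal((8, 2))
        fit = fit_mglm(Y, _design(X, roles))
        B_oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        assert np.allclose(fit.B, B_oracle, atol=1e-10)
        R = Y - X @ B_oracle
        assert np.allclose(fit.E, R.T @ R, atol=1e-10)

    def test_row_mismatch_and_no_error_df(self, rng):
        X, roles = random_design(rng, 6, 1)
        with pytest.raises(ValueError, match="rows"):
            fit_mglm(rng.standard_normal((5, 2)), _design(X, roles))
        with pytest.raises(ValueError, match="error degrees"):
            DesignMatrix(np.column_stack([np.ones(3), [0, 1, 1], [1, 2, 3]]),
                         ["intercept", "group", "confound"])

    def test_rank_deficient_design_uses_min_norm(self, rng):
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5),
                             np.repeat([1, 0], 5)])  # third = 1 - second
        d = DesignMatrix(X, ["intercept", "group", "group"])
        assert d.rank == 2
        Y = rng.standard_normal((10, 2))
        fit = fit_mglm(Y, d)
        assert fit.error_df == 8
        proj = X @ np.linalg.pinv(X)
        assert np.allclose(fit.E, Y.T @ (np.eye(10) - proj) @ Y, atol=1e-8)


class TestHypothesisSSCP:
    def test_equal_group_means_give_zero_H(self, rng):
        block = rng.standard_normal((5, 3))
        Y = np.vstack([block, block])
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        d = _design(X, ["intercept", "group"])
        C = HypothesisContrast([[0.0, 1.0]])
        H = hypothesis_sscp(fit_mglm(Y, d), d, C)
        assert np.allclose(H, 0, atol=1e-10)

    def test_one_way_anova_by_hand(self):
        """Groups {1,2,3} vs {3,4,5}: between-group SS = 3(2-3)^2 + 3(4-3)^2 = 6."""
        Y = np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]])
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        d = _design(X, ["intercept", "group"])
        fit = fit_mglm(Y, d)
        H = hypothesis_sscp(fit, d, HypothesisContrast([[0.0, 1.0]]))
        assert H[0, 0] == pytest.approx(6.0)
        assert fit.E[0, 0] == pytest.approx(4.0)  # within-group SS

    def test_extra_sscp_identity(self, rng):
        """H must equal E_reduced - E_full where the reduced model drops the
        group column (independent route to the same matrix)."""
        Y, d, C = _random_instance(rng)
        fit = fit_mglm(Y, d)
        H = hypothesis_sscp(fit, d, C)
        X_red = np.delete(d.matrix, 1, axis=1)
        R_red = Y - X_red @ np.linalg.lstsq(X_red, Y, rcond=None)[0]
        E_red = R_red.T @ R_red
        assert np.allclose(H, E_red - fit.E, atol=1e-8)
        # H is PSD
        assert np.all(np.linalg.eigvalsh(H) > -1e-10)

    def test_inestimable_contrast_rejected(self, rng):
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5),
                             np.repeat([1, 0], 5)])
        d = DesignMatrix(X, ["intercept", "group", "group"])
        fit = fit_mglm(rng.standard_normal((10, 2)), d)
        with pytest.raises(ValueError, match="estimable"):
            hypothesis_sscp(fit, d, HypothesisContrast([[0.0, 1.0, 1.0]]))


class TestWilksLambda:
    def test_null_hypothesis_gives_one(self):
        assert wilks_lambda(np.zeros((2, 2)), np.eye(2)) == 1.0

    def test_hand_determinants(self):
        # det(I)/det(diag(2,4)) = 1/8
        assert wilks_lambda(np.diag([1.0, 3.0]), np.eye(2)) == pytest.approx(0.125)

    def test_univariate_ratio(self):
        assert wilks_lambda([[6.0]], [[6.0]]) == pytest.approx(0.5)

    def test_singular_E_advises(self):
        with pytest.raises(np.linalg.LinAlgError, match="more subjects"):
            wilks_lambda(np.eye(2), np.array([[1.0, 1.0], [1.0, 1.0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1.001, 50.0))
    def test_scaling_H_never_increases_lambda(self, seed, c):
        r = np.random.default_rng(seed)
        A = r.standard_normal((4, 3))
        E = A.T @ A + 0.1 * np.eye(3)
        Bm = r.standard_normal((4, 3))
        H = Bm.T @ Bm
        assert wilks_lambda(c * H, E) <= wilks_lambda(H, E) + 1e-12


class TestBartlettRao:
    def test_lambda_one_is_zero_statistic(self):
        chi2, df = bartlett_chi2(1.0, 44, 5, 3, 1)
        assert chi2 == 0.0 and df == 3
        F, df1, df2 = rao_f(1.0, 44, 5, 3, 1)
        assert F == 0.0 and df1 == 3

    def test_bartlett_arithmetic_by_hand(self):
        # scale = 10 - 2 - (2 - 1 + 1)/2 = 7; chi2 = 7 ln 8
        chi2, df = bartlett_chi2(0.125, 10, 2, 2, 1)
        assert chi2 == pytest.approx(7 * np.log(8.0), rel=1e-12)
        assert df == 2

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            bartlett_chi2(0.5, 5, 4, 3, 1)

    def test_rao_f_equals_anova_f_univariate(self):
        # H=6, E=4, n=6, r=2 -> Lambda = 4/10; F = (0.6/0.4)*4 = 6
        lam = wilks_lambda([[6.0]], [[4.0]])
        assert lam == pytest.approx(0.4)
        F, df1, df2 = rao_f(lam, 6, 2, 1, 1)
        assert F == pytest.approx(6.0, rel=1e-12)
        assert (df1, df2) == (1, 4)
        # and matches scipy's one-way ANOVA directly
        F_scipy = stats.f_oneway([1, 2, 3], [3, 4, 5]).statistic
        assert F == pytest.approx(F_scipy, rel=1e-12)

    def test_chi2_upper_tail(self):
        assert chi2_upper_tail(0.0, 5) == 1.0
        assert chi2_upper_tail(3.84, 1) == pytest.approx(0.05, abs=2e-3)
        with pytest.raises(ValueError):
            chi2_upper_tail(-1.0, 3)
        with pytest.raises(ValueError):
            chi2_upper_tail(1.0, 0)


class TestCanonicalVectors:
    def test_scalar_case(self):
        vecs, vals = canonical_vectors([[3.0]], [[1.5]])
        assert vecs[0, 0] == pytest.approx(1.0)
        assert vals[0] == pytest.approx(2.0)

    def test_diagonal_eigenproblem_by_inspection(self):
        vecs, vals = canonical_vectors(np.diag([3.0, 1.0]), np.eye(2))
        assert np.allclose(vals, [3.0, 1.0])
        assert np.allclose(np.abs(vecs), np.eye(2), atol=1e-12)
        assert vecs[0, 0] > 0 and vecs[1, 1] > 0  # sign convention

    def test_unit_norm_and_descending(self, rng):
        for _ in range(10):
            A = rng.standard_normal((6, 3))
            E = A.T @ A + 0.5 * np.eye(3)
            Bm = rng.standard_normal((2, 3))
            H = Bm.T @ Bm
            vecs, vals = canonical_vectors(H, E)
            assert np.allclose(np.linalg.norm(vecs, axis=0), 1.0, atol=1e-10)
            assert np.all(np.diff(vals) <= 1e-12)
            assert np.all(vals >= 0)
            for j in range(3):
                k = np.argmax(np.abs(vecs[:, j]))
                assert vecs[k, j] > 0


class TestRegionTest:
    def test_composition_equals_manual_chain(self, rng):
        Y, d, C = _random_instance(rng)
        res = region_test(Y, d, C, region_id=7, region_name="demo")
        fit = fit_mglm(Y, d)
        H = hypothesis_sscp(fit, d, C)
        lam = wilks_lambda(H, fit.E)
        chi2, df = bartlett_chi2(lam, d.n, d.rank, 3, 1)
        assert res.wilks_lambda == pytest.approx(lam, abs=1e-14)
        assert res.chi_square == pytest.approx(chi2, abs=1e-12)
        assert res.df == df
        assert res.p_value == pytest.approx(chi2_upper_tail(chi2, df), abs=1e-14)
        vecs, vals = canonical_vectors(H, fit.E)
        assert np.allclose(res.canonical_vector, vecs[:, 0])

    def test_eigenvalue_product_identity(self, rng):
        """Wilks lambda must equal prod 1/(1+lambda_i) of the canonical
        eigenvalues on every tested region."""
        for _ in range(10):
            Y, d, C = _random_instance(rng)
            res = region_test(Y, d, C)
            assert res.wilks_lambda == pytest.approx(
                np.prod(1.0 / (1.0 + res.canonical_eigenvalues)), abs=1e-10
            )
            assert np.linalg.norm(res.canonical_vector) == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_statsmodels_manova(self, rng):
        """Independent cross-check: statsmodels' MANOVA Wilks lambda and F
        for the group term must match ours."""
        from statsmodels.multivariate.manova import MANOVA

        Y, d, C = _random_instance(rng, n=30)
        res = region_test(Y, d, C)
        mv = MANOVA(endog=Y, exog=d.matrix)
        L = np.zeros((1, d.matrix.shape[1]))
        L[0, 1] = 1.0
        sm_tbl = mv.mv_test(hypotheses=[("group", L, None)])
        frame = sm_tbl.results["group"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(frame.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert res.f_stat == pytest.approx(
            float(frame.loc["Wilks' lambda", "F Value"]), rel=1e-6
        )
        assert res.f_p_value == pytest.approx(
            float(frame.loc["Wilks' lambda", "Pr > F"]), abs=1e-8
        )

    def test_affine_invariance(self, rng):
        """Y -> Y A (nonsingular A) leaves Lambda, chi-square and p unchanged."""
        Y, d, C = _random_instance(rng)
        base = region_test(Y, d, C)
        for _ in range(5):
            A = rng.standard_normal((3, 3)) + 0.5 * np.eye(3)
            if abs(np.linalg.det(A)) < 1e-3:
                continue
            t = region_test(Y @ A, d, C)
            assert t.wilks_lambda == pytest.approx(base.wilks_lambda, abs=1e-8)
            assert t.chi_square == pytest.approx(base.chi_square, abs=1e-8)
            assert t.p_value == pytest.approx(base.p_value, abs=1e-8)

    def test_confound_invariance(self, rng):
        """Adding any linear function of the confound columns to Y cannot
        change H, E or Lambda (the hypothesis is orthogonal to nuisance)."""
        Y, d, C = _random_instance(rng)
        fit = fit_mglm(Y, d)
        H = hypothesis_sscp(fit, d, C)
        lam = wilks_lambda(H, fit.E)
        G = rng.standard_normal((len(d.confound_columns), Y.shape[1]))
        Y2 = Y + d.matrix[:, d.confound_columns] @ G
        fit2 = fit_mglm(Y2, d)
        H2 = hypothesis_sscp(fit2, d, C)
        assert np.allclose(fit2.E, fit.E, atol=1e-8)
        assert np.allclose(H2, H, atol=1e-8)
        assert wilks_lambda(H2, fit2.E) == pytest.approx(lam, abs=1e-8)

    def test_null_pvalues_uniform(self):
        """Under the null (no group effect) the Bartlett p-values over many
        replicates should be close to uniform."""
        r = np.random.default_rng(404)
        X, roles = random_design(r, 44, 3)
        d = DesignMatrix(X, roles)
        C = HypothesisContrast(np.eye(5)[1:2])
        pvals = [region_test(r.standard_normal((44, 3)), d, C).p_value
                 for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_direction_recovered(self):
        """A strong planted group shift along (0.6, 0.8, 0) must be recovered
        by the leading canonical vector (|cosine| >= 0.95)."""
        from massmva import SyntheticCohortSpec, simulate_cohort, tensor_from_cohort

        direction = np.array([0.6, 0.8, 0.0])
        spec = SyntheticCohortSpec(
            n_group1=200, n_group2=200, n_regions=1, effect_size=2.0,
            effect_direction=direction, affected_regions={0},
            noise_covariance=np.eye(3), seed=77,
        )
        cohort = simulate_cohort(spec)
        X, C = build_design(cohort)
        res = region_test(tensor_from_cohort(cohort)[0], X, C)
        cos = abs(res.canonical_vector @ direction)
        assert cos >= 0.95


def test_build_design_roles_and_contrast(rng):
    cohort = cohort_frame(rng)
    X, C = build_design(cohort)
    assert X.column_roles == ["intercept", "group", "confound", "confound", "confound"]
    assert C.q == 1 and C.matrix[0, 1] == 1.0
    with pytest.raises(ValueError, match="2 levels"):
        bad = cohort.copy()
        bad.loc[0, "diagnosis"] = "c"
        build_design(bad)
    with pytest.raises(ValueError, match="not in cohort"):
        build_design(cohort, confounds=("age", "missing_col"))
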