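"""Connectivity scorers versus independent brute-force oracles."""

import numpy as np
import pytest

from consensus_grn import (
    ContractError,
    DimensionError,
    ExpressionMatrix,
    ParameterError,
    ScoringParams,
    SingularityError,
    score,
    score_correlation,
    score_pcr,
    score_pls,
    score_ridge,
    standardize,
    symmetrize_scores,
)

import oracles
from conftest import random_matrix


def orthogonal_rows_matrix(p=4, n=8):
    """Standardized matrix whose gene rows are exactly mutually orthogonal."""
    rng = np.random.default_rng(42)
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    rows = q[:, :p].T  # orthonormal rows; still need mean 0 per row
    rows = rows - rows.mean(axis=1, keepdims=True)
    # re-orthogonalize the centered rows
    q2, _ = np.linalg.qr(rows.T)
    rows = q2[:, :p].T
    rows = rows - rows.mean(axis=1, keepdims=True)
    rows = rows / rows.std(axis=1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        [f"g{i}" for i in range(p)], [f"c{j}" for j in range(n)],
        rows, standardized=True,
    )


class TestSymmetrize:
    def test_symmetric_input_unchanged_off_diagonal(self):
        m = np.array([[9.0, 2.0], [2.0, 9.0]])
        out = symmetrize_scores(m)
        assert out[0, 1] == out[1, 0] == 2.0
        assert out[0, 0] == out[1, 1] == 0.0

    def test_averages_two_directions(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1.0
        out = symmetrize_scores(m)
        assert out[0, 1] == out[1, 0] == 0.5

    def test_antisymmetric_cancels(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((5, 5))
        anti = a - a.T
        np.testing.assert_array_equal(symmetrize_scores(anti), np.zeros((5, 5)))

    def test_non_square_rejected(self):
        with pytest.raises(DimensionError):
            symmetrize_scores(np.zeros((2, 3)))

    def test_output_exactly_symmetric(self):
        rng = np.random.default_rng(2)
        out = symmetrize_scores(rng.standard_normal((6, 6)))
        assert np.array_equal(out, out.T)


class TestCorrelation:
    def test_requires_standardized(self):
        with pytest.raises(ContractError):
            score_correlation(random_matrix(4, 6))

    def test_identical_rows_score_one(self):
        base = np.random.default_rng(0).standard_normal(8)
        x = standardize(ExpressionMatrix(
            ["a", "b", "c"], [f"c{j}" for j in range(8)],
            np.vstack([base, base, base[::-1]]),
        ))
        s = score_correlation(x).scores
        assert abs(s[0, 1] - 1.0) < 1e-12

    def test_negated_row_scores_minus_one(self):
        base = np.random.default_rng(1).standard_normal(8)
        x = standardize(ExpressionMatrix(
            ["a", "b"], [f"c{j}" for j in range(8)], np.vstack([base, -base]),
        ))
        assert abs(score_correlation(x).scores[0, 1] + 1.0) < 1e-12

    def test_matches_brute_force_pearson(self):
        x = standardize(random_matrix(5, 6, seed=9))
        s = score_correlation(x).scores
        raw = random_matrix(5, 6, seed=9).values
        for i in range(5):
            for k in range(i + 1, 5):
                expected = oracles.pearson_brute(list(raw[i]), list(raw[k]))
                assert abs(s[i, k] - expected) < 1e-12

    def test_bounded_in_minus_one_one(self, std_matrix_10x12):
        s = score_correlation(std_matrix_10x12).scores
        off = s[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) <= 1 + 1e-12)

    def test_invariant_to_positive_rescaling_of_raw_rows(self):
        raw = random_matrix(5, 7, seed=4)
        scaled = ExpressionMatrix(
            list(raw.gene_ids), list(raw.condition_ids),
            raw.values * np.array([1.0, 2.5, 10.0, 0.3, 7.0])[:, None],
        )
        s1 = score_correlation(standardize(raw)).scores
        s2 = score_correlation(standardize(scaled)).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestPcr:
    def test_full_components_equal_ols(self, std_matrix_10x12):
        s = score_pcr(std_matrix_10x12, k=9).scores
        expected = oracles.symmetrized(oracles.ols_directional(std_matrix_10x12.values))
        np.testing.assert_allclose(s, expected, atol=1e-8)

    def test_orthogonal_rows_give_zero_scores(self):
        x = orthogonal_rows_matrix()
        s = score_pcr(x, k=2).scores
        assert np.all(np.abs(s) < 1e-10)

    def test_near_duplicate_gene_dominates_its_row(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((6, 12))
        vals[3] = vals[0] + 1e-3 * rng.standard_normal(12)
        x = standardize(ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"c{j}" for j in range(12)], vals,
        ))
        s = score_pcr(x, k=2).scores
        assert np.argmax(np.abs(s[0])) == 3
        # low-rank scores still agree with the independent eigen-based oracle
        s1 = score_pcr(x, k=1).scores
        expected = oracles.symmetrized(oracles.pcr_directional(x.values, 1))
        np.testing.assert_allclose(s1, expected, atol=1e-9)

    def test_k_out_of_range_rejected(self, std_matrix_10x12):
        with pytest.raises(ParameterError):
            score_pcr(std_matrix_10x12, k=10)
        with pytest.raises(ParameterError):
            score_pcr(std_matrix_10x12, k=0)


class TestPls:
    def test_matches_literal_oracle(self, std_matrix_6x8):
        s = score_pls(std_matrix_6x8, v=2).scores
        expected = oracles.symmetrized(
            oracles.pls_directional(std_matrix_6x8.values, 2)
        )
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_orthogonal_rows_give_zero_scores(self):
        s = score_pls(orthogonal_rows_matrix(), v=2).scores
        assert np.all(np.abs(s) < 1e-10)

    def test_duplicated_pair_attains_max_score(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((6, 10))
        vals[4] = vals[1] + 1e-6 * rng.standard_normal(10)
        x = standardize(ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"c{j}" for j in range(10)], vals,
        ))
        s = np.abs(score_pls(x, v=2).scores)
        iu = np.triu_indices(6, k=1)
        best = np.argmax(s[iu])
        assert (iu[0][best], iu[1][best]) == (1, 4)

    def test_weights_match_reference_pls(self, std_matrix_10x12):
        """Latent weights and coefficients agree (up to paired sign flips)
        with scikit-learn's NIPALS PLS1 for a single target gene."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        vals = std_matrix_10x12.values
        design, y = vals[1:].T, vals[0]
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(
            design, y.reshape(-1, 1)
        )
        # weight-expanded directional coefficients: sum_l b_l w^(l)
        expected = (ref.x_weights_ * ref.y_loadings_.ravel()).sum(axis=1)
        ours = oracles.pls_directional(vals, 3)[0, 1:]
        impl = score_pls(std_matrix_10x12, v=3)
        np.testing.assert_allclose(ours, expected, atol=1e-10)
        assert impl.method == "pls"

    def test_v_out_of_range_rejected(self, std_matrix_6x8):
        with pytest.raises(ParameterError):
            score_pls(std_matrix_6x8, v=0)
        with pytest.raises(ParameterError):
            score_pls(std_matrix_6x8, v=6)


class TestRidge:
    def test_lambda_zero_equals_ols(self, std_matrix_10x12):
        s = score_ridge(std_matrix_10x12, 0.0).scores
        expected = oracles.symmetrized(oracles.ols_directional(std_matrix_10x12.values))
        np.testing.assert_allclose(s, expected, atol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self, std_matrix_10x12):
        s = score_ridge(std_matrix_10x12, 1e9).scores
        assert np.all(np.abs(s) < 1e-6)

    def test_matches_direct_solve(self):
        x = standardize(random_matrix(8, 10, seed=12))
        s = score_ridge(x, 1.0).scores
        expected = oracles.symmetrized(oracles.ridge_directional(x.values, 1.0))
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_matches_reference_ridge(self, std_matrix_10x12):
        Ridge = pytest.importorskip("sklearn.linear_model").Ridge
        vals = std_matrix_10x12.values
        design, y = vals[1:].T, vals[0]
        ref = Ridge(alpha=2.0, fit_intercept=False).fit(design, y)
        ours = oracles.ridge_directional(vals, 2.0)[0, 1:]
        np.testing.assert_allclose(ours, ref.coef_, atol=1e-10)

    def test_singular_design_with_zero_lambda_rejected(self):
        # p - 1 = 5 predictors but only 4 conditions: rank-deficient
        rng = np.random.default_rng(3)
        x = standardize(ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"c{j}" for j in range(4)],
            rng.standard_normal((6, 4)),
        ))
        with pytest.raises(SingularityError, match="lambda"):
            score_ridge(x, 0.0)

    def test_negative_lambda_rejected(self, std_matrix_6x8):
        with pytest.raises(ParameterError):
            score_ridge(std_matrix_6x8, -0.1)


class TestCrossMethodProperties:
    def test_pcr_full_and_ridge_zero_agree(self, std_matrix_10x12):
        a = score_pcr(std_matrix_10x12, k=9).scores
        b = score_ridge(std_matrix_10x12, 0.0).scores
        np.testing.assert_allclose(a, b, atol=1e-8)

    @pytest.mark.parametrize("method", ["correlation", "pcr", "pls", "ridge"])
    def test_gene_permutation_equivariance(self, method):
        x = standardize(random_matrix(7, 9, seed=21))
        params = ScoringParams(pcr_components=2, pls_components=2, ridge_lambda=0.5)
        s = score(x, method, params).scores
        rng = np.random.default_rng(5)
        perm = rng.permutation(7)
        xp = ExpressionMatrix(
            [x.gene_ids[i] for i in perm], list(x.condition_ids),
            x.values[perm], standardized=True,
        )
        sp = score(xp, method, params).scores
        np.testing.assert_allclose(sp, s[np.ix_(perm, perm)], atol=1e-9)

    @pytest.mark.parametrize("method", ["correlation", "pcr", "pls", "ridge"])
    def test_symmetric_with_zero_diagonal(self, method, std_matrix_10x12):
        s = score(std_matrix_10x12, method).scores
        assert np.array_equal(s, s.T)
        assert np.all(np.diag(s) == 0)
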