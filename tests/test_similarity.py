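"""Association measures: closed forms, null calibration, permutation p-values."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import mutual_info_score

from hiblock.config import AnalysisConfig
from hiblock.similarity import (
    _dcor_statistic,
    _spearman_beta_null,
    dcor_assoc,
    mi_assoc,
    mutual_information,
    nmi_assoc,
    pairwise_matrix,
    pearson_assoc,
    permutation_pvalue,
    spearman_assoc,
    xicor_assoc,
)

from conftest import make_table


class TestSpearman:
    def test_printed_three_point_example(self):
        r = spearman_assoc(np.array([1.0, 2, 3]), np.array([3.0, 1, 2]))
        assert r.statistic == pytest.approx(-0.5)

    def test_monotone_is_one(self, rng):
        x = rng.standard_normal(20)
        r = spearman_assoc(x, np.exp(x))
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value < 1e-7

    def test_reversed_is_minus_one(self, rng):
        x = rng.standard_normal(20)
        assert spearman_assoc(x, -x).statistic == pytest.approx(-1.0)

    def test_constant_vector_degenerate(self):
        r = spearman_assoc(np.ones(10), np.arange(10.0))
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_beta_null_exact_calibration_small_n(self):
        """Against the exhaustive permutation null at n=7, P(p <= t) ~ t."""
        n = 7
        u = np.arange(1, n + 1) - (n + 1) / 2
        v = float(np.sum(u ** 2))
        rhos = np.array(
            [float(np.dot(u, perm)) / v for perm in itertools.permutations(u)]
        )
        a, c = _spearman_beta_null(n)
        p = 2 * stats.beta.sf(np.clip((np.abs(rhos) / c + 1) / 2, 0, 1), a, a)
        for t in (0.2, 0.1, 0.05, 0.01):
            assert np.mean(p <= t) == pytest.approx(t, rel=0.35)

    def test_pvalue_close_to_scipy_in_bulk(self, rng):
        x, y = rng.standard_normal((2, 60))
        ours = spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.15, abs=0.01)


class TestPearson:
    def test_affine_invariance(self, rng):
        x = rng.standard_normal(15)
        assert pearson_assoc(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_assoc(x, -x).statistic == pytest.approx(-1.0)

    def test_printed_example(self):
        r = pearson_assoc(np.array([0.0, 1, 2]), np.array([0.0, 1, 4]))
        assert round(r.statistic, 4) == 0.9608

    def test_pvalue_matches_scipy(self, rng):
        x, y = rng.standard_normal((2, 40))
        ours = pearson_assoc(x, y)
        ref = stats.pearsonr(x, y)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestMutualInformation:
    def test_balanced_identical_two_bins_is_ln2(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert mutual_information(x, x) == pytest.approx(np.log(2))
        r = mi_assoc(x.astype(float), x.astype(float), n_perm=200, seed=0)
        assert r.statistic == pytest.approx(np.log(2))

    def test_product_joint_is_zero(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 50)
        y = rng.integers(0, 4, 50)
        assert mutual_information(x, y) == pytest.approx(mutual_info_score(x, y))
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_degenerate_single_level(self):
        r = mi_assoc(np.zeros(10), np.arange(10.0) % 2, n_perm=50, seed=0)
        assert (r.statistic, r.p_value) == (0.0, 1.0)


class TestNmi:
    def test_identical_balanced_is_one(self):
        x = np.array([0.0, 0, 0, 1, 1, 1])
        r = nmi_assoc(x, x, n_perm=100, seed=0)
        assert r.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 30).astype(float)
        y = rng.integers(0, 3, 30).astype(float)
        r = nmi_assoc(x, y, n_perm=20, seed=seed)
        assert 0.0 <= r.statistic <= 1.0


class TestXicor:
    @pytest.mark.parametrize("n", [5, 8, 20, 51])
    def test_monotone_no_ties_closed_form(self, n):
        x = np.arange(1.0, n + 1)
        r = xicor_assoc(x, x ** 3)
        assert r.statistic == pytest.approx((n - 2) / (n + 1))

    def test_asymmetric_in_arguments(self, rng):
        # y a function of x but not vice versa: xi(x,y) >> xi(y,x)
        x = np.linspace(-2, 2, 80)
        y = x ** 2
        fwd = xicor_assoc(x, y).statistic
        rev = xicor_assoc(y, x).statistic
        assert fwd > rev + 0.2

    def test_constant_y_degenerate(self):
        r = xicor_assoc(np.arange(10.0), np.ones(10))
        assert (r.statistic, r.p_value) == (0.0, 1.0)


class TestDcor:
    def test_identity_is_one(self, rng):
        x = rng.standard_normal(25)
        r = dcor_assoc(x, x, n_perm=20, seed=0)
        assert r.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_nonnegative_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 30))
        assert _dcor_statistic(x, y) >= 0.0
        assert _dcor_statistic(x, y) == pytest.approx(_dcor_statistic(y, x))


class TestPermutationPvalue:
    def test_floor_is_one_over_b_plus_one(self, rng):
        x = np.arange(30.0)
        p = permutation_pvalue(lambda a, b: np.corrcoef(a, b)[0, 1], x, x, 99, rng)
        assert p == pytest.approx(1 / 100)

    def test_bounds(self, rng):
        x, y = rng.standard_normal((2, 12))
        p = permutation_pvalue(lambda a, b: np.corrcoef(a, b)[0, 1], x, y, 49, 3)
        assert 1 / 50 <= p <= 1.0

    def test_deterministic_under_seed(self, rng):
        x, y = rng.standard_normal((2, 15))
        f = lambda a, b: abs(np.corrcoef(a, b)[0, 1])
        assert permutation_pvalue(f, x, y, 100, 7) == permutation_pvalue(f, x, y, 100, 7)

    def test_exhaustive_enumeration_oracle_n4(self):
        """MC permutation p converges to the exhaustive all-orderings value."""
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 1, 1])
        obs = mutual_information(x, y)
        hits = sum(
            abs(mutual_information(x, np.array(p))) >= abs(obs)
            for p in itertools.permutations(y)
        )
        exact = hits / 24
        mc = permutation_pvalue(mutual_information, x, y, 3000, 0)
        assert mc == pytest.approx(exact, abs=0.03)


class TestPairwiseMatrix:
    def test_shape_contract(self, rng):
        x = make_table(rng.standard_normal((2, 30)), "X")
        y = make_table(rng.standard_normal((3, 30)), "Y")
        res = pairwise_matrix(x, y, AnalysisConfig())
        assert res.S.shape == res.P.shape == res.Q.shape == (2, 3)

    def test_planted_identity_is_matrix_minimum(self, rng):
        X = rng.standard_normal((4, 30))
        Y = rng.standard_normal((5, 30))
        Y[2] = X[1]
        res = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig())
        assert res.P[1, 2] == res.P.min()

    def test_categorical_rejected_for_rank_measures(self, rng):
        x = make_table([[0.0, 1, 0, 1, 0, 1]], kinds=["categorical"])
        y = make_table(rng.standard_normal((1, 6)), "Y")
        with pytest.raises(ValueError, match="mi"):
            pairwise_matrix(x, y, AnalysisConfig(measure="spearman"))

    @pytest.mark.parametrize("measure", ["spearman", "pearson"])
    def test_fast_path_matches_per_pair_functions(self, rng, measure):
        X = rng.standard_normal((3, 25))
        Y = rng.standard_normal((4, 25))
        res = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig(measure=measure))
        fn = spearman_assoc if measure == "spearman" else pearson_assoc
        for i in range(3):
            for j in range(4):
                r = fn(X[i], Y[j])
                assert res.S[i, j] == pytest.approx(r.statistic, abs=1e-10)
                assert res.P[i, j] == pytest.approx(r.p_value, rel=1e-8, abs=1e-12)

    def test_missing_data_uses_pairwise_complete(self, rng):
        X = rng.standard_normal((2, 30))
        X[0, :3] = np.nan
        Y = rng.standard_normal((2, 30))
        res = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig())
        expected = spearman_assoc(X[0], Y[1])
        assert res.S[0, 1] == pytest.approx(expected.statistic)

    def test_xicor_matrix_matches_per_pair_statistic(self, rng):
        X = rng.standard_normal((3, 30))
        Y = rng.standard_normal((3, 30))
        cfg = AnalysisConfig(measure="xicor", seed=5)
        res = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), cfg)
        for i in range(3):
            for j in range(3):
                # no ties in x: the statistic does not depend on tie-break seed
                r = xicor_assoc(X[i], Y[j], seed=0)
                assert res.S[i, j] == pytest.approx(r.statistic, abs=1e-10)

    def test_joint_sample_permutation_invariance(self, rng):
        X = rng.standard_normal((2, 20))
        Y = rng.standard_normal((2, 20))
        perm = rng.permutation(20)
        a = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig())
        b = pairwise_matrix(make_table(X[:, perm], "X"), make_table(Y[:, perm], "Y"), AnalysisConfig())
        np.testing.assert_allclose(a.S, b.S, atol=1e-12)


@pytest.mark.parametrize("measure", ["spearman", "pearson"])
def test_null_pvalues_approximately_uniform(measure, rng):
    """Independent features at n=100: parametric p ~ U(0,1) (KS check)."""
    X = rng.standard_normal((30, 100))
    Y = rng.standard_normal((30, 100))
    res = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig(measure=measure))
    stat = stats.kstest(res.P.ravel(), "uniform").statistic
    assert stat < 0.05


def test_statistic_ranges(rng):
    X = rng.standard_normal((4, 40))
    Y = rng.standard_normal((4, 40))
    s_rank = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), AnalysisConfig()).S
    assert (np.abs(s_rank) <= 1).all()
    cfg = AnalysisConfig(measure="mi", n_permutations=10)
    s_mi = pairwise_matrix(make_table(X, "X"), make_table(Y, "Y"), cfg).S
    assert (s_mi >= 0).all()
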