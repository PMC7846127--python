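import numpy as np
import pytest
from hypothesis import given, strategies as st

from structkin import (
    AStatMatrix,
    a_min_subpops,
    a_statistic,
    coancestry_std_iaf,
    convert_relatedness,
    estimate_freqs,
    inbreeding_new,
    inbreeding_std,
    kinship_new,
    kinship_std,
    kinship_wg,
    rmse_relative,
    uniform_weights,
)
from structkin.evaluation import mean_relatedness_value
from structkin.limits import limit_kinship_std, limit_kinship_wg


class TestEstimateFreqs:
    @pytest.mark.parametrize(
        "col,w,expected",
        [
            ([0, 2], [0.5, 0.5], 0.5),
            ([1, 1], [0.5, 0.5], 0.5),
            ([0, 2], [0.25, 0.75], 0.75),
        ],
    )
    def test_genotype_columns(self, col, w, expected):
        X = np.array(col).reshape(2, 1)
        assert estimate_freqs(X, w).p_hat[0] == pytest.approx(expected)

    def test_iaf_drops_the_half(self):
        P = np.array([[0.2], [0.6]])
        assert estimate_freqs(P, [0.5, 0.5], data="iaf").p_hat[0] == pytest.approx(0.4)

    def test_rejects_nonpositive_weights(self):
        X = np.array([[0, 2], [2, 0]])
        with pytest.raises(ValueError):
            estimate_freqs(X, [0.0, 1.0])

    def test_rejects_missing_dosages(self):
        with pytest.raises(ValueError):
            estimate_freqs(np.array([[0, -1], [2, 0]]), [0.5, 0.5])


class TestKinshipStd:
    def test_two_individual_hand_example(self):
        # numerator -2, denominator 2 => kinship -1 for the opposed pair
        X = np.array([[0, 2], [2, 0]])
        K = kinship_std(X)
        assert K.values[0, 1] == pytest.approx(-1.0)

    def test_monomorphic_matrix_raises(self):
        with pytest.raises(ZeroDivisionError):
            kinship_std(np.zeros((3, 4), dtype=int))

    def test_all_heterozygote_matrix_is_zero(self):
        # p_hat = 0.5 everywhere: denominator positive, estimates all zero
        K = kinship_std(np.ones((3, 4), dtype=int))
        np.testing.assert_allclose(K.values, 0.0, atol=1e-15)

    def test_matches_limit_on_simulated_admixture(self, admix_bundle):
        b = admix_bundle
        K = kinship_std(b.X)
        lim = limit_kinship_std(convert_relatedness(b.theta_true, "kinship"))
        pm = mean_relatedness_value(b.theta_true)
        assert rmse_relative(K, lim, pm) < 15.0  # percent of mean kinship

    def test_ratio_of_means_closer_to_limit_than_mean_of_ratios(self, admix_bundle):
        b = admix_bundle
        lim = limit_kinship_std(convert_relatedness(b.theta_true, "kinship"))
        pm = mean_relatedness_value(b.theta_true)
        rom = rmse_relative(kinship_std(b.X), lim, pm)
        mor = rmse_relative(kinship_std(b.X, form="mean_of_ratios"), lim, pm)
        assert rom < mor


class TestInbreedingStd:
    def test_fully_homozygous_individual_stdII_is_one(self, rng):
        X = rng.choice([0, 2], size=(4, 50))
        X[1] = rng.integers(0, 3, 50)  # keep p_hat polymorphic
        f = inbreeding_std(X, variant="stdII")
        assert f[0] == pytest.approx(1.0)

    def test_fully_heterozygous_individual_stdII(self, rng):
        X = rng.integers(0, 3, size=(4, 60))
        X[2] = 1
        p = estimate_freqs(X, uniform_weights(4)).p_hat
        expected = 1 - 60 / (2 * np.sum(p * (1 - p)))
        assert inbreeding_std(X, variant="stdII")[2] == pytest.approx(expected)

    def test_std_matches_kinship_diagonal(self, rng):
        X = rng.integers(0, 3, size=(5, 40))
        f = inbreeding_std(X, variant="std")
        K = kinship_std(X)
        np.testing.assert_allclose(f, 2 * np.diag(K.values) - 1, rtol=1e-12)


class TestAStatistic:
    @pytest.mark.parametrize(
        "xj,xk,expected",
        [
            ([0, 2], [2, 0], -2.0),  # opposed homozygotes
            ([1, 1], [1, 1], -1.0),  # heterozygote products vanish
            ([0, 2], [0, 2], 0.0),  # identical homozygotes, self-pair
        ],
    )
    def test_hand_values(self, xj, xk, expected):
        X = np.array([xj, xk])
        A = a_statistic(X)
        assert A.values[0, 1] == pytest.approx(expected)
        if xj == xk:
            assert A.values[0, 0] == pytest.approx(expected)

    @given(
        st.integers(2, 6).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(0, 2), min_size=4, max_size=4),
                min_size=n, max_size=n,
            )
        )
    )
    def test_algebraic_bounds(self, rows):
        A = a_statistic(np.array(rows))
        assert A.values.min() >= -2.0 - 1e-12
        assert A.values.max() <= 0.0 + 1e-12

    def test_expectation_proportional_to_kinship_minus_one(self, rng):
        # unrelated outbred pair: E[A_jk] = -v = -(4/m) sum p(1-p)
        m, reps = 200, 400
        p = rng.uniform(0.1, 0.5, m)
        v = 4 * np.mean(p * (1 - p))
        vals = np.empty(reps)
        for r in range(reps):
            X = rng.binomial(2, p, size=(2, m)).astype(np.int8)
            vals[r] = a_statistic(X).values[0, 1]
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() + v) < 3 * se + 1e-12

    def test_freq_estimate_variance_inflated_by_mean_kinship(self, rng):
        # Var(p_hat) ~= p(1-p) * phi_bar: n individuals from one drifted
        # subpopulation share coancestry f, so p_hat does not concentrate
        n, f, p0, reps = 50, 0.2, 0.3, 2000
        phat = np.empty(reps)
        for r in range(reps):
            nu = 1 / f - 1
            ps = rng.beta(p0 * nu, (1 - p0) * nu)
            x = rng.binomial(2, ps, size=n)
            phat[r] = x.mean() / 2
        phi_bar = (n - 1) / n * f + (1 + f) / (2 * n)  # uniform-weight mean kinship
        expected = p0 * (1 - p0) * phi_bar
        assert phat.var(ddof=1) == pytest.approx(expected, rel=0.15)


class TestAMin:
    def test_brute_force_over_three_groups(self, rng):
        v = rng.uniform(-1.5, -0.1, (9, 9))
        v = (v + v.T) / 2
        A = AStatMatrix(values=v, m_loci=2)
        labels = np.repeat([0, 1, 2], 3)
        groups = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        expected = min(
            v[np.ix_(groups[a], groups[b])].mean()
            for a in range(3) for b in range(a + 1, 3)
        )
        assert a_min_subpops(A, labels) == pytest.approx(expected)

    def test_two_groups_and_singletons(self):
        v = np.array([[0.0, -0.4, -0.9], [-0.4, 0.0, -0.2], [-0.9, -0.2, 0.0]])
        A = AStatMatrix(values=v, m_loci=1)
        assert a_min_subpops(A, [0, 0, 1]) == pytest.approx((-0.9 - 0.2) / 2)
        # singleton blocks: minimum over individual cross-block entries
        assert a_min_subpops(A, [0, 1, 2]) == pytest.approx(-0.9)

    def test_single_group_raises(self):
        A = AStatMatrix(values=-np.eye(3), m_loci=1)
        with pytest.raises(ValueError, match="unrelated"):
            a_min_subpops(A, [0, 0, 0])


class TestKinshipNew:
    def test_rescaling_arithmetic(self):
        v = np.array([[-0.8, -0.5], [-0.5, -0.8]])
        A = AStatMatrix(values=v, m_loci=1)
        K = kinship_new(A, -0.8)
        assert K.values[0, 0] == pytest.approx(0.0)  # A == a_min -> zero kinship
        assert K.values[0, 1] == pytest.approx(0.375)
        K2 = kinship_new(AStatMatrix(values=np.zeros((2, 2)), m_loci=1), -0.3)
        assert K2.values[0, 0] == pytest.approx(1.0)  # A == 0 -> kinship 1

    def test_nonnegative_a_min_rejected(self):
        A = AStatMatrix(values=-np.eye(2), m_loci=1)
        with pytest.raises(ValueError):
            kinship_new(A, 0.0)

    def test_inbreeding_new(self):
        from structkin import RelatednessMatrix
        K = RelatednessMatrix(np.diag([0.5, 1.0, 0.55]), form="kinship")
        np.testing.assert_allclose(inbreeding_new(K), [0.0, 1.0, 0.1], atol=1e-12)

    def test_recovers_truth_on_simulated_admixture(self, admix_bundle):
        b = admix_bundle
        A = a_statistic(b.X)
        K = kinship_new(A, a_min_subpops(A, b.partition.labels))
        pm = mean_relatedness_value(b.theta_true)
        assert rmse_relative(K, b.theta_true, pm) < 15.0


class TestKinshipWG:
    def test_pair_at_average_maps_to_zero(self):
        v = np.array([[-0.2, -0.5, -0.8], [-0.5, -0.2, -0.5],
                      [-0.8, -0.5, -0.2]])
        A = AStatMatrix(values=v, m_loci=1)
        K = kinship_wg(A)
        a_avg = v[~np.eye(3, dtype=bool)].mean()
        assert a_avg == pytest.approx(-0.6)
        assert K.values[0, 2] == pytest.approx(1 - (-0.8) / (-0.6))

    def test_matches_wg_limit_on_admixture(self, admix_bundle):
        b = admix_bundle
        K = kinship_wg(a_statistic(b.X))
        lim = limit_kinship_wg(convert_relatedness(b.theta_true, "kinship"))
        pm = mean_relatedness_value(b.theta_true)
        assert rmse_relative(K, lim, pm) < 15.0


class TestCoancestryIAF:
    def test_identical_rows_zero_matrix(self):
        P = np.tile(np.linspace(0.1, 0.9, 12), (4, 1))
        C = coancestry_std_iaf(P)
        np.testing.assert_allclose(C.values, 0.0, atol=1e-12)

    def test_two_subpop_single_locus(self):
        C = coancestry_std_iaf(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(
            C.values, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12
        )

    def test_matches_limit_on_admixture(self, admix_bundle):
        from structkin.limits import limit_coancestry_std
        b = admix_bundle
        C = coancestry_std_iaf(b.iaf)
        lim = limit_coancestry_std(b.theta_true)
        pm = mean_relatedness_value(b.theta_true)
        assert rmse_relative(C, lim, pm) < 5.0
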