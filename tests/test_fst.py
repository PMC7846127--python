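import numpy as np
import pytest

from structkin import (
    RelatednessMatrix,
    SubpopPartition,
    fst_adjust_s,
    fst_adjust_theta,
    fst_hudson_k,
    fst_hudson_pair,
    fst_indep,
    fst_new,
    fst_std,
    fst_wc,
    fst_weir_hill,
    fst_wg_individuals,
    inbreeding_std,
    uniform_weights,
)
from structkin.fst import (
    fst_hudson_k_from_freqs,
    fst_hudson_pair_from_freqs,
    fst_wc_from_freqs,
    fst_weir_hill_from_freqs,
)
from structkin.limits import limit_fst_indep


class TestFstIndep:
    def test_fixed_alternative_alleles(self):
        assert fst_indep(np.array([[0.0], [1.0]])).value == pytest.approx(1.0)

    def test_identical_rows_zero(self):
        P = np.tile(np.linspace(0.1, 0.9, 7), (3, 1))
        assert fst_indep(P).value == pytest.approx(0.0, abs=1e-15)

    def test_single_locus_hand_value(self):
        # p=(0.2,0.4): sigma2=0.02, p_bar q_bar + sigma2/2 = 0.21+0.01
        est = fst_indep(np.array([[0.2], [0.4]]))
        assert est.value == pytest.approx(0.02 / 0.22)
        assert est.value == pytest.approx(est.numerator_sum / est.denominator_sum)


class TestInfiniteSampleReduction:
    """With true frequencies and vanishing corrections, WC, Weir-Hill and
    HudsonK all collapse to the idealized independent-subpopulations
    estimator."""

    @pytest.fixture
    def freqs(self, rng):
        return rng.uniform(0.05, 0.95, size=(6, 300))

    @pytest.mark.parametrize(
        "fn", [fst_wc_from_freqs, fst_weir_hill_from_freqs, fst_hudson_k_from_freqs]
    )
    def test_collapse_at_infinite_sizes(self, freqs, fn):
        target = fst_indep(freqs).value
        sizes = np.full(freqs.shape[0], np.inf)
        assert fn(freqs, sizes).value == pytest.approx(target, abs=1e-12)

    @pytest.mark.parametrize(
        "fn", [fst_wc_from_freqs, fst_weir_hill_from_freqs, fst_hudson_k_from_freqs]
    )
    def test_finite_formulas_approach_the_limit(self, freqs, fn):
        target = fst_indep(freqs).value
        sizes = np.full(freqs.shape[0], 1e6)
        assert fn(freqs, sizes).value == pytest.approx(target, abs=1e-4)


class TestHudson:
    def test_opposite_fixation_is_one(self):
        freqs = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert fst_hudson_pair_from_freqs(freqs, [50, 50]).value == pytest.approx(1.0)

    def test_single_locus_hand_value(self):
        est = fst_hudson_pair_from_freqs(np.array([[0.2], [0.4]]), [50, 50])
        expected = (0.04 - 0.16 / 99 - 0.24 / 99) / 0.44
        assert est.value == pytest.approx(expected)

    def test_identical_frequencies_slightly_negative(self):
        p = np.linspace(0.2, 0.8, 40)
        est = fst_hudson_pair_from_freqs(np.vstack([p, p]), [30, 30])
        assert -0.05 < est.value < 0.0

    def test_requires_two_groups(self, rng):
        X = rng.integers(0, 3, (6, 10))
        with pytest.raises(ValueError):
            fst_hudson_pair(X, [0, 0, 1, 1, 2, 2])

    def test_hudson_k_equals_pairwise_for_two_groups(self, rng):
        X = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(8, 50)).astype(np.int8)
        labels = [0, 1] * 4
        pair = fst_hudson_pair(X, labels)
        k2 = fst_hudson_k(X, labels)
        # identical up to the shared factor 1/2 in numerator and denominator
        assert k2.value == pytest.approx(pair.value, rel=1e-12)

    def test_hudson_k_consistent_on_independent_subpops(self, indep_bundle):
        b = indep_bundle
        est = fst_hudson_k(b.X, b.partition)
        assert est.value == pytest.approx(b.fst, abs=0.01)


class TestWCandWH:
    def test_wc_near_truth_on_independent_subpops(self, indep_bundle):
        b = indep_bundle
        est = fst_wc(b.X, b.partition)
        # WC assumes equal differentiation across groups: small bias only
        assert est.value == pytest.approx(b.fst, abs=0.02)

    def test_wc_maximal_differentiation(self):
        X = np.vstack([np.zeros((20, 30)), np.full((20, 30), 2)]).astype(np.int8)
        est = fst_wc(X, [0] * 20 + [1] * 20)
        assert est.value == pytest.approx(1.0, abs=0.03)

    def test_wh_identical_group_frequencies_near_zero(self, rng):
        p = rng.uniform(0.3, 0.7, 80)
        X = rng.binomial(2, p, size=(60, 80)).astype(np.int8)
        est = fst_weir_hill(X, [0, 1, 2] * 20)
        assert abs(est.value) < 0.02

    def test_wh_matches_transformed_limit_on_admixture(self, admix_bundle):
        b = admix_bundle
        est = fst_weir_hill(b.X, b.partition)
        assert est.value == pytest.approx(limit_fst_indep(b.theta_true), abs=0.015)

    def test_empty_group_rejected(self, rng):
        X = rng.integers(0, 3, (4, 10))
        with pytest.raises(ValueError):
            fst_wc(X, np.array(["a", "a", "a", "a"]))  # single group: K < 2


class TestFstStd:
    def test_two_individual_hand_value(self):
        est = fst_std(np.array([[0, 2], [2, 0]]))
        assert est.value == pytest.approx(1.0)

    def test_identical_iaf_rows_zero(self):
        P = np.tile(np.linspace(0.2, 0.8, 9), (5, 1))
        assert fst_std(P, data="iaf").value == pytest.approx(0.0, abs=1e-14)

    def test_three_inbreeding_variants_same_plugin(self, rng):
        X = rng.binomial(2, rng.uniform(0.1, 0.9, 60), size=(12, 60)).astype(np.int8)
        w = rng.dirichlet(np.ones(12))
        plug = fst_std(X, w).value
        for variant in ("std", "stdII", "stdIII"):
            f = inbreeding_std(X, w, variant=variant)
            assert float(w @ f) == pytest.approx(plug, rel=1e-12)

    def test_biased_toward_transformed_value_on_admixture(self, admix_bundle):
        b = admix_bundle
        est = fst_std(b.X, b.weights)
        from structkin.limits import limit_fst_std_from_s
        assert est.value == pytest.approx(limit_fst_std_from_s(0.1, 0.5), abs=0.015)


class TestAdjustments:
    def test_adjust_theta_trivials(self):
        assert fst_adjust_theta(0.0, 0.3) == pytest.approx(0.3)
        assert fst_adjust_theta(0.42, 0.0) == pytest.approx(0.42)
        with pytest.raises(ValueError):
            fst_adjust_theta(0.1, 1.0)

    def test_adjust_s_full_bias_recovers_one(self):
        assert fst_adjust_s(0.37, 1.0) == pytest.approx(1.0)

    def test_adjust_inverts_limit_exactly(self):
        fst, s = 0.1, 0.5
        theta_bar = s * fst
        limit = (fst - theta_bar) / (1 - theta_bar)
        assert fst_adjust_theta(limit, theta_bar) == pytest.approx(fst, rel=1e-12)
        assert fst_adjust_s(limit, s) == pytest.approx(fst, rel=1e-12)

    def test_adjust_s_one_over_n_equals_fst_indep(self, rng):
        # the s = 1/n special case reproduces the idealized estimator exactly
        P = rng.uniform(0.05, 0.95, size=(9, 120))
        n = P.shape[0]
        adj = fst_adjust_s(fst_std(P, data="iaf").value, 1.0 / n)
        assert adj == pytest.approx(fst_indep(P).value, rel=1e-12)


class TestNewAndWG:
    def test_outbred_diagonal_gives_zero(self):
        K = RelatednessMatrix(np.full((4, 4), 0.2) + np.eye(4) * 0.3, form="kinship")
        assert fst_new(K, uniform_weights(4)).value == pytest.approx(0.0)

    def test_new_estimator_accurate_on_both_models(self, admix_bundle, indep_bundle):
        from structkin import a_min_subpops, a_statistic, kinship_new
        for b in (admix_bundle, indep_bundle):
            A = a_statistic(b.X)
            K = kinship_new(A, a_min_subpops(A, b.partition.labels))
            est = fst_new(K, b.weights)
            assert est.value == pytest.approx(b.fst, abs=0.01)

    def test_wg_targets_transformed_fst_on_admixture(self, admix_bundle):
        from structkin import a_statistic, kinship_wg
        from structkin.limits import limit_kinship_wg
        from structkin import convert_relatedness
        b = admix_bundle
        est = fst_wg_individuals(kinship_wg(a_statistic(b.X)))
        lim_mat = limit_kinship_wg(convert_relatedness(b.theta_true, "kinship"))
        target = float(np.mean(2 * np.diag(lim_mat.values) - 1))
        assert est.value == pytest.approx(target, abs=0.015)

    def test_ratio_invariant_holds_for_ratio_methods(self, indep_bundle):
        b = indep_bundle
        for est in (
            fst_wc(b.X, b.partition),
            fst_hudson_k(b.X, b.partition),
            fst_std(b.X, b.weights),
            fst_weir_hill(b.X, b.partition),
        ):
            assert est.value == pytest.approx(
                est.numerator_sum / est.denominator_sum, rel=1e-12
            )
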