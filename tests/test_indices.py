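import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ordqual.errors import DegenerateWeightsError, ScaleMismatchError, ValidationError
from ordqual.indices import (
    between_group_lottery,
    comparative_indices,
    lottery_index,
    pairwise_comparison,
    rank_agreement,
    variance_decomposition,
    within_group_lottery,
)
from ordqual.profiles import ProviderSet, QualityScale, aggregate_to_groups

from conftest import random_provider_set


def brute_force_comparison(a: np.ndarray, b: np.ndarray):
    """O(Q^2) double sum over all category pairs: the independent oracle."""
    p_better = p_worse = p_tie = 0.0
    for qa, ma in enumerate(a):
        for qb, mb in enumerate(b):
            if qb > qa:
                p_better += ma * mb
            elif qb < qa:
                p_worse += ma * mb
            else:
                p_tie += ma * mb
    return p_better, p_worse, p_tie


def profile_pair(rng, Q):
    scale = QualityScale("ordinal", tuple(f"c{q}" for q in range(Q)))
    mass = rng.dirichlet(np.ones(Q), size=2)
    ps = ProviderSet(scale, ["a", "b"], mass, np.array([0.5, 0.5]), ["g", "g"])
    return ps.profile("a"), ps.profile("b")


class TestPairwiseComparison:
    def test_worked_example(self, two_practice_set):
        """A random patient of A beats one of B 33% of the time, loses 32%, ties 35%."""
        cmp = pairwise_comparison(two_practice_set.profile("B"), two_practice_set.profile("A"))
        assert cmp.p_better == pytest.approx(0.33, abs=1e-12)
        assert cmp.p_worse == pytest.approx(0.32, abs=1e-12)
        assert cmp.p_tie == pytest.approx(0.35, abs=1e-12)
        assert cmp.delta == pytest.approx(0.01, abs=1e-12)

    def test_antisymmetry(self, two_practice_set):
        ab = pairwise_comparison(two_practice_set.profile("A"), two_practice_set.profile("B"))
        ba = pairwise_comparison(two_practice_set.profile("B"), two_practice_set.profile("A"))
        assert ab.delta == pytest.approx(-ba.delta, abs=1e-15)
        assert ab.p_better == ba.p_worse

    def test_identical_profiles(self, rng):
        a, _ = profile_pair(rng, 6)
        cmp = pairwise_comparison(a, a)
        assert cmp.delta == pytest.approx(0.0, abs=1e-15)
        assert cmp.p_tie == pytest.approx(np.sum(a.mass**2), abs=1e-15)

    def test_complete_separation(self):
        scale = QualityScale("ordinal", ("lo", "mid", "hi"))
        mass = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        ps = ProviderSet(scale, ["low", "high"], mass, np.array([0.5, 0.5]), ["g", "g"])
        cmp = pairwise_comparison(ps.profile("low"), ps.profile("high"))
        assert cmp.delta == 1.0 and cmp.p_tie == 0.0

    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(300):
            Q = int(rng.integers(2, 11))
            a, b = profile_pair(rng, Q)
            cmp = pairwise_comparison(a, b)
            pb, pw, pt = brute_force_comparison(a.mass, b.mass)
            assert abs(cmp.p_better - pb) < 1e-12
            assert abs(cmp.p_worse - pw) < 1e-12
            assert abs(cmp.p_tie - pt) < 1e-12
            assert abs(cmp.delta - (pb - pw)) < 1e-12

    def test_mismatched_scales_rejected(self, rng):
        a, _ = profile_pair(rng, 3)
        b, _ = profile_pair(rng, 4)
        with pytest.raises(ScaleMismatchError):
            pairwise_comparison(a, b)


class TestComparativeIndices:
    def test_worked_example_equal_weights(self, two_practice_set):
        """Delta_A = +0.005 and Delta_B = -0.005 at weights 1/2, 1/2."""
        ix = {i.provider_id: i.delta_k for i in comparative_indices(two_practice_set)}
        assert ix["A"] == pytest.approx(0.005, abs=1e-12)
        assert ix["B"] == pytest.approx(-0.005, abs=1e-12)

    def test_identical_profiles_all_zero(self):
        scale = QualityScale("ordinal", ("a", "b"))
        mass = np.tile([0.3, 0.7], (4, 1))
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g"] * 4)
        assert all(i.delta_k == pytest.approx(0.0, abs=1e-15) for i in comparative_indices(ps))

    def test_weighted_mean_zero_and_bounds(self, rng):
        for _ in range(20):
            ps = random_provider_set(rng, K=5, Q=4)
            ix = comparative_indices(ps)
            deltas = np.array([i.delta_k for i in ix])
            assert abs(ps.weights @ deltas) < 1e-10
            assert np.all(np.abs(deltas) <= 1.0 - ps.weights + 1e-12)

    def test_matches_brute_force_pairwise_oracle(self, rng):
        ps = random_provider_set(rng, K=5, Q=6)
        ix = {i.provider_id: i.delta_k for i in comparative_indices(ps)}
        for k, pid in enumerate(ps.ids):
            expect = 0.0
            for k2 in range(ps.K):
                pb, pw, _ = brute_force_comparison(ps.mass[k2], ps.mass[k])
                expect += ps.weights[k2] * (pb - pw)
            assert ix[pid] == pytest.approx(expect, abs=1e-12)

    def test_single_provider_rejected(self):
        scale = QualityScale("ordinal", ("a", "b"))
        ps = ProviderSet(scale, ["only"], np.array([[0.5, 0.5]]), np.array([1.0]), ["g"])
        with pytest.raises(ValidationError):
            comparative_indices(ps)


class TestLotteryIndex:
    def test_worked_example(self, two_practice_set):
        res = lottery_index(two_practice_set)
        assert res.L == pytest.approx(0.01, abs=1e-12)
        assert res.numerator == pytest.approx(0.005, abs=1e-12)
        assert res.normalizer == pytest.approx(0.5, abs=1e-15)
        assert res.choice_value == pytest.approx(0.005, abs=1e-12)

    def test_zero_on_identical_profiles(self, rng):
        scale = QualityScale("ordinal", tuple("abcd"))
        mass = np.tile(rng.dirichlet(np.ones(4)), (6, 1))
        ps = ProviderSet(scale, [f"p{i}" for i in range(6)], mass, np.ones(6), ["g"] * 6)
        assert lottery_index(ps).L == pytest.approx(0.0, abs=1e-15)

    def test_one_on_disjoint_equal_weight_supports(self):
        K = 4
        scale = QualityScale("ordinal", tuple(f"c{q}" for q in range(K)))
        ps = ProviderSet(scale, [f"p{i}" for i in range(K)], np.eye(K), np.ones(K), ["g"] * K)
        assert lottery_index(ps).L == pytest.approx(1.0, abs=1e-15)

    def test_binary_scale_closed_form(self, rng):
        """On a 0/1 scale L is the normalized weighted mean absolute
        difference in the proportion receiving good care."""
        for _ in range(30):
            K = int(rng.integers(2, 9))
            good = rng.uniform(size=K)
            w = rng.dirichlet(np.ones(K))
            scale = QualityScale("ordinal", ("bad", "good"))
            mass = np.column_stack([1 - good, good])
            ps = ProviderSet(scale, [f"p{i}" for i in range(K)], mass, w, ["g"] * K)
            expect = sum(
                w[i] * w[j] * abs(good[i] - good[j]) for i in range(K) for j in range(K)
            ) / (1 - np.sum(w**2))
            assert lottery_index(ps).L == pytest.approx(expect, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(25):
            ps = random_provider_set(rng, K=int(rng.integers(2, 10)), Q=5)
            assert 0.0 <= lottery_index(ps).L <= 1.0

    def test_degenerate_weights_rejected(self):
        scale = QualityScale("ordinal", ("a", "b"))
        mass = np.array([[0.5, 0.5], [0.2, 0.8]])
        ps = ProviderSet(scale, ["x", "y"], mass, np.array([1.0, 0.0]), ["g", "g"])
        with pytest.raises(DegenerateWeightsError):
            lottery_index(ps)


class TestGroupedLottery:
    def two_identical_groups(self, two_practice_set):
        scale = two_practice_set.scale
        mass = np.vstack([two_practice_set.mass, two_practice_set.mass])
        return ProviderSet(
            scale, ["A1", "B1", "A2", "B2"], mass, np.ones(4) / 4, ["g1", "g1", "g2", "g2"]
        )

    def test_within_composed_of_worked_example(self, two_practice_set):
        ps = self.two_identical_groups(two_practice_set)
        res = within_group_lottery(ps)
        np.testing.assert_allclose(res.per_group["L"], [0.01, 0.01], atol=1e-12)
        assert res.average == pytest.approx(0.01, abs=1e-12)

    def test_within_zero_for_homogeneous_group(self):
        scale = QualityScale("ordinal", ("a", "b"))
        mass = np.array([[0.3, 0.7], [0.3, 0.7], [0.1, 0.9], [0.6, 0.4]])
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g1", "g1", "g2", "g2"])
        res = within_group_lottery(ps)
        assert res.per_group.loc["g1", "L"] == pytest.approx(0.0, abs=1e-15)

    def test_permutation_invariance(self, rng):
        ps = random_provider_set(rng, K=9, Q=4, n_groups=3)
        perm = rng.permutation(ps.K)
        shuffled = ps.subset(perm)
        a, b = within_group_lottery(ps), within_group_lottery(shuffled)
        assert a.average == pytest.approx(b.average, abs=1e-12)
        for g in a.per_group.index:
            assert a.per_group.loc[g, "L"] == pytest.approx(b.per_group.loc[g, "L"], abs=1e-12)

    def test_singleton_group_excluded_with_warning(self, two_practice_set):
        scale = two_practice_set.scale
        mass = np.vstack([two_practice_set.mass, [[0.1, 0.2, 0.7]]])
        ps = ProviderSet(scale, ["A", "B", "C"], mass, np.ones(3) / 3, ["g1", "g1", "g2"])
        with pytest.warns(UserWarning, match="single provider"):
            res = within_group_lottery(ps)
        assert np.isnan(res.per_group.loc["g2", "L"])
        assert res.average == pytest.approx(0.01, abs=1e-12)

    def test_all_singletons_rejected(self, two_practice_set):
        ps = ProviderSet(
            two_practice_set.scale, ["A", "B"], two_practice_set.mass,
            two_practice_set.weights, ["g1", "g2"],
        )
        with pytest.raises(ValidationError):
            within_group_lottery(ps)

    def test_between_zero_when_aggregates_match(self):
        # different internal spreads, identical group aggregates
        scale = QualityScale("ordinal", ("a", "b", "c"))
        mass = np.array(
            [[1.0, 0.0, 0.0], [0.0, 0.0, 1.0],  # g1: extremes, mean (.5, 0, .5)
             [0.5, 0.0, 0.5], [0.5, 0.0, 0.5]]  # g2: identical, same mean
        )
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g1", "g1", "g2", "g2"])
        assert between_group_lottery(ps).L == pytest.approx(0.0, abs=1e-15)

    def test_between_worked_example_at_group_level(self, two_practice_set):
        scale = two_practice_set.scale
        # each group aggregates to one of the example profiles
        mass = np.vstack([two_practice_set.mass[0], two_practice_set.mass[0],
                          two_practice_set.mass[1], two_practice_set.mass[1]])
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4) / 4, ["gA", "gA", "gB", "gB"])
        assert between_group_lottery(ps).L == pytest.approx(0.01, abs=1e-12)

    def test_between_invariant_to_aggregate_preserving_reshuffle(self, rng):
        ps = random_provider_set(rng, K=12, Q=4, n_groups=3)
        base = between_group_lottery(ps).L
        # move mass between two providers of one group, preserving the
        # weighted group aggregate
        mass = ps.mass.copy()
        g0 = np.flatnonzero(ps.groups == ps.group_ids()[0])[:2]
        i, j = g0
        wi, wj = ps.weights[i], ps.weights[j]
        shift = 0.05 * np.array([1.0, -1.0, 0.0, 0.0])
        mass[i] = mass[i] + shift / wi * min(wi, wj) * 0.1
        mass[j] = mass[j] - shift / wj * min(wi, wj) * 0.1
        assert np.all(mass >= 0)
        ps2 = ProviderSet(ps.scale, ps.ids, mass / mass.sum(axis=1, keepdims=True),
                          ps.weights, ps.groups)
        # aggregate must be unchanged for the invariance to apply
        from ordqual.profiles import aggregate_to_groups as agg

        np.testing.assert_allclose(agg(ps2).mass, agg(ps).mass, atol=1e-12)
        assert between_group_lottery(ps2).L == pytest.approx(base, abs=1e-12)

    def test_single_group_rejected(self, two_practice_set):
        with pytest.raises(DegenerateWeightsError):
            between_group_lottery(two_practice_set)


class TestVarianceDecomposition:
    def test_between_only(self):
        scale = QualityScale("ordinal", ("a", "b"))
        mass = np.array([[0.8, 0.2], [0.8, 0.2], [0.2, 0.8], [0.2, 0.8]])
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g1", "g1", "g2", "g2"])
        shares = variance_decomposition(comparative_indices(ps), ps)
        assert shares.defined
        assert shares.between_share == pytest.approx(1.0, abs=1e-12)
        assert shares.within_share == pytest.approx(0.0, abs=1e-12)

    def test_within_only(self):
        scale = QualityScale("ordinal", ("a", "b"))
        # group means of delta both zero, spread inside each group
        mass = np.array([[0.8, 0.2], [0.2, 0.8], [0.8, 0.2], [0.2, 0.8]])
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g1", "g1", "g2", "g2"])
        shares = variance_decomposition(comparative_indices(ps), ps)
        assert shares.between_share == pytest.approx(0.0, abs=1e-12)
        assert shares.within_share == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        scale = QualityScale("ordinal", ("a", "b"))
        mass = np.tile([0.4, 0.6], (4, 1))
        ps = ProviderSet(scale, list("wxyz"), mass, np.ones(4), ["g1", "g1", "g2", "g2"])
        shares = variance_decomposition(comparative_indices(ps), ps)
        assert not shares.defined
        assert np.isnan(shares.within_share) and np.isnan(shares.between_share)

    def test_shares_sum_to_one_and_match_two_pass_oracle(self, rng):
        ps = random_provider_set(rng, K=12, Q=5, n_groups=4)
        ix = comparative_indices(ps)
        shares = variance_decomposition(ix, ps)
        assert shares.within_share + shares.between_share == pytest.approx(1.0, abs=1e-12)
        d = np.array([i.delta_k for i in ix])
        w = ps.weights
        mean = w @ d
        total = w @ (d - mean) ** 2
        within = 0.0
        for g in ps.group_ids():
            m = np.flatnonzero(ps.groups == g)
            gm = w[m] @ d[m] / w[m].sum()
            within += w[m] @ (d[m] - gm) ** 2
        assert shares.within_share == pytest.approx(within / total, abs=1e-12)


class TestRankAgreement:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert rank_agreement(x, x).tau_a == pytest.approx(1.0)
        assert rank_agreement(x, x[::-1]).tau_a == pytest.approx(-1.0)

    def test_one_adjacent_swap_enumeration(self):
        """n = 4 with one swapped adjacent pair: 5 concordant, 1 discordant."""
        tau = rank_agreement([1, 2, 3, 4], [2, 1, 3, 4]).tau_a
        assert tau == pytest.approx((5 - 1) / 6)

    def test_all_tied_is_zero(self):
        assert rank_agreement([1.0] * 5, [1, 2, 3, 4, 5]).tau_a == 0.0

    def test_matches_scipy_on_tie_free_data(self, rng):
        # without ties tau-a coincides with scipy's tau-b
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = rank_agreement(x, y)
        expect = stats.kendalltau(x, y).statistic
        assert res.tau_a == pytest.approx(expect, abs=1e-12)
        assert res.ci_low < res.tau_a < res.ci_high

    def test_ci_covers_truth_reasonably(self, rng):
        # sanity: with independent data the CI straddles zero most of the time
        hits = 0
        for _ in range(50):
            x, y = rng.normal(size=30), rng.normal(size=30)
            r = rank_agreement(x, y)
            hits += r.ci_low <= 0.0 <= r.ci_high
        assert hits >= 40

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rank_agreement([1, 2], [1, 2, 3])


class TestScaleInvariance:
    """All indices depend only on the category ordering, never on labels or
    any numeric scoring — the core robustness claim of the framework."""

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_indices_invariant_under_monotone_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        mass = rng.dirichlet(np.ones(5), size=6)
        w = rng.uniform(0.2, 2.0, size=6)
        ids = [f"p{i}" for i in range(6)]
        groups = [f"g{i % 2}" for i in range(6)]
        ps = ProviderSet(QualityScale("ordinal", tuple("abcde")), ids, mass, w, groups)
        # strictly increasing relabeling: new labels, same order
        relabeled = ProviderSet(
            QualityScale("cardinal-discretized", (1.0, 2.5, 7.0, 7.5, 100.0)),
            ids, mass, w, groups,
        )
        assert lottery_index(relabeled).L == lottery_index(ps).L
        a = [i.delta_k for i in comparative_indices(ps)]
        b = [i.delta_k for i in comparative_indices(relabeled)]
        assert a == b
        assert between_group_lottery(relabeled).L == between_group_lottery(ps).L

    def test_mean_scores_equal_but_delta_nonzero(self, two_practice_set):
        """Equally spaced scores 1, 2, 3 give both example practices mean 2.1,
        yet the pairwise difference still separates them."""
        scores = np.array([1.0, 2.0, 3.0])
        means = two_practice_set.mass @ scores
        np.testing.assert_allclose(means, [2.1, 2.1], atol=1e-12)
        cmp = pairwise_comparison(
            two_practice_set.profile("B"), two_practice_set.profile("A")
        )
        assert cmp.delta == pytest.approx(0.01, abs=1e-12)
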