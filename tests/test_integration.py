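import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate as sci_integrate
from scipy.stats import norm

from mirank.features import FeatureTable
from mirank.integration import (
    integrate,
    integrate_average_ratio,
    integrate_inverse_normal,
    q_statistic,
    ranking_ratio,
)


def joint_cdf_oracle(r1, r2, r3):
    """P(U_(1)<=r1, U_(2)<=r2, U_(3)<=r3) for sorted bounds, by direct
    numerical integration of the order-statistic density 3! over the
    constrained simplex u1 < u2 < u3."""
    val, _ = sci_integrate.dblquad(
        lambda u2, u1: r3 - u2, 0.0, r1, lambda u1: u1, lambda u1: r2
    )
    return 6.0 * val


def random_table(rng, M):
    return FeatureTable(
        [f"mir-{i:03d}" for i in range(M)],
        rng.normal(size=M),
        rng.uniform(0, 1, size=M),
        rng.integers(0, 40, size=M),
    )


class TestRankingRatio:
    def test_strict_descending_order(self):
        np.testing.assert_allclose(ranking_ratio([10, 5, 1], "descending"), [1 / 3, 2 / 3, 1.0])

    def test_average_rank_ties(self):
        np.testing.assert_allclose(ranking_ratio([5, 5, 1], "descending"), [0.5, 0.5, 1.0])

    def test_directions_sum_to_identity_without_ties(self, rng):
        for M in (1, 2, 7, 40):
            v = rng.permutation(M).astype(float)  # tie-free
            total = ranking_ratio(v, "descending") + ranking_ratio(v, "ascending")
            np.testing.assert_allclose(total, (M + 1) / M)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ranking_ratio([], "descending")


class TestQStatistic:
    def test_certain_event(self):
        assert q_statistic([1.0, 1.0, 1.0]) == 1.0

    def test_equal_thresholds_collapse_to_power(self):
        assert q_statistic([0.5, 0.5, 0.5]) == pytest.approx(0.125, abs=1e-14)

    def test_inclusion_exclusion_value(self):
        # P = 1 - P(U_(1)>0.1) - P(U_(1)<=0.1, U_(2)>0.5) = 1 - 0.9^3 - 3*0.1*0.25
        assert q_statistic([0.1, 0.5, 1.0]) == pytest.approx(0.196, abs=1e-12)

    def test_zero_lower_bound_kills_probability(self):
        assert q_statistic([0.0, 0.4, 0.9]) == 0.0

    @pytest.mark.parametrize("n_ratios", [1, 2, 3])
    def test_matches_joint_cdf_integration_oracle(self, rng, n_ratios):
        for _ in range(20):
            r = np.sort(rng.uniform(0, 1, size=3))
            if n_ratios == 1:
                assert q_statistic([r[0]]) == pytest.approx(r[0], abs=1e-12)
            elif n_ratios == 2:
                expected = 2 * r[0] * r[1] - r[0] ** 2
                assert q_statistic(r[:2]) == pytest.approx(expected, abs=1e-12)
            else:
                assert q_statistic(r) == pytest.approx(joint_cdf_oracle(*r), abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_and_bounded(self, ratios, idx, bump):
        q0 = q_statistic(ratios)
        assert 0.0 <= q0 <= 1.0
        bumped = list(ratios)
        i = idx % len(bumped)
        bumped[i] = min(1.0, bumped[i] + bump)
        assert q_statistic(bumped) >= q0 - 1e-12


class TestIntegrate:
    def test_dominant_mirna_wins(self):
        ft = FeatureTable(["a", "b"], [2.0, 1.0], [0.9, 0.1], [10, 2])
        res = integrate(ft)
        i = ft.mirna_ids.index("a")
        assert res.rq1[i] == 1 and res.rq2[i] == 1 and res.rq[i] == 2
        assert res.final_rank[i] == 1

    def test_total_tie_resolved_deterministically(self):
        ft = FeatureTable(["c", "a", "b"], [1.0] * 3, [0.5] * 3, [4] * 3)
        res = integrate(ft)
        assert len(set(res.rq)) == 1
        # lexicographic id tie-break
        assert res.ranked_ids() == ["a", "b", "c"]

    def test_balanced_profile_beats_spiky_profile(self):
        # one miRNA is best on one feature but worst on the other two;
        # another is middling on all three; verified against the direct
        # joint-CDF oracle for both Q values
        M = 10
        rng = np.random.default_rng(7)
        a = np.arange(M, dtype=float)
        c = np.linspace(0.1, 0.9, M)
        t = np.arange(M) * 3
        # spiky: best a, worst c and t
        a[0], c[0], t[0] = 100.0, 0.01, 0
        # balanced: middling everywhere (index 5 keeps monotone profile)
        ft = FeatureTable([f"m{i}" for i in range(M)], a, c, t)
        res = integrate(ft)
        spiky, balanced = 0, 5
        assert res.final_rank[balanced] < res.final_rank[spiky]
        # cross-check each Q1 against independent numerical integration
        from mirank.integration import ranking_ratio as rr

        RD = np.column_stack(
            [rr(a, "descending"), rr(c, "descending"), rr(t.astype(float), "descending")]
        )
        for i in (spiky, balanced):
            r = np.sort(RD[i])
            assert res.q1[i] == pytest.approx(joint_cdf_oracle(*r), abs=1e-9)

    def test_permutation_equivariance(self, rng):
        ft = random_table(rng, 25)
        res = integrate(ft)
        perm = rng.permutation(25)
        ft2 = FeatureTable(
            [ft.mirna_ids[i] for i in perm], ft.a[perm], ft.c[perm], ft.t[perm]
        )
        res2 = integrate(ft2)
        np.testing.assert_allclose(res2.q1, res.q1[perm], atol=1e-14)
        np.testing.assert_array_equal(res2.final_rank, res.final_rank[perm])

    def test_invariants_on_random_instance(self, rng):
        res = integrate(random_table(rng, 30))
        assert ((res.q1 >= 0) & (res.q1 <= 1)).all()
        np.testing.assert_allclose(res.rq, res.rq1 + res.rq2)
        assert sorted(res.final_rank) == list(range(1, 31))

    def test_single_mirna_rejected(self):
        with pytest.raises(ValueError):
            integrate(FeatureTable(["a"], [1.0], [0.5], [1]))


class TestBaselineIntegrators:
    def test_equal_features_give_equal_scores(self):
        ft = FeatureTable(["a", "b", "c"], [1.0] * 3, [0.5] * 3, [4] * 3)
        scores = integrate_average_ratio(ft)
        assert scores.nunique() == 1

    def test_degenerate_weights_reduce_to_single_feature(self, rng):
        ft = random_table(rng, 15)
        scores = integrate_average_ratio(ft, (1.0, 0.0, 0.0))
        expected = ranking_ratio(ft.a, "descending")
        by_id = scores.reindex([f"mir-{i:03d}" for i in range(15)])
        np.testing.assert_allclose(by_id.to_numpy(), expected)

    def test_weighted_mean_matches_arithmetic_oracle(self, rng):
        ft = random_table(rng, 12)
        w = (0.2, 1.0, 0.5)
        scores = integrate_average_ratio(ft, w)
        RD = np.column_stack(
            [
                ranking_ratio(ft.a, "descending"),
                ranking_ratio(ft.c, "descending"),
                ranking_ratio(ft.t.astype(float), "descending"),
            ]
        )
        expected = (RD * w).sum(axis=1) / sum(w)
        by_id = scores.reindex(ft.mirna_ids)
        np.testing.assert_allclose(by_id.to_numpy(), expected, atol=1e-14)

    def test_inverse_normal_median_rank_maps_to_zero(self):
        M = 9
        ft = FeatureTable(
            [f"m{i}" for i in range(M)],
            np.arange(M, dtype=float),
            np.linspace(0.1, 0.9, M),
            np.arange(M),
        )
        scores = integrate_inverse_normal(ft)
        # middle miRNA has median rank on every feature -> mean z == 0
        assert scores.loc["m4"] == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_symmetric_ranks_give_symmetric_z(self):
        M = 9
        ft = FeatureTable(
            [f"m{i}" for i in range(M)],
            np.arange(M, dtype=float),
            np.linspace(0.1, 0.9, M),
            np.arange(M),
        )
        scores = integrate_inverse_normal(ft)
        for i in range(M):
            assert scores.loc[f"m{i}"] == pytest.approx(-scores.loc[f"m{M-1-i}"], abs=1e-12)

    def test_inverse_normal_matches_quantile_table(self):
        # ranks 1..4 on all features -> z = Phi^-1(1 - (rank-0.5)/4)
        M = 4
        ft = FeatureTable(
            [f"m{i}" for i in range(M)],
            np.array([4.0, 3.0, 2.0, 1.0]),
            np.array([0.8, 0.6, 0.4, 0.2]),
            np.array([9, 7, 5, 3]),
        )
        scores = integrate_inverse_normal(ft)
        for i in range(M):
            expected = norm.ppf(1 - (i + 0.5) / M)
            assert scores.loc[f"m{i}"] == pytest.approx(expected, abs=1e-12)
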