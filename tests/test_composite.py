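import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radrobust.clustering import Partition
from radrobust.composite import (
    FeatureRobustnessRecord,
    SelectionResult,
    aggregate_winner_frequencies,
    composite_index,
    ks_statistic,
    mean_fractional_ratio,
    qc_filter,
    robust_z,
    select_winners,
)
from radrobust.io import AlignedPair, FeatureTable

from .oracles import ks_ecdf_sweep

# frozen via the exhaustive ECDF sweep oracle
KS_1234_2345 = 0.25
# frozen by hand: med=3, MAD=1 -> z = 97 / 1.4826
Z_OUTLIER = 97 / 1.4826


class TestKsStatistic:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(20)
        assert ks_statistic(a, a) == pytest.approx(0.0)

    def test_disjoint_supports(self):
        assert ks_statistic([1, 2, 3], [10, 11, 12]) == pytest.approx(1.0)

    def test_frozen_oracle_value(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        assert ks_statistic(a, b) == pytest.approx(KS_1234_2345)
        assert ks_ecdf_sweep(a, b) == pytest.approx(KS_1234_2345)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(20):
            a = rng.standard_normal(int(rng.integers(5, 30)))
            b = rng.standard_normal(int(rng.integers(5, 30))) + 0.5
            assert ks_statistic(a, b) == pytest.approx(
                ks_ecdf_sweep(a, b), abs=1e-12
            )

    def test_empty_vector(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1, 2])


class TestMeanFractionalRatio:
    def test_equal_means(self):
        mfr, sign = mean_fractional_ratio([1, 2, 3], [3, 2, 1])
        assert mfr == pytest.approx(0.0)
        assert sign == 0

    def test_factor_two_epsilon_zero(self):
        mfr, sign = mean_fractional_ratio([2.0, 2.0], [1.0, 1.0], epsilon=0.0)
        assert mfr == pytest.approx(np.log(2.0))
        assert sign == 1

    def test_identical_vectors_any_epsilon(self, rng):
        a = rng.standard_normal(10)
        for eps in (0.0, 1e-6, 1.0):
            mfr, _ = mean_fractional_ratio(a, a, epsilon=eps)
            assert mfr == pytest.approx(0.0)

    def test_direction_sign(self):
        _, s_up = mean_fractional_ratio([10.0], [1.0])
        _, s_down = mean_fractional_ratio([1.0], [10.0])
        assert (s_up, s_down) == (1, -1)

    def test_near_zero_means_stabilized(self):
        mfr, _ = mean_fractional_ratio([1e-12, -1e-12], [5.0, -5.0])
        assert np.isfinite(mfr)


class TestRobustZ:
    def test_median_maps_to_zero(self):
        z = robust_z([1.0, 2.0, 3.0, 4.0, 5.0])
        assert z[2] == pytest.approx(0.0)

    def test_constant_all_zeros(self):
        np.testing.assert_array_equal(robust_z([4.0] * 6), np.zeros(6))

    def test_outlier_frozen_value(self):
        z = robust_z([1.0, 2.0, 3.0, 4.0, 100.0])
        assert z[-1] == pytest.approx(Z_OUTLIER, rel=1e-12)

    def test_mad_zero_iqr_fallback(self):
        # median 1, MAD 0 (majority at 1), IQR > 0
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        z = robust_z(x)
        assert np.isfinite(z).all()
        assert z.max() > 0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_always_finite(self, xs):
        z = robust_z(np.array(xs))
        assert np.all(np.isfinite(z))


def make_pair(A, B, names=None):
    n, p = A.shape
    names = names or [f"original_firstorder_sim{i:03d}" for i in range(p)]
    lesions = [f"L{i}" for i in range(n)]
    ta = FeatureTable("A", lesions, list(names), A)
    tb = FeatureTable("B", lesions, list(names), B)
    return AlignedPair(ta, tb, list(names))


class TestCompositeIndex:
    def test_exact_copy_degenerate_all_zero_ci(self, rng):
        A = rng.standard_normal((30, 5))
        records = composite_index(make_pair(A, A.copy()))
        for rec in records:
            assert rec.r == pytest.approx(1.0)
            assert rec.ks == pytest.approx(0.0)
            assert rec.mfr == pytest.approx(0.0)
            assert rec.ci == pytest.approx(0.0)  # robust z of constants

    def test_single_high_fidelity_feature_wins(self, rng):
        n, p = 60, 10
        A = rng.standard_normal((n, p)) + 2.0
        B = A.copy()
        B[:, 1:] = 5.0 * A[:, 1:] ** 3 + rng.standard_normal((n, p - 1)) * 3.0
        B[:, 0] = A[:, 0] + 0.02 * rng.standard_normal(n)
        records = composite_index(make_pair(A, B))
        best = max(records, key=lambda r: r.ci)
        assert best.feature_name == records[0].feature_name
        assert records[0].ci > max(r.ci for r in records[1:])

    def test_common_rescale_leaves_ci_unchanged(self, rng):
        A = rng.standard_normal((40, 6)) + 1.0
        B = A + 0.1 * rng.standard_normal((40, 6))
        # epsilon=0: the stabilizer is the only thing breaking exact
        # invariance of MFR under a common positive rescale
        r1 = composite_index(make_pair(A, B), epsilon=0.0)
        A2, B2 = A.copy(), B.copy()
        A2[:, 2] *= 10.0
        B2[:, 2] *= 10.0
        r2 = composite_index(make_pair(A2, B2), epsilon=0.0)
        for a, b in zip(r1, r2):
            assert a.ci == pytest.approx(b.ci, abs=1e-9)

    def test_ci_identity_holds(self, rng):
        A = rng.standard_normal((30, 8))
        B = A + rng.standard_normal((30, 8)) * 0.3
        for rec in composite_index(make_pair(A, B)):
            assert rec.ci == pytest.approx(rec.z_corr - rec.z_ks - rec.z_mfr)
            assert -1.0 <= rec.r <= 1.0
            assert 0.0 <= rec.ks <= 1.0
            assert rec.mfr >= 0.0

    def test_too_few_features(self, rng):
        A = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match=">=3 features"):
            composite_index(make_pair(A, A))


def rec(name, ci, r=0.95):
    return FeatureRobustnessRecord(name, r, 0.1, 0.1, 0, 0.0, 0.0, 0.0, ci)


def two_cluster_partition():
    names = ["fa", "fb", "fc", "fd", "fe", "ff"]
    return Partition("pearson", "average", 2, names,
                     np.array([1, 1, 1, 2, 2, 2]))


class TestSelectWinners:
    def test_winner_and_near_winner(self):
        part = Partition("pearson", "average", 1, ["fa", "fb", "fc"],
                         np.array([1, 1, 1]))
        records = [rec("fa", 2.0), rec("fb", 1.9), rec("fc", 0.2)]
        sel = select_winners(part, records, delta=0.3)
        assert sel.winners[1] == "fa"
        assert sel.near_winners[1] == ["fb"]

    def test_exact_tie_lexicographic_co_winners(self):
        part = Partition("pearson", "average", 1, ["fz", "fa"],
                         np.array([1, 1]))
        records = [rec("fz", 1.5), rec("fa", 1.5)]
        sel = select_winners(part, records)
        assert sel.winners[1] == "fa"
        assert sel.co_winners[1] == ["fa", "fz"]

    def test_unscored_cluster_skipped(self):
        part = two_cluster_partition()
        records = [rec("fa", 1.0), rec("fb", 0.5), rec("fc", 0.2)]
        sel = select_winners(part, records)
        assert sel.winners == {1: "fa"}
        assert sel.skipped_clusters == [2]

    def test_winner_count_equals_k(self):
        part = two_cluster_partition()
        records = [rec(n, i * 0.1) for i, n in enumerate(part.feature_names)]
        sel = select_winners(part, records)
        assert len(sel.winners) == part.k


class TestQcFilter:
    def _setup(self, rng, records):
        part = two_cluster_partition()
        X = rng.standard_normal((40, 6))
        return part, X

    def test_low_correlation_dropped_with_reason(self, rng):
        part, X = self._setup(rng, None)
        records = [rec("fa", 2.0, r=0.3), rec("fb", 1.0), rec("fc", 0.5),
                   rec("fd", 1.5), rec("fe", 0.1), rec("ff", 0.0)]
        sel = select_winners(part, records, delta=1.5)
        final = qc_filter(sel, records, part, X, part.feature_names,
                          min_corr=0.5)
        assert "fa" not in final
        assert "correlation" in sel.qc_reasons["fa"]

    def test_redundant_pair_keeps_higher_ci(self, rng):
        part, X = self._setup(rng, None)
        X[:, 1] = X[:, 0] * 1.0001 + 1e-6 * rng.standard_normal(40)  # fa~fb
        records = [rec("fa", 2.0), rec("fb", 1.9), rec("fc", 0.5),
                   rec("fd", 1.5), rec("fe", 0.1), rec("ff", 0.0)]
        sel = select_winners(part, records, delta=0.3)
        final = qc_filter(sel, records, part, X, part.feature_names,
                          redundancy_cutoff=0.9)
        assert "fa" in final and "fb" not in final
        assert sel.qc_reasons["fb"] == "redundant with fa"

    def test_final_set_pairwise_correlation_bounded(self, rng):
        from scipy import stats

        part, X = self._setup(rng, None)
        # plant heavy redundancy inside cluster 1
        X[:, 1] = X[:, 0] + 0.01 * rng.standard_normal(40)
        X[:, 2] = X[:, 0] + 0.01 * rng.standard_normal(40)
        records = [rec(n, 2.0 - 0.1 * i)
                   for i, n in enumerate(part.feature_names)]
        sel = select_winners(part, records, delta=5.0)
        final = qc_filter(sel, records, part, X, part.feature_names,
                          redundancy_cutoff=0.9)
        label = part.label_of()
        col = {f: j for j, f in enumerate(part.feature_names)}
        for i, f in enumerate(final):
            for g in final[i + 1:]:
                if label[f] == label[g]:
                    c = abs(stats.pearsonr(X[:, col[f]], X[:, col[g]]).statistic)
                    assert c <= 0.9


class TestAggregateWinnerFrequencies:
    @staticmethod
    def _solution(winners, near=None):
        sel = SelectionResult(winners=dict(enumerate(winners, start=1)))
        sel.near_winners = {1: list(near or [])}
        return sel

    def test_three_solutions_one_feature(self):
        sols = [self._solution(["fx"]) for _ in range(3)]
        rows = aggregate_winner_frequencies(sols)
        assert rows[0] == {"feature": "fx", "winner_count": 3,
                           "winner_or_near_count": 3}

    def test_winner_and_near_counts(self):
        sols = [self._solution(["fx"]), self._solution(["fx"]),
                self._solution(["fy"], near=["fx"])]
        rows = {r["feature"]: r for r in aggregate_winner_frequencies(sols)}
        assert rows["fx"]["winner_count"] == 2
        assert rows["fx"]["winner_or_near_count"] == 3

    def test_sorted_descending(self):
        sols = [self._solution(["fa", "fb"]), self._solution(["fb"])]
        rows = aggregate_winner_frequencies(sols)
        assert rows[0]["feature"] == "fb"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            aggregate_winner_frequencies([])
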