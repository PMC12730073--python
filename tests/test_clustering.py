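import numpy as np
import pytest

from radrobust.clustering import (
    LINKAGES,
    Partition,
    cut_merges,
    hierarchical_cluster,
    internal_indices,
    linkage_matrix,
    select_k_consensus,
)
from radrobust.distances import DistanceMatrix, correlation_distance

from .conftest import make_block_distance
from .oracles import merge_sets_from_scipy, naive_agglomerate


def dm(d, metric="pearson"):
    names = [f"f{i}" for i in range(d.shape[0])]
    return DistanceMatrix(metric, names, d)


class TestHierarchicalCluster:
    @pytest.mark.parametrize("linkage", sorted(LINKAGES))
    def test_separated_blocks_recovered_by_every_linkage(self, linkage):
        d = dm(make_block_distance([4, 3]))
        part = hierarchical_cluster(d, linkage, 2)
        assert part.as_sets() == {
            frozenset(d.feature_names[:4]),
            frozenset(d.feature_names[4:]),
        }

    def test_single_linkage_chaining(self):
        # chain f0..f4 at consecutive distance 1, far outlier f5
        n = 6
        d = np.full((n, n), 10.0)
        for i in range(4):
            d[i, i + 1] = d[i + 1, i] = 1.0
        # transitively closer within the chain than to the outlier
        for i in range(5):
            for j in range(5):
                d[i, j] = min(d[i, j], abs(i - j) * 1.0)
        np.fill_diagonal(d, 0.0)
        part = hierarchical_cluster(dm(d), "single", 2)
        assert part.as_sets() == {
            frozenset([f"f{i}" for i in range(5)]), frozenset(["f5"]),
        }

    @pytest.mark.parametrize("linkage", sorted(LINKAGES))
    def test_merge_sequence_matches_naive_oracle(self, rng, linkage):
        for _ in range(5):
            n = int(rng.integers(6, 10))
            # Euclidean-embeddable distances keep ward/centroid well-posed
            pts = rng.standard_normal((n, 3))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            Z = linkage_matrix(dm(d), linkage)
            got = merge_sets_from_scipy(Z)
            expected = naive_agglomerate(d, linkage)
            for (gi, gj, gh), (ei, ej, eh) in zip(got, expected):
                assert {gi, gj} == {ei, ej}
                assert gh == pytest.approx(eh, abs=1e-9)

    def test_deterministic(self, rng):
        raw = rng.uniform(0.1, 2.0, size=(8, 8))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0)
        d = dm(sym)
        p1 = hierarchical_cluster(d, "average", 3)
        p2 = hierarchical_cluster(d, "average", 3)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_input_order_invariance(self, rng):
        base = rng.standard_normal((9, 4))
        d1 = np.sqrt(((base[:, None] - base[None]) ** 2).sum(-1))
        perm = rng.permutation(9)
        names = [f"f{i}" for i in range(9)]
        m1 = DistanceMatrix("euclidean", names, d1)
        m2 = DistanceMatrix("euclidean", [names[i] for i in perm],
                            d1[np.ix_(perm, perm)])
        p1 = hierarchical_cluster(m1, "complete", 3)
        p2 = hierarchical_cluster(m2, "complete", 3)
        assert p1.as_sets() == p2.as_sets()

    def test_nested_cuts(self, rng):
        pts = rng.standard_normal((10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        Z = linkage_matrix(dm(d), "average")
        for k in range(3, 10):
            fine = cut_merges(Z, k)
            coarse = cut_merges(Z, k - 1)
            # each coarse cluster is a union of fine clusters, and exactly
            # two fine clusters share a coarse id
            mapping = {}
            for f, c in zip(fine, coarse):
                mapping.setdefault(f, set()).add(c)
            assert all(len(v) == 1 for v in mapping.values())
            merged = [c for c in set(coarse)
                      if sum(next(iter(v)) == c for v in mapping.values()) > 1]
            assert len(merged) == 1

    def test_k_out_of_range(self):
        d = dm(make_block_distance([3, 3]))
        with pytest.raises(ValueError, match="out of range"):
            hierarchical_cluster(d, "average", 6)
        with pytest.raises(ValueError, match="out of range"):
            hierarchical_cluster(d, "average", 1)

    def test_unknown_linkage(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            linkage_matrix(dm(make_block_distance([3, 3])), "median")


class TestInternalIndices:
    def test_separated_blocks_high_scores(self):
        d = dm(make_block_distance([5, 5], within=0.1, between=2.0))
        part = hierarchical_cluster(d, "average", 2)
        idx = internal_indices(part, d)
        assert idx["silhouette"] > 0.9
        assert idx["dunn"] > 1.0

    def test_uniform_distances_near_zero_silhouette(self):
        n = 8
        d_mat = np.ones((n, n))
        np.fill_diagonal(d_mat, 0.0)
        d = dm(d_mat)
        labels = np.array([1] * (n - 1) + [2])
        part = Partition("pearson", "single", 2, d.feature_names, labels)
        idx = internal_indices(part, d)
        assert idx["silhouette"] == pytest.approx(0.0, abs=1e-12)

    def test_silhouette_bounds(self, rng):
        for _ in range(10):
            pts = rng.standard_normal((8, 2))
            d_mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            d = dm(d_mat)
            k = int(rng.integers(2, 7))
            part = hierarchical_cluster(d, "average", k)
            s = internal_indices(part, d)["silhouette"]
            assert -1.0 <= s <= 1.0

    def test_silhouette_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score

        pts = rng.standard_normal((12, 3))
        d_mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = dm(d_mat)
        part = hierarchical_cluster(d, "complete", 3)
        ours = internal_indices(part, d)["silhouette"]
        theirs = silhouette_score(d_mat, part.labels, metric="precomputed")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_ch_needs_feature_vectors(self, rng):
        d = dm(make_block_distance([4, 4]))
        part = hierarchical_cluster(d, "average", 2)
        no_x = internal_indices(part, d)
        assert np.isnan(no_x["calinski_harabasz"])
        X = rng.standard_normal((10, 8))
        with_x = internal_indices(part, d, X=X)
        assert np.isfinite(with_x["calinski_harabasz"])
        assert with_x["calinski_harabasz"] >= 0


class TestSelectKConsensus:
    def test_three_blocks_full_support(self):
        d = dm(make_block_distance([5, 5, 5]))
        report = select_k_consensus(d, "average", indices=("silhouette", "dunn"))
        assert report.consensus_k == 3
        assert report.support == 1.0

    def test_two_blocks(self):
        d = dm(make_block_distance([6, 4]))
        report = select_k_consensus(d, "complete", indices=("silhouette", "dunn"))
        assert report.consensus_k == 2

    def test_correlated_block_features(self, rng):
        # three latent blocks of correlated features -> consensus 3
        latent = rng.standard_normal((120, 3))
        X = np.repeat(latent, 5, axis=1) + 0.2 * rng.standard_normal((120, 15))
        d = correlation_distance(X, [f"f{i}" for i in range(15)])
        report = select_k_consensus(d, "average", X=X)
        assert report.consensus_k == 3

    def test_early_stop_triggers(self, rng):
        # unstructured distances: votes scatter, support collapses
        pts = rng.standard_normal((20, 10))
        d_mat = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        report = select_k_consensus(
            dm(d_mat), "average", k_range=(2, 19),
            early_stop=(1.01, 2),  # impossible support -> must stop early
        )
        assert report.stopped_early_at is not None
        assert report.k_scanned[-1] == report.stopped_early_at

    def test_k_range_respected(self):
        d = dm(make_block_distance([5, 5, 5]))
        report = select_k_consensus(d, "average", k_range=(4, 8))
        assert all(k >= 4 for k in report.k_scanned)

    def test_report_votes_within_range(self):
        d = dm(make_block_distance([4, 4, 4]))
        report = select_k_consensus(d, "ward.D2")
        for k in report.votes.values():
            assert min(report.k_scanned) <= k <= max(report.k_scanned)
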