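"""Agglomerative clustering of features with consensus selection of k.

Dendrograms are built by scipy's linkage routines on a precomputed
dissimilarity matrix.  Cutting into k clusters applies the first
``n - k`` merges of the linkage matrix, which always yields exactly k
non-empty clusters (and remains well defined for centroid linkage, whose
dendrogram may contain inversions).  Cluster ids are 1..k, numbered by each
cluster's smallest member index, which makes partitions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.metrics import calinski_harabasz_score

from radrobust.distances import DistanceMatrix

__all__ = [
    "LINKAGES",
    "EUCLIDEAN_SAFE_METRICS",
    "Partition",
    "KSelectionReport",
    "linkage_matrix",
    "cut_merges",
    "hierarchical_cluster",
    "internal_indices",
    "select_k_consensus",
]

#: public linkage name -> scipy method
LINKAGES = {
    "ward.D2": "ward",
    "average": "average",
    "complete": "complete",
    "single": "single",
    "centroid": "centroid",
}

#: metrics whose matrices embed in Euclidean space, safe for ward.D2/centroid
EUCLIDEAN_SAFE_METRICS = ("pearson", "spearman", "euclidean")

DEFAULT_INDICES = ("silhouette", "dunn", "calinski_harabasz")


@dataclass
class Partition:
    """Assignment of features to clusters for one (metric, linkage, k) config."""

    metric: str
    linkage: str
    k: int
    feature_names: list[str]
    labels: np.ndarray  # cluster ids 1..k, aligned with feature_names

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.feature_names),):
            raise ValueError("labels length mismatch")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError(
                f"expected cluster ids 1..{self.k}, got {present.tolist()}"
            )

    def label_of(self) -> dict[str, int]:
        return dict(zip(self.feature_names, self.labels.tolist()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for name, lab in zip(self.feature_names, self.labels):
            out[int(lab)].append(name)
        return out

    def as_sets(self) -> set[frozenset]:
        return {frozenset(v) for v in self.clusters().values()}


@dataclass
class KSelectionReport:
    """Outcome of consensus k selection from internal validity indices."""

    votes: dict[str, int]                    # index name -> voted k
    scores: dict[str, dict[int, float]]      # index name -> {k: score}
    consensus_k: int
    support: float                           # fraction of indices voting consensus_k
    stopped_early_at: int | None = None
    k_scanned: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "votes": dict(self.votes),
            "scores": {i: {str(k): v for k, v in s.items()}
                       for i, s in self.scores.items()},
            "consensus_k": self.consensus_k,
            "support": self.support,
            "stopped_early_at": self.stopped_early_at,
            "k_scanned": list(self.k_scanned),
        }


def linkage_matrix(d: DistanceMatrix, linkage: str) -> np.ndarray:
    """scipy linkage matrix for a distance matrix under the named rule.

    ward.D2 and centroid assume Euclidean-embeddable dissimilarities; the
    correlation distance sqrt(2 (1 - r)) is an equivalent Euclidean distance,
    but cosine/manhattan inputs only satisfy this approximately, so callers
    should consult :data:`EUCLIDEAN_SAFE_METRICS`.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(LINKAGES)}")
    if d.n_features < 2:
        raise ValueError("need >=2 features to cluster")
    return scipy_linkage(d.condensed(), method=LINKAGES[linkage])


def cut_merges(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage matrix into exactly k clusters by applying n-k merges.

    Labels are 1..k ordered by each cluster's smallest original index.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        i, j = int(Z[step, 0]), int(Z[step, 1])
        members[n + step] = members.pop(i) + members.pop(j)
    groups = sorted(members.values(), key=min)
    labels = np.empty(n, dtype=int)
    for cid, group in enumerate(groups, start=1):
        labels[group] = cid
    return labels


def hierarchical_cluster(d: DistanceMatrix, linkage: str, k: int) -> Partition:
    """Cluster features into k groups; deterministic given the distance matrix."""
    if not 2 <= k <= d.n_features - 1:
        raise ValueError(f"k={k} out of range [2, {d.n_features - 1}]")
    Z = linkage_matrix(d, linkage)
    labels = cut_merges(Z, k)
    return Partition(d.metric, linkage, k, list(d.feature_names), labels)


def _silhouette(labels: np.ndarray, d: np.ndarray) -> float:
    """Mean silhouette from a precomputed matrix; singletons score 0."""
    n = len(labels)
    scores = np.zeros(n)
    clusters = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            continue  # singleton convention: 0
        a = d[i, own[own != i]].mean()
        b = min(
            d[i, idx].mean() for c, idx in clusters.items() if c != labels[i]
        )
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())


def _dunn(labels: np.ndarray, d: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    diameters = [d[np.ix_(idx, idx)].max() for idx in clusters]
    max_diam = max(diameters)
    min_inter = min(
        d[np.ix_(ci, cj)].min()
        for a, ci in enumerate(clusters)
        for cj in clusters[a + 1:]
    )
    if max_diam == 0:
        return float("inf") if min_inter > 0 else 0.0
    return float(min_inter / max_diam)


def internal_indices(
    partition: Partition,
    d: DistanceMatrix,
    X: np.ndarray | None = None,
) -> dict[str, float]:
    """Silhouette, Dunn and (when feature vectors are given) Calinski-Harabasz.

    ``X`` is the lesions x features matrix matching ``d.feature_names``;
    Calinski-Harabasz is evaluated on the z-scored feature vectors (features
    as points) and reported as NaN when ``X`` is absent or k pins every
    feature to its own cluster.
    """
    if partition.feature_names != d.feature_names:
        raise ValueError("partition and distance matrix disagree on features")
    labels = partition.labels
    out = {
        "silhouette": _silhouette(labels, d.d),
        "dunn": _dunn(labels, d.d),
        "calinski_harabasz": float("nan"),
    }
    if X is not None and 1 < partition.k < len(labels):
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        Xz = (X - X.mean(axis=0)) / std
        out["calinski_harabasz"] = float(
            calinski_harabasz_score(Xz.T, labels)
        )
    return out


def select_k_consensus(
    d: DistanceMatrix,
    linkage: str,
    k_range: tuple[int, int] = (2, 10),
    indices: tuple[str, ...] = DEFAULT_INDICES,
    early_stop: tuple[float, int] = (0.5, 3),
    X: np.ndarray | None = None,
) -> KSelectionReport:
    """Majority-rule consensus k over a scanned range of internal indices.

    Each index votes for its best-scoring k seen so far (all three indices
    are better-is-higher).  After each k the modal vote's support is checked;
    ``patience`` consecutive k values with support below ``threshold`` halt
    the scan early.  Consensus ties break toward smaller k (parsimony).
    """
    threshold, patience = early_stop
    kmin, kmax = k_range
    kmin = max(2, kmin)
    kmax = min(kmax, d.n_features - 1)
    if kmin > kmax:
        raise ValueError(f"empty k range [{kmin}, {kmax}]")
    Z = linkage_matrix(d, linkage)

    scores: dict[str, dict[int, float]] = {i: {} for i in indices}
    best: dict[str, tuple[float, int]] = {}
    stopped_early_at = None
    scanned: list[int] = []
    below = 0
    for k in range(kmin, kmax + 1):
        labels = cut_merges(Z, k)
        part = Partition(d.metric, linkage, k, list(d.feature_names), labels)
        vals = internal_indices(part, d, X=X)
        scanned.append(k)
        for idx in indices:
            v = vals.get(idx, float("nan"))
            scores[idx][k] = v
            if np.isfinite(v) and (idx not in best or v > best[idx][0]):
                best[idx] = (v, k)
        if not best:
            continue
        votes_now = [bk for _, bk in best.values()]
        support_now = max(votes_now.count(v) for v in set(votes_now)) / len(indices)
        if support_now < threshold:
            below += 1
            if below >= patience:
                stopped_early_at = k
                break
        else:
            below = 0

    if not best:
        raise ValueError("all internal indices undefined over the scanned range")
    votes = {idx: bk for idx, (_, bk) in best.items()}
    counts: dict[int, int] = {}
    for bk in votes.values():
        counts[bk] = counts.get(bk, 0) + 1
    top = max(counts.values())
    consensus_k = min(k for k, c in counts.items() if c == top)
    return KSelectionReport(
        votes=votes,
        scores=scores,
        consensus_k=consensus_k,
        support=top / len(indices),
        stopped_early_at=stopped_early_at,
        k_scanned=scanned,
    )
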