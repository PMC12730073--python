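"""Cross-platform partition stability via the Adjusted Rand Index.

Every (distance metric, linkage) configuration clusters the two platform
tables independently; the Hubert-Arabie chance-corrected Rand index between
the two partitions gates "stable" configurations at a threshold (default
0.8).  Degenerate partitions (one giant cluster plus singletons) can score a
perfect silhouette while carrying no structure, so they are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from radrobust.clustering import (
    EUCLIDEAN_SAFE_METRICS,
    Partition,
    cut_merges,
    internal_indices,
    linkage_matrix,
    select_k_consensus,
)
from radrobust.distances import ALL_METRICS, feature_distance
from radrobust.io import AlignedPair

__all__ = [
    "StabilityRecord",
    "DEFAULT_ARI_THRESHOLD",
    "ari_from_labels",
    "adjusted_rand_index",
    "is_degenerate",
    "evaluate_grid",
    "select_stable_configs",
]

DEFAULT_ARI_THRESHOLD = 0.8


@dataclass
class StabilityRecord:
    """One cell of the metric x linkage stability grid."""

    metric: str
    linkage: str
    k_a: int | None = None
    k_b: int | None = None
    ari: float = float("nan")
    silhouette_a: float = float("nan")
    silhouette_b: float = float("nan")
    dunn_a: float = float("nan")
    dunn_b: float = float("nan")
    stable: bool = False
    degenerate_a: bool = False
    degenerate_b: bool = False
    euclidean_warning: bool = False
    error: str | None = None
    partition_a: Partition | None = field(default=None, repr=False)
    partition_b: Partition | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "linkage": self.linkage,
            "k_a": self.k_a,
            "k_b": self.k_b,
            "ari": self.ari,
            "silhouette_a": self.silhouette_a,
            "silhouette_b": self.silhouette_b,
            "dunn_a": self.dunn_a,
            "dunn_b": self.dunn_b,
            "stable": self.stable,
            "degenerate_a": self.degenerate_a,
            "degenerate_b": self.degenerate_b,
            "euclidean_warning": self.euclidean_warning,
            "error": self.error or "",
        }


def ari_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index from two label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and equally long")
    n = len(a)
    if n < 2:
        raise ValueError("need >=2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    sum_ij = comb2(contingency)
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """ARI between two partitions of the identical feature set.

    Raises ``ValueError`` listing the symmetric difference when the feature
    sets differ.  Invariant to cluster relabeling; 1.0 for identical
    partitions.
    """
    if set(p.feature_names) != set(q.feature_names):
        diff = sorted(set(p.feature_names) ^ set(q.feature_names))
        raise ValueError(f"feature sets differ; symmetric difference: {diff}")
    order = {f: i for i, f in enumerate(p.feature_names)}
    q_labels = np.empty(len(q.feature_names), dtype=int)
    for f, lab in zip(q.feature_names, q.labels):
        q_labels[order[f]] = lab
    return ari_from_labels(p.labels, q_labels)


def is_degenerate(partition: Partition, giant_fraction: float = 0.9) -> bool:
    """Flag one-giant-cluster-plus-singletons partitions (chaining artifacts)."""
    sizes = sorted(
        (len(v) for v in partition.clusters().values()), reverse=True
    )
    if len(sizes) < 2:
        return False
    return sizes[0] >= giant_fraction * sum(sizes) and all(
        s == 1 for s in sizes[1:]
    )


def _usable_features(pair: AlignedPair) -> list[str]:
    """Features non-constant and finite on both platforms (metric-safe)."""
    va, vb = pair.table_a.values, pair.table_b.values
    ok = (
        np.all(np.isfinite(va), axis=0)
        & np.all(np.isfinite(vb), axis=0)
        & (va.std(axis=0) > 0)
        & (vb.std(axis=0) > 0)
    )
    return [f for f, good in zip(pair.common_features, ok) if good]


def evaluate_grid(
    pair: AlignedPair,
    metrics: tuple[str, ...] = ALL_METRICS,
    linkages: tuple[str, ...] = ("ward.D2", "average", "complete", "single", "centroid"),
    k_policy: str = "consensus",
    k_range: tuple[int, int] = (2, 10),
    early_stop: tuple[float, int] = (0.5, 3),
    standardize: bool = True,
    fixed_k: int | None = None,
) -> list[StabilityRecord]:
    """Cluster both platforms under every metric x linkage configuration.

    ``k_policy``: ``consensus`` lets each platform use its own consensus k;
    ``common`` forces platform A's consensus k on both sides; ``fixed`` uses
    ``fixed_k`` everywhere.  Per-cell failures are recorded, not fatal.
    """
    if k_policy not in {"consensus", "common", "fixed"}:
        raise ValueError(f"unknown k_policy {k_policy!r}")
    if k_policy == "fixed" and fixed_k is None:
        raise ValueError("k_policy='fixed' requires fixed_k")
    features = _usable_features(pair)
    if len(features) < 3:
        raise ValueError("fewer than 3 usable common features")
    Xa = pair.table_a.subset(feature_names=features).values
    Xb = pair.table_b.subset(feature_names=features).values

    records: list[StabilityRecord] = []
    for metric in metrics:
        for linkage in linkages:
            rec = StabilityRecord(metric=metric, linkage=linkage)
            rec.euclidean_warning = (
                linkage in ("ward.D2", "centroid")
                and metric not in EUCLIDEAN_SAFE_METRICS
            )
            try:
                da = feature_distance(Xa, features, metric, standardize=standardize)
                db = feature_distance(Xb, features, metric, standardize=standardize)
                if da.feature_names != db.feature_names:
                    # metric-level exclusions must agree so partitions compare
                    common = [f for f in da.feature_names
                              if f in set(db.feature_names)]
                    if len(common) < 3:
                        raise ValueError("metric excluded too many features")
                    ia = [da.feature_names.index(f) for f in common]
                    ib = [db.feature_names.index(f) for f in common]
                    da.d, da.feature_names = da.d[np.ix_(ia, ia)], common
                    db.d, db.feature_names = db.d[np.ix_(ib, ib)], common

                Za = linkage_matrix(da, linkage)
                Zb = linkage_matrix(db, linkage)
                if k_policy == "fixed":
                    k_a = k_b = int(fixed_k)  # type: ignore[arg-type]
                else:
                    ka_report = select_k_consensus(
                        da, linkage, k_range=k_range, early_stop=early_stop,
                        X=Xa if da.feature_names == features else None,
                    )
                    k_a = ka_report.consensus_k
                    if k_policy == "common":
                        k_b = k_a
                    else:
                        kb_report = select_k_consensus(
                            db, linkage, k_range=k_range, early_stop=early_stop,
                            X=Xb if db.feature_names == features else None,
                        )
                        k_b = kb_report.consensus_k
                pa = Partition(metric, linkage, k_a, list(da.feature_names),
                               cut_merges(Za, k_a))
                pb = Partition(metric, linkage, k_b, list(db.feature_names),
                               cut_merges(Zb, k_b))
                ia_idx = internal_indices(pa, da)
                ib_idx = internal_indices(pb, db)
                rec.k_a, rec.k_b = k_a, k_b
                rec.ari = adjusted_rand_index(pa, pb)
                rec.silhouette_a = ia_idx["silhouette"]
                rec.silhouette_b = ib_idx["silhouette"]
                rec.dunn_a = ia_idx["dunn"]
                rec.dunn_b = ib_idx["dunn"]
                rec.degenerate_a = is_degenerate(pa)
                rec.degenerate_b = is_degenerate(pb)
                rec.partition_a, rec.partition_b = pa, pb
            except (ValueError, np.linalg.LinAlgError) as exc:
                rec.error = str(exc)
            records.append(rec)
    return records


def select_stable_configs(
    records: list[StabilityRecord],
    ari_threshold: float = DEFAULT_ARI_THRESHOLD,
) -> list[StabilityRecord]:
    """Configurations with ARI >= threshold, best first.

    Sorted by ARI descending, then platform-A silhouette descending, then
    (metric, linkage) for determinism.  An empty result is allowed; callers
    flag it.
    """
    if not records:
        raise ValueError("no stability records")
    stable = []
    for rec in records:
        rec.stable = bool(
            rec.error is None
            and np.isfinite(rec.ari)
            and rec.ari >= ari_threshold
        )
        if rec.stable:
            stable.append(rec)
    stable.sort(
        key=lambda r: (-r.ari, -(r.silhouette_a if np.isfinite(r.silhouette_a)
                                 else -np.inf), r.metric, r.linkage)
    )
    return stable
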