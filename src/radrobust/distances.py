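"""Feature-feature dissimilarity matrices.

Five metrics over feature columns (points are features, coordinates are
lesions): Pearson and Spearman correlation distances ``sqrt(2 (1 - r))``,
Euclidean, Manhattan and cosine distance ``1 - cos``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "DistanceMatrix",
    "CORRELATION_METRICS",
    "GEOMETRIC_METRICS",
    "ALL_METRICS",
    "correlation_distance",
    "geometric_distance",
    "feature_distance",
]

CORRELATION_METRICS = ("pearson", "spearman")
GEOMETRIC_METRICS = ("euclidean", "manhattan", "cosine")
ALL_METRICS = CORRELATION_METRICS + GEOMETRIC_METRICS


@dataclass
class DistanceMatrix:
    """Symmetric feature-feature dissimilarity matrix tagged with its metric."""

    metric: str
    feature_names: list[str]
    d: np.ndarray
    excluded: list[str] = field(default_factory=list)  # features the metric rejects
    standardized: bool | None = None  # None for correlation metrics (vacuous)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        p = len(self.feature_names)
        if self.d.shape != (p, p):
            raise ValueError(f"matrix shape {self.d.shape} != ({p}, {p})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix has a non-zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distance matrix has negative entries")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def _validated(X: np.ndarray, feature_names: list[str]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError("X must be lesions x features matching feature_names")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values; filter features first")
    return X


def correlation_distance(
    X: np.ndarray, feature_names: list[str], rank: bool = False
) -> DistanceMatrix:
    """``d[j,k] = sqrt(2 (1 - r_jk))`` with Pearson or (``rank=True``) Spearman r.

    Constant features have undefined correlation and are excluded, recorded in
    ``DistanceMatrix.excluded``.  Requires >=3 lesions.
    """
    X = _validated(X, feature_names)
    if X.shape[0] < 3:
        raise ValueError("correlation distance needs >=3 lesions")
    keep = X.std(axis=0) > 0
    excluded = [f for f, k in zip(feature_names, keep) if not k]
    names = [f for f, k in zip(feature_names, keep) if k]
    Xk = X[:, keep]
    if Xk.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")
    if rank:
        Xk = np.apply_along_axis(rankdata, 0, Xk)  # average ranks for ties
    r = np.corrcoef(Xk.T)
    d = np.sqrt(np.clip(2.0 * (1.0 - r), 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    metric = "spearman" if rank else "pearson"
    return DistanceMatrix(metric, names, d, excluded=excluded)


def geometric_distance(
    X: np.ndarray,
    feature_names: list[str],
    metric: str,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean, Manhattan or cosine distance between feature columns.

    With ``standardize`` (default) columns are z-scored across lesions first;
    raw radiomic features span orders of magnitude, which otherwise dominates
    these metrics.  Constant columns cannot be z-scored and all-zero columns
    have no cosine direction; both are excluded with a record.
    """
    if metric not in GEOMETRIC_METRICS:
        raise ValueError(f"unknown geometric metric {metric!r}")
    X = _validated(X, feature_names)
    if X.shape[0] < 2:
        raise ValueError("geometric distance needs >=2 lesions")
    if standardize:
        keep = X.std(axis=0) > 0
    elif metric == "cosine":
        keep = np.linalg.norm(X, axis=0) > 0
    else:
        keep = np.ones(X.shape[1], dtype=bool)
    excluded = [f for f, k in zip(feature_names, keep) if not k]
    names = [f for f, k in zip(feature_names, keep) if k]
    Xk = X[:, keep]
    if Xk.shape[1] < 2:
        raise ValueError("fewer than 2 usable features")
    if standardize:
        Xk = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
    scipy_metric = {"euclidean": "euclidean", "manhattan": "cityblock",
                    "cosine": "cosine"}[metric]
    d = squareform(pdist(Xk.T, metric=scipy_metric))
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(metric, names, d, excluded=excluded,
                          standardized=standardize)


def feature_distance(
    X: np.ndarray,
    feature_names: list[str],
    metric: str,
    standardize: bool = True,
) -> DistanceMatrix:
    """Dispatch to the correlation or geometric implementation by metric name."""
    if metric == "pearson":
        return correlation_distance(X, feature_names, rank=False)
    if metric == "spearman":
        return correlation_distance(X, feature_names, rank=True)
    return geometric_distance(X, feature_names, metric, standardize=standardize)
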