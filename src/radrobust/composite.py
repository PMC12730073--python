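"""Composite Index: per-feature cross-platform robustness and winner selection.

For each feature f measured on both platforms the index combines three
components, each standardized by a robust z-score across the feature cohort:

* ``r_f``   — Pearson correlation of the two platforms' values (shape consistency)
* ``D_f``   — two-sample Kolmogorov-Smirnov statistic (distributional similarity)
* ``MFR_f`` — stabilized absolute log-ratio of mean values (scale bias)

``CI_f = z_corr_f - z_KS_f - z_MFR_f`` so that strong correlation, low
distributional divergence and low scale bias all push CI up.  The
highest-CI feature of each cluster is its "winner"; features within a
tolerance of the winner are "near-winners"; quality-control filters then
drop weakly correlated or mutually redundant selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from radrobust.clustering import Partition
from radrobust.io import AlignedPair

__all__ = [
    "FeatureRobustnessRecord",
    "SelectionResult",
    "ks_statistic",
    "mean_fractional_ratio",
    "robust_z",
    "composite_index",
    "select_winners",
    "qc_filter",
    "aggregate_winner_frequencies",
]

DEFAULT_EPSILON = 1e-6
DEFAULT_NEAR_WINNER_DELTA = 0.5
DEFAULT_MIN_CORR = 0.6
DEFAULT_REDUNDANCY_CUTOFF = 0.9

_MAD_SCALE = 1.4826          # MAD -> sigma under normality
_IQR_SCALE = 1.349           # IQR -> sigma under normality


@dataclass(frozen=True)
class FeatureRobustnessRecord:
    feature_name: str
    r: float        # inter-platform Pearson correlation
    ks: float       # two-sample KS statistic
    mfr: float      # |log mean ratio|, epsilon-stabilized
    mfr_sign: int   # +1 if platform A mean dominates, -1 if B, 0 if equal
    z_corr: float
    z_ks: float
    z_mfr: float
    ci: float

    def to_row(self) -> dict:
        return {
            "feature": self.feature_name,
            "r": self.r,
            "ks": self.ks,
            "mfr": self.mfr,
            "mfr_sign": self.mfr_sign,
            "z_corr": self.z_corr,
            "z_ks": self.z_ks,
            "z_mfr": self.z_mfr,
            "ci": self.ci,
        }


@dataclass
class SelectionResult:
    """Per-cluster winners/near-winners and the QC-filtered final set."""

    winners: dict[int, str]                       # cluster -> winner feature
    co_winners: dict[int, list[str]] = field(default_factory=dict)
    near_winners: dict[int, list[str]] = field(default_factory=dict)
    skipped_clusters: list[int] = field(default_factory=list)
    qc_pass: dict[str, bool] = field(default_factory=dict)
    qc_reasons: dict[str, str] = field(default_factory=dict)
    final_set: list[str] = field(default_factory=list)

    def selected(self) -> list[str]:
        out = []
        for c in sorted(self.winners):
            out.append(self.winners[c])
            out.extend(self.near_winners.get(c, []))
        return out


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup distance between ECDFs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >=2 values")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def mean_fractional_ratio(
    a: np.ndarray, b: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> tuple[float, int]:
    """Stabilized absolute log-ratio of mean values, plus the bias direction.

    ``MFR = |log((|mean a| + eps) / (|mean b| + eps))|``; 0 means no scale
    bias.  The sign (+1: A dominates, -1: B dominates) is kept separately.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty vector")
    log_ratio = float(
        np.log((abs(a.mean()) + epsilon) / (abs(b.mean()) + epsilon))
    )
    return abs(log_ratio), int(np.sign(log_ratio))


def robust_z(values: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores with an IQR fallback for zero MAD.

    ``z = (x - median) / (1.4826 * MAD)``; when MAD is 0 the scale falls back
    to IQR/1.349, and when that is 0 too every z is 0 (constant input).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = _MAD_SCALE * mad
    # treat float-noise-level spread as constant input (e.g. correlations
    # that are all 1.0 up to rounding must not explode into huge z-scores)
    tiny = 1e-12 * max(1.0, float(np.abs(x).max()))
    if scale <= tiny:
        q1, q3 = np.percentile(x, [25, 75])
        scale = (q3 - q1) / _IQR_SCALE
    if scale <= tiny:
        return np.zeros_like(x)
    return (x - med) / scale


def composite_index(
    pair: AlignedPair,
    features: list[str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[FeatureRobustnessRecord]:
    """Composite Index for every feature of an aligned platform pair.

    z-scores are computed across the feature cohort entering this stage, so
    the index is relative to that cohort; at least 3 features are required.
    """
    if features is None:
        features = list(pair.common_features)
    if len(features) < 3:
        raise ValueError("composite index needs >=3 features")
    fa = pair.table_a.subset(feature_names=features)
    fb = pair.table_b.subset(feature_names=features)
    r = np.empty(len(features))
    ks = np.empty(len(features))
    mfr = np.empty(len(features))
    sign = np.empty(len(features), dtype=int)
    for j, _ in enumerate(features):
        a, b = fa.values[:, j], fb.values[:, j]
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError(f"feature {features[j]!r} has missing values")
        if a.std() == 0 or b.std() == 0:
            r[j] = np.nan  # correlation undefined for a constant vector
        else:
            r[j] = stats.pearsonr(a, b).statistic
        ks[j] = ks_statistic(a, b)
        mfr[j], sign[j] = mean_fractional_ratio(a, b, epsilon=epsilon)
    r_filled = np.where(np.isfinite(r), r, 0.0)  # constant features score worst
    z_corr = robust_z(r_filled)
    z_ks = robust_z(ks)
    z_mfr = robust_z(mfr)
    ci = z_corr - z_ks - z_mfr
    return [
        FeatureRobustnessRecord(
            f, float(r_filled[j]), float(ks[j]), float(mfr[j]), int(sign[j]),
            float(z_corr[j]), float(z_ks[j]), float(z_mfr[j]), float(ci[j]),
        )
        for j, f in enumerate(features)
    ]


def select_winners(
    partition: Partition,
    records: list[FeatureRobustnessRecord],
    delta: float = DEFAULT_NEAR_WINNER_DELTA,
) -> SelectionResult:
    """Per-cluster winner (argmax CI) and near-winners (CI within ``delta``).

    Exact CI ties crown the lexicographically first name; all tied features
    are reported as co-winners.  Clusters with no scored feature are skipped
    and reported.
    """
    by_name = {rec.feature_name: rec for rec in records}
    result = SelectionResult(winners={})
    for cluster, members in sorted(partition.clusters().items()):
        scored = sorted(
            (m for m in members if m in by_name),
            key=lambda m: (-by_name[m].ci, m),
        )
        if not scored:
            result.skipped_clusters.append(cluster)
            continue
        winner = scored[0]
        ci_w = by_name[winner].ci
        result.winners[cluster] = winner
        result.co_winners[cluster] = [
            m for m in scored if by_name[m].ci == ci_w
        ]
        result.near_winners[cluster] = [
            m for m in scored[1:] if ci_w - by_name[m].ci <= delta
        ]
    return result


def qc_filter(
    selection: SelectionResult,
    records: list[FeatureRobustnessRecord],
    partition: Partition,
    values: np.ndarray,
    feature_names: list[str],
    min_corr: float = DEFAULT_MIN_CORR,
    redundancy_cutoff: float = DEFAULT_REDUNDANCY_CUTOFF,
) -> list[str]:
    """Quality-control the selected features into the final set.

    Drops selections whose inter-platform correlation is below ``min_corr``,
    then greedily (descending CI) drops any feature whose within-cluster
    |Pearson correlation| with an already-kept feature exceeds
    ``redundancy_cutoff``.  ``values`` are the platform-A lesion vectors used
    for the redundancy correlations.  Reasons land in ``selection.qc_reasons``
    and the final set in ``selection.final_set``.
    """
    by_name = {rec.feature_name: rec for rec in records}
    col = {f: j for j, f in enumerate(feature_names)}
    label = partition.label_of()
    candidates = sorted(
        set(selection.selected()), key=lambda f: (-by_name[f].ci, f)
    )
    kept: list[str] = []
    for f in candidates:
        if by_name[f].r < min_corr:
            selection.qc_pass[f] = False
            selection.qc_reasons[f] = (
                f"inter-platform correlation {by_name[f].r:.3f} < {min_corr}"
            )
            continue
        redundant_with = None
        for g in kept:
            if label.get(g) != label.get(f):
                continue
            x, y = values[:, col[f]], values[:, col[g]]
            if x.std() == 0 or y.std() == 0:
                continue
            if abs(stats.pearsonr(x, y).statistic) > redundancy_cutoff:
                redundant_with = g
                break
        if redundant_with is not None:
            selection.qc_pass[f] = False
            selection.qc_reasons[f] = f"redundant with {redundant_with}"
            continue
        selection.qc_pass[f] = True
        kept.append(f)
    selection.final_set = kept
    return kept


def aggregate_winner_frequencies(
    solutions: list[SelectionResult],
) -> list[dict]:
    """Winner and winner-or-near-winner counts across stable solutions.

    Rows sorted by winner count descending, then combined count, then name.
    """
    if not solutions:
        raise ValueError("need >=1 solution")
    win: dict[str, int] = {}
    either: dict[str, int] = {}
    for sol in solutions:
        winners = set(sol.winners.values())
        near = {f for fs in sol.near_winners.values() for f in fs}
        for f in winners:
            win[f] = win.get(f, 0) + 1
        for f in winners | near:
            either[f] = either.get(f, 0) + 1
    rows = [
        {
            "feature": f,
            "winner_count": win.get(f, 0),
            "winner_or_near_count": either.get(f, 0),
        }
        for f in either
    ]
    rows.sort(key=lambda r: (-r["winner_count"], -r["winner_or_near_count"],
                             r["feature"]))
    return rows
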