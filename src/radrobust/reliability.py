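"""Intra-software repeatability via ICC(A,1) and robustness filtering.

ICC(A,1) is the two-way model, single-measurement, absolute-agreement
intraclass correlation:

    icc = (MSR - MSE) / (MSR + (k - 1) MSE + k (MSC - MSE) / n)

where MSR is the mean square between subjects, MSC the mean square between
measurements, MSE the residual mean square, k the number of repeated
measurements and n the number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCComponents",
    "ICCResult",
    "compute_icc_a1",
    "classify_reliability",
    "icc_results",
    "filter_robust",
    "load_repeated_measures_csv",
]

#: category boundaries, closed on the left so they align with the >= 0.75 gate
_CATEGORIES = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))

DEFAULT_ICC_THRESHOLD = 0.75

_EPS = 1e-12


@dataclass(frozen=True)
class ICCComponents:
    """Two-way ANOVA mean squares backing an ICC(A,1) value."""

    msr: float  # mean square between subjects
    msc: float  # mean square between measurements
    mse: float  # residual mean square
    k: int      # repeated measurements per subject
    n: int      # subjects


@dataclass(frozen=True)
class ICCResult:
    feature_name: str
    icc: float  # NaN when undefined (zero total variance)
    category: str  # poor / moderate / good / excellent / undefined
    retained: bool


def compute_icc_a1(measurements: np.ndarray) -> tuple[ICCComponents, float]:
    """ICC(A,1) of a complete subjects x repetitions matrix.

    Returns the ANOVA components and the coefficient; the coefficient is NaN
    (undefined) when the matrix carries no variance at all.

    Raises ``ValueError`` on fewer than 2 subjects/repetitions or on any
    missing cell, naming the offending subject and repetition.
    """
    y = np.asarray(measurements, dtype=float)
    if y.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x repetitions matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >=2 subjects and >=2 repetitions, got {n}x{k}")
    bad = np.argwhere(~np.isfinite(y))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"missing measurement at subject {i}, repetition {j}")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    components = ICCComponents(float(msr), float(msc), float(mse), k, n)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    scale = max(abs(y).max(), 1.0) ** 2
    if abs(denom) <= _EPS * scale:
        return components, float("nan")
    return components, float((msr - mse) / denom)


def classify_reliability(icc: float) -> str:
    """Reliability category; intervals closed on the left (0.75 -> good)."""
    if not np.isfinite(icc):
        return "undefined"
    for lo, name in _CATEGORIES:
        if icc >= lo:
            return name
    return "poor"


def icc_results(
    measurements: dict[str, np.ndarray],
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> list[ICCResult]:
    """Per-feature ICC(A,1) with category and retention flag.

    ``measurements`` maps feature name -> subjects x repetitions matrix.
    Undefined ICC (constant feature) is never retained.
    """
    out = []
    for name, matrix in measurements.items():
        _, icc = compute_icc_a1(matrix)
        retained = bool(np.isfinite(icc) and icc >= threshold)
        out.append(ICCResult(name, icc, classify_reliability(icc), retained))
    return out


def filter_robust(
    results_per_platform: dict[str, list[ICCResult]],
    mode: str = "intersection",
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-platform retained feature lists plus the combined set.

    ``mode`` controls how per-platform sets combine for the cross-platform
    stage: ``intersection`` (default), ``union`` or a single platform id.
    """
    per_platform = {
        pid: [r.feature_name for r in results if r.retained]
        for pid, results in results_per_platform.items()
    }
    sets = [set(v) for v in per_platform.values()]
    if mode == "intersection":
        combined_set = set.intersection(*sets) if sets else set()
    elif mode == "union":
        combined_set = set.union(*sets) if sets else set()
    elif mode in per_platform:
        combined_set = set(per_platform[mode])
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    # deterministic order: first platform's listing order, then the rest
    seen, combined = set(), []
    for listing in per_platform.values():
        for f in listing:
            if f in combined_set and f not in seen:
                seen.add(f)
                combined.append(f)
    return per_platform, combined


def load_repeated_measures_csv(path: str) -> dict[str, np.ndarray]:
    """Read long-format repeated measures: columns lesion_id, repetition, features...

    Returns feature name -> subjects x repetitions matrix (subjects sorted by
    first appearance, repetitions sorted by label).  Missing cells stay NaN
    and are caught by :func:`compute_icc_a1`.
    """
    df = pd.read_csv(path)
    required = {"lesion_id", "repetition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    subjects = list(dict.fromkeys(df["lesion_id"]))
    reps = sorted(df["repetition"].unique())
    features = [c for c in df.columns if c not in required]
    out: dict[str, np.ndarray] = {}
    pivotable = df.set_index(["lesion_id", "repetition"])
    for feat in features:
        wide = pivotable[feat].unstack("repetition")
        wide = wide.reindex(index=subjects, columns=reps)
        out[feat] = wide.to_numpy(dtype=float)
    return out
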