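"""Reading, validation, harmonization and alignment of platform feature tables.

A feature table is a lesions x features numeric matrix exported by a radiomic
extraction platform as delimited text: one lesion-id column followed by one
column per feature.  Two platforms exporting the same PyRadiomics-style
feature core may still differ in naming dialect (case, separators, vendor
prefixes), so alignment harmonizes names before intersecting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMeta",
    "FeatureTable",
    "AlignedPair",
    "ParseReport",
    "AlignmentReport",
    "harmonize_feature_name",
    "parse_feature_name",
    "read_feature_table",
    "write_feature_table",
    "align_platforms",
]

#: feature families recognised in `<filter>_<family>_<name>` column names
FAMILIES = frozenset(
    {"firstorder", "shape", "shape2d", "glcm", "glrlm", "glszm", "gldm", "ngtdm"}
)

#: three-axis wavelet sub-band codes (low/high pass along x, y, z)
WAVELET_BANDS = frozenset(
    {"lll", "llh", "lhl", "lhh", "hll", "hlh", "hhl", "hhh"}
)

#: vendor prefixes stripped before cross-platform name matching
PLATFORM_PREFIXES = ("pyradiomics_", "radiomics_", "syngo_", "slicer_", "mm_")

_SEPARATORS = re.compile(r"[-.\s]+")
_MULTI_UNDERSCORE = re.compile(r"_+")


def harmonize_feature_name(name: str) -> str:
    """Canonicalize a feature column name for cross-platform matching.

    Case-folds, maps ``-``, ``.`` and whitespace to ``_``, collapses repeated
    underscores and strips known vendor prefixes.
    """
    s = _SEPARATORS.sub("_", str(name).strip().casefold())
    s = _MULTI_UNDERSCORE.sub("_", s).strip("_")
    for prefix in PLATFORM_PREFIXES:
        if s.startswith(prefix) and len(s) > len(prefix):
            s = s[len(prefix):]
            break
    return s


@dataclass(frozen=True)
class FeatureMeta:
    """Filter / family metadata parsed from a feature column name."""

    feature_name: str
    filter: str | None  # "original" or "wavelet-LLL" .. "wavelet-HHH"
    family: str | None  # firstorder, shape, glcm, glrlm, glszm, gldm, ngtdm
    parsed: bool


def parse_feature_name(name: str) -> FeatureMeta:
    """Parse ``<filter>_<family>_<featurename>`` into :class:`FeatureMeta`.

    Unparseable names are flagged (``parsed=False``), never dropped.
    """
    parts = harmonize_feature_name(name).split("_")
    if len(parts) >= 3 and parts[0] == "original" and parts[1] in FAMILIES:
        return FeatureMeta(name, "original", parts[1], True)
    if (
        len(parts) >= 4
        and parts[0] == "wavelet"
        and parts[1] in WAVELET_BANDS
        and parts[2] in FAMILIES
    ):
        return FeatureMeta(name, f"wavelet-{parts[1].upper()}", parts[2], True)
    return FeatureMeta(name, None, None, False)


@dataclass
class ParseReport:
    """What happened while reading a table."""

    platform_id: str
    source: str
    dropped_columns: list[str] = field(default_factory=list)
    coerced_cells: list[tuple[str, str]] = field(default_factory=list)  # (lesion, feature)
    unparseable_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "platform_id": self.platform_id,
            "source": self.source,
            "dropped_columns": list(self.dropped_columns),
            "coerced_cells": [list(c) for c in self.coerced_cells],
            "unparseable_names": list(self.unparseable_names),
        }


@dataclass
class FeatureTable:
    """Lesions x features numeric matrix with a platform label.

    ``values`` is an (n_lesions, n_features) float array; missing entries are
    NaN and are reported, not silently imputed.
    """

    platform_id: str
    lesion_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lesion_ids), len(self.feature_names)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.lesion_ids)} lesions x {len(self.feature_names)} features"
            )
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            raise ValueError("duplicate lesion ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def meta(self) -> list[FeatureMeta]:
        return [parse_feature_name(n) for n in self.feature_names]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.lesion_ids, name="lesion_id"),
            columns=self.feature_names,
        )

    def validate(self) -> list[tuple[str, str]]:
        """Return (lesion_id, feature_name) for every non-finite entry."""
        bad = np.argwhere(~np.isfinite(self.values))
        return [(self.lesion_ids[i], self.feature_names[j]) for i, j in bad]

    def subset(
        self, lesion_ids: list[str] | None = None,
        feature_names: list[str] | None = None,
    ) -> "FeatureTable":
        lesions = self.lesion_ids if lesion_ids is None else list(lesion_ids)
        feats = self.feature_names if feature_names is None else list(feature_names)
        li = [self.lesion_ids.index(l) for l in lesions]
        fi = [self.feature_names.index(f) for f in feats]
        return FeatureTable(
            self.platform_id, lesions, feats, self.values[np.ix_(li, fi)]
        )

    def rename_features(self, mapping: dict[str, str]) -> "FeatureTable":
        return FeatureTable(
            self.platform_id,
            list(self.lesion_ids),
            [mapping.get(f, f) for f in self.feature_names],
            self.values.copy(),
        )


@dataclass
class AlignmentReport:
    exclusive_a: list[str] = field(default_factory=list)
    exclusive_b: list[str] = field(default_factory=list)
    lesions_dropped_a: list[str] = field(default_factory=list)
    lesions_dropped_b: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exclusive_a": list(self.exclusive_a),
            "exclusive_b": list(self.exclusive_b),
            "lesions_dropped_a": list(self.lesions_dropped_a),
            "lesions_dropped_b": list(self.lesions_dropped_b),
        }


@dataclass
class AlignedPair:
    """Two platform tables restricted to shared lesions and harmonized features."""

    table_a: FeatureTable
    table_b: FeatureTable
    common_features: list[str]
    report: AlignmentReport = field(default_factory=AlignmentReport)

    def __post_init__(self) -> None:
        if self.table_a.feature_names != self.common_features:
            raise ValueError("table_a feature order differs from common_features")
        if self.table_b.feature_names != self.common_features:
            raise ValueError("table_b feature order differs from common_features")
        if self.table_a.lesion_ids != self.table_b.lesion_ids:
            raise ValueError("lesion order differs between tables")


def _parse_float(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def read_feature_table(
    path: str,
    platform_id: str,
    lesion_id_column: str | None = None,
    sep: str | None = None,
) -> tuple[FeatureTable, ParseReport]:
    """Read a delimited feature table (header row, lesion-id column first).

    Non-numeric cells inside otherwise numeric columns are coerced to NaN and
    reported; columns with no numeric content at all are dropped and reported.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a lesion-id column and >=1 feature column")
    if lesion_id_column is None:
        lesion_id_column = df.columns[0]
    if lesion_id_column not in df.columns:
        raise ValueError(f"{path}: missing lesion-id column {lesion_id_column!r}")
    lesion_ids = [str(v) for v in df[lesion_id_column]]
    if len(set(lesion_ids)) != len(lesion_ids):
        dupes = sorted({l for l in lesion_ids if lesion_ids.count(l) > 1})
        raise ValueError(f"{path}: duplicate lesion ids {dupes}")

    report = ParseReport(platform_id=platform_id, source=str(path))
    feature_cols = [c for c in df.columns if c != lesion_id_column]
    kept, columns = [], []
    for col in feature_cols:
        raw = df[col]
        # float() per cell: exact decimal round-trip, unlike pandas' fast parser
        numeric = np.array([_parse_float(v) for v in raw], dtype=float)
        if np.all(np.isnan(numeric)):
            report.dropped_columns.append(col)
            continue
        coerced = np.isnan(numeric) & raw.notna().to_numpy()
        for i in np.flatnonzero(coerced):
            report.coerced_cells.append((lesion_ids[i], col))
        kept.append(col)
        columns.append(numeric)
    if not kept:
        raise ValueError(f"{path}: zero numeric feature columns")
    report.unparseable_names = [c for c in kept if not parse_feature_name(c).parsed]
    table = FeatureTable(platform_id, lesion_ids, kept, np.column_stack(columns))
    return table, report


def write_feature_table(table: FeatureTable, path: str) -> None:
    """Write as CSV; float formatting round-trips via ``repr``."""
    table.to_frame().to_csv(path)


def align_platforms(a: FeatureTable, b: FeatureTable) -> AlignedPair:
    """Restrict two tables to shared lesions and name-harmonized shared features.

    Features are matched on :func:`harmonize_feature_name`; both tables are
    renamed to the harmonized names so downstream stages see one vocabulary.
    Shared lesions/features keep platform A's order.
    """
    ha = {harmonize_feature_name(f): f for f in a.feature_names}
    hb = {harmonize_feature_name(f): f for f in b.feature_names}
    if len(ha) != a.n_features or len(hb) != b.n_features:
        raise ValueError("name harmonization collides within one platform")
    common = [harmonize_feature_name(f) for f in a.feature_names
              if harmonize_feature_name(f) in hb]
    if not common:
        raise ValueError("zero shared features after harmonization")
    shared_lesions = [l for l in a.lesion_ids if l in set(b.lesion_ids)]
    if len(shared_lesions) < 2:
        raise ValueError(
            f"only {len(shared_lesions)} shared lesion id(s); need >=2"
        )
    report = AlignmentReport(
        exclusive_a=[ha[h] for h in ha if h not in hb],
        exclusive_b=[hb[h] for h in hb if h not in ha],
        lesions_dropped_a=[l for l in a.lesion_ids if l not in set(shared_lesions)],
        lesions_dropped_b=[l for l in b.lesion_ids if l not in set(shared_lesions)],
    )
    sub_a = a.subset(shared_lesions, [ha[h] for h in common]).rename_features(
        {ha[h]: h for h in common}
    )
    sub_b = b.subset(shared_lesions, [hb[h] for h in common]).rename_features(
        {hb[h]: h for h in common}
    )
    return AlignedPair(sub_a, sub_b, common, report)
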