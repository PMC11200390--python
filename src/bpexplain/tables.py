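"""Radiomic feature tables: the naming convention, the data model, and I/O.

A feature table holds one row per MRI slice and one column per named
radiomic feature, plus patient id, slice id, and the ordinal BPE label
(1=minimal, 2=mild, 3=moderate, 4=marked).  Feature names follow the
dominant radiomics-extractor convention ``<filter>_<class>_<type>``,
e.g. ``log-sigma-2-0-mm-3D_glrlm_GrayLevelNonUniformity``: hyphens are
allowed inside parts, underscores separate the three parts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Closed set of radiomic feature classes (first-order statistics, 2-D shape
#: descriptors, and the five texture-matrix families).
FEATURE_CLASSES = frozenset(
    {"firstorder", "shape2D", "glcm", "glszm", "glrlm", "ngtdm", "gldm"}
)

LABEL_NAMES = {1: "minimal", 2: "mild", 3: "moderate", 4: "marked"}

METADATA_COLUMNS = ("patient_id", "slice_id", "label")


class FeatureNameError(ValueError):
    """Raised when a column name does not follow the naming convention."""


@dataclasses.dataclass(frozen=True)
class FeatureName:
    """Three-part decomposition of a radiomic feature name.

    ``raw`` round-trips as ``filter_tag + "_" + feature_class + "_" +
    feature_type``.  ``feature_type`` is the terminal token (e.g.
    ``GrayLevelNonUniformity``) — the unit at which importance reports
    aggregate, pooled over filters and texture-matrix classes.
    """

    raw: str
    filter_tag: str
    feature_class: str
    feature_type: str


def parse_feature_name(raw: str) -> FeatureName:
    """Split a raw column name into filter tag, feature class and type.

    The feature class is the second-to-last underscore-separated token and
    must belong to :data:`FEATURE_CLASSES`; the filter tag is everything
    before it (and may itself contain hyphens or underscores).
    """
    if not raw:
        raise FeatureNameError("empty feature name")
    parts = raw.rsplit("_", 2)
    if len(parts) != 3 or not all(parts):
        raise FeatureNameError(
            f"feature name {raw!r} does not have the form <filter>_<class>_<type>"
        )
    filter_tag, feature_class, feature_type = parts
    if feature_class not in FEATURE_CLASSES:
        raise FeatureNameError(
            f"column {raw!r}: unrecognized feature class {feature_class!r} "
            f"(expected one of {sorted(FEATURE_CLASSES)})"
        )
    return FeatureName(raw, filter_tag, feature_class, feature_type)


def compose_feature_name(filter_tag: str, feature_class: str, feature_type: str) -> str:
    """Inverse of :func:`parse_feature_name`."""
    if feature_class not in FEATURE_CLASSES:
        raise FeatureNameError(f"unrecognized feature class {feature_class!r}")
    return f"{filter_tag}_{feature_class}_{feature_type}"


@dataclasses.dataclass
class FeatureTable:
    """Slices x radiomic features with patient/slice/label metadata.

    Invariants (enforced by :meth:`validate`): unique slice ids, labels in
    1..4, a rectangular finite value matrix, and parseable feature names.
    """

    patient_id: np.ndarray  # (n_slices,) str
    slice_id: np.ndarray  # (n_slices,) str, unique
    label: np.ndarray  # (n_slices,) int in 1..4
    feature_names: list[str]
    values: np.ndarray  # (n_slices, n_features) float64

    def __post_init__(self) -> None:
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.slice_id = np.asarray(self.slice_id, dtype=object)
        self.label = np.asarray(self.label, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = list(self.feature_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.slice_id)
        if n == 0:
            raise ValueError("feature table has no rows")
        if len(self.feature_names) == 0:
            raise ValueError("feature table has no feature columns")
        if self.values.shape != (n, len(self.feature_names)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} slices x {len(self.feature_names)} features"
            )
        if len(self.patient_id) != n or len(self.label) != n:
            raise ValueError("metadata column lengths disagree")
        if len(set(self.slice_id)) != n:
            raise ValueError("duplicate slice_id")
        bad = (self.label < 1) | (self.label > 4)
        if bad.any():
            raise ValueError(
                f"labels outside 1..4: {sorted(set(self.label[bad].tolist()))}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(
                "non-finite feature values after ingestion; "
                "use impute='median' on read_feature_table to impute instead"
            )
        for name in self.feature_names:
            parse_feature_name(name)

    # -- conveniences -------------------------------------------------------
    @property
    def n_slices(self) -> int:
        return len(self.slice_id)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def parsed_names(self) -> list[FeatureName]:
        return [parse_feature_name(n) for n in self.feature_names]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        """Row subset by boolean mask or integer index array."""
        return FeatureTable(
            self.patient_id[mask],
            self.slice_id[mask],
            self.label[mask],
            self.feature_names,
            self.values[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.label)
        df.insert(0, "slice_id", self.slice_id.astype(str))
        df.insert(0, "patient_id", self.patient_id.astype(str))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, impute: str | None = None) -> "FeatureTable":
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        feature_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
        if not feature_cols:
            raise ValueError("no feature columns found")
        values = df[feature_cols].to_numpy(dtype=float)
        if impute == "median":
            values = _impute_median(values)
        elif impute is not None:
            raise ValueError(f"unknown impute policy {impute!r}")
        return cls(
            df["patient_id"].astype(str).to_numpy(dtype=object),
            df["slice_id"].astype(str).to_numpy(dtype=object),
            df["label"].to_numpy(),
            feature_cols,
            values,
        )


def _impute_median(values: np.ndarray) -> np.ndarray:
    values = values.copy()
    bad = ~np.isfinite(values)
    if bad.any():
        med = np.nanmedian(np.where(np.isinf(values), np.nan, values), axis=0)
        if not np.isfinite(med).all():
            raise ValueError("cannot impute: some columns have no finite values")
        values[bad] = np.broadcast_to(med, values.shape)[bad]
    return values


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix in {".parquet", ".pq"}:
        return "parquet"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer table format from {path!r}; pass format=")


def read_feature_table(
    path: str | Path, format: str | None = None, impute: str | None = None
) -> FeatureTable:
    """Read a feature table from CSV or Parquet.

    Non-finite values are rejected unless ``impute='median'``, which fills
    them with the column median.  (When imputing a table that will be split,
    impute on the training split only and propagate the medians.)
    """
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return FeatureTable.from_frame(df, impute=impute)


def write_feature_table(
    table: FeatureTable, path: str | Path, format: str | None = None
) -> None:
    """Write a table; Parquet is lossless, CSV keeps 17 significant digits."""
    fmt = _infer_format(path, format)
    df = table.to_frame()
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
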