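"""Data model, file I/O, validation and standardization.

The universal in-memory container is a pandas DataFrame with one row per
sample (index = unique sample IDs) and one column per feature, holding
finite numeric values only — typically normalized relative expression
(2^-ddCt scale) or clinical units.  All downstream stages accept this
"feature matrix" form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrixError",
    "StandardizedMatrix",
    "ValidationReport",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_metadata",
    "standardize",
    "validate_dataset",
]


class FeatureMatrixError(ValueError):
    """Raised when a table violates the feature-matrix contract."""


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_matrix(path, id_column: str | int = 0, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited sample-by-feature table into a feature matrix.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row of feature names; one column holds
        the sample IDs.
    id_column : str or int, default 0
        Name or position of the sample-ID column.
    sep : str, optional
        Field delimiter.  Auto-detected from {comma, tab} when omitted.

    Raises
    ------
    FeatureMatrixError
        On missing values (named by row/column), duplicate IDs, or
        non-numeric cells.
    """
    if sep is None:
        sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if isinstance(id_column, int):
        id_column = raw.columns[id_column]
    if id_column not in raw.columns:
        raise FeatureMatrixError(f"ID column {id_column!r} not found in header")
    ids = raw[id_column].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise FeatureMatrixError(f"duplicate sample IDs: {dups}")
    body = raw.drop(columns=[id_column])
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            text = cell.strip()
            if text == "":
                raise FeatureMatrixError(
                    f"missing value at sample {ids.iloc[i]!r}, feature {col!r}"
                )
            try:
                values[i, j] = float(text)
            except ValueError:
                raise FeatureMatrixError(
                    f"non-numeric value {text!r} at sample {ids.iloc[i]!r}, feature {col!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FeatureMatrixError(
            f"non-finite value at sample {ids.iloc[i]!r}, feature {body.columns[j]!r}"
        )
    return pd.DataFrame(values, index=pd.Index(ids, name=id_column), columns=body.columns)


def write_feature_matrix(m: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a feature matrix with full double precision decimal text."""
    m.to_csv(path, sep=sep, float_format="%.17g")


def read_metadata(path, id_column: str | int = 0, sep: str | None = None) -> pd.DataFrame:
    """Read a sample-metadata table of categorical factors keyed by sample ID."""
    if sep is None:
        sep = _sniff_delimiter(path)
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if isinstance(id_column, int):
        id_column = meta.columns[id_column]
    meta = meta.set_index(id_column)
    if meta.index.duplicated().any():
        raise FeatureMatrixError("duplicate sample IDs in metadata")
    return meta


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored matrix with its centering/scale constants.

    ``values`` has the same shape and labels as the input; ``center`` and
    ``scale`` are the per-feature mean and sample SD (n-1 denominator).
    Constant columns are mapped to all-zero and listed in
    ``constant_features``.
    """

    values: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    constant_features: list[str] = field(default_factory=list)


def standardize(m: pd.DataFrame) -> StandardizedMatrix:
    """Z-score each feature using the sample SD (n-1 denominator).

    Constant columns cannot be scaled; they map to all-zero with a warning
    so that downstream detectors still run on small panels containing
    near-constant controls.
    """
    if m.shape[0] < 2:
        raise FeatureMatrixError("standardization needs at least 2 samples")
    center = m.mean(axis=0)
    scale = m.std(axis=0, ddof=1)
    constant = scale[scale == 0.0].index.tolist()
    if constant:
        warnings.warn(f"constant features standardized to zero: {constant}")
    safe_scale = scale.replace(0.0, 1.0)
    z = (m - center) / safe_scale
    return StandardizedMatrix(values=z, center=center, scale=scale, constant_features=constant)


@dataclass
class ValidationReport:
    n_samples: int
    n_features: int
    feature_min: pd.Series
    feature_max: pd.Series
    constant_features: list[str]
    metadata_aligned: bool
    ok: bool


def validate_dataset(m: pd.DataFrame, meta: pd.DataFrame | None = None) -> ValidationReport:
    """Check matrix invariants and (optionally) metadata/matrix ID alignment.

    Misaligned metadata is a hard error naming the offending IDs; constant
    features are only flagged in the report.
    """
    if m.index.duplicated().any():
        raise FeatureMatrixError("duplicate sample IDs")
    if m.shape[0] < 3:
        raise FeatureMatrixError("need at least 3 samples")
    if m.shape[1] < 1:
        raise FeatureMatrixError("need at least 1 feature")
    if not np.all(np.isfinite(m.to_numpy())):
        raise FeatureMatrixError("matrix contains non-finite values")
    aligned = True
    if meta is not None:
        missing = m.index.difference(meta.index)
        extra = meta.index.difference(m.index)
        if len(missing) or len(extra):
            raise FeatureMatrixError(
                f"metadata misaligned: missing={list(missing)} extra={list(extra)}"
            )
    spread = m.max(axis=0) - m.min(axis=0)
    constant = spread[spread == 0.0].index.tolist()
    return ValidationReport(
        n_samples=m.shape[0],
        n_features=m.shape[1],
        feature_min=m.min(axis=0),
        feature_max=m.max(axis=0),
        constant_features=constant,
        metadata_aligned=aligned,
        ok=True,
    )
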