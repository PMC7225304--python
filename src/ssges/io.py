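"""Reading, validation, merging and writing of expression matrices and sample annotations.

The in-memory expression matrix is a :class:`pandas.DataFrame` with gene
(probe or symbol) identifiers on the index, sample identifiers on the
columns, float64 log2 intensities as values and ``NaN`` marking missing
entries.  Orientation is fixed as genes-in-rows, samples-in-columns — the
dominant microarray convention — and readers reject malformed files rather
than guessing.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionFormatError",
    "AnnotationError",
    "CLASS_LABELS",
    "TBCL_SUBTYPES",
    "group_for_class",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_annotations",
    "write_sample_annotations",
    "merge_datasets",
    "validate_expression_matrix",
]

#: Missing-value tokens accepted on read; always written back as "NA".
MISSING_TOKENS = ("NA", "NaN", "nan", "null", "")

#: Sample-type vocabulary: control spleen, SMZL, and the tissue B-cell
#: lymphoma (TBCL) subtypes compared against it.
TBCL_SUBTYPES = ("DLBCL", "EMZL", "FL", "MCL", "NMZL")
CLASS_LABELS = ("CSP", "SMZL") + TBCL_SUBTYPES

_SM_TABLE_BEGIN = "!series_matrix_table_begin"
_SM_TABLE_END = "!series_matrix_table_end"


class ExpressionFormatError(ValueError):
    """Malformed expression matrix file or invalid matrix structure."""


class AnnotationError(ValueError):
    """Malformed or out-of-vocabulary sample annotation table."""


def group_for_class(class_label: str) -> str:
    """Map a sample-type label to its comparison group (CSP / SMZL / TBCL)."""
    if class_label == "CSP":
        return "CSP"
    if class_label == "SMZL":
        return "SMZL"
    if class_label in TBCL_SUBTYPES:
        return "TBCL"
    raise AnnotationError(
        f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
    )


def validate_expression_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning the matrix.

    Raises :class:`ExpressionFormatError` on duplicate gene or sample
    identifiers, or on non-finite values other than NaN (missing).
    """
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ExpressionFormatError(f"duplicate gene id: {dup!r}")
    if m.columns.has_duplicates:
        dup = m.columns[m.columns.duplicated()][0]
        raise ExpressionFormatError(f"duplicate sample id: {dup!r}")
    values = m.to_numpy(dtype=float)
    bad = np.isinf(values)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ExpressionFormatError(
            f"non-finite value at gene {m.index[i]!r}, sample {m.columns[j]!r}"
        )
    return m


def _parse_table(text_lines: Sequence[str], path: str) -> pd.DataFrame:
    """Parse a tab-delimited gene × sample block into a validated DataFrame."""
    if not text_lines or len(text_lines) < 2:
        raise ExpressionFormatError(f"{path}: empty data block")
    raw = pd.read_csv(
        _stdio.StringIO("\n".join(text_lines)),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    # series-matrix files quote identifiers
    raw.index = raw.index.astype(str).str.strip('"')
    raw.columns = raw.columns.astype(str).str.strip('"')
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionFormatError(f"{path}: empty data block")

    def _cell(v: str) -> float:
        s = v.strip().strip('"')
        if s in MISSING_TOKENS:
            return np.nan
        return float(s)

    out = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        col_vals = raw.iloc[:, j].to_numpy()
        for i, v in enumerate(col_vals):
            try:
                out[i, j] = _cell(v)
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}: non-numeric value {v!r} at gene "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
    m = pd.DataFrame(out, index=raw.index.rename("ID"), columns=raw.columns)
    return validate_expression_matrix(m)


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes × samples expression matrix.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"tsv"`` — plain tab-separated text, header row of sample ids,
        first column gene ids.  ``"series_matrix"`` — the GEO series-matrix
        text dialect: lines starting with ``!`` are metadata and are
        ignored; the data block sits between the standard table markers;
        identifiers may be quoted.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "tsv":
        table = [ln for ln in lines if ln.strip()]
    elif dialect == "series_matrix":
        in_block = False
        table = []
        for ln in lines:
            stripped = ln.strip()
            if stripped.lower() == _SM_TABLE_BEGIN:
                in_block = True
                continue
            if stripped.lower() == _SM_TABLE_END:
                in_block = False
                continue
            if stripped.startswith("!"):
                continue
            if in_block and stripped:
                table.append(ln)
        if not table:
            # tolerate marker-less files: fall back to all non-metadata lines
            table = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("!")]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'series_matrix'")
    return _parse_table(table, str(path))


def write_expression_matrix(m: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV with an ``ID`` header column; missing → ``NA``."""
    validate_expression_matrix(m)
    out = m.copy()
    out.index.name = "ID"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (TSV) and derive the comparison group.

    Expected columns: ``sample_id``, ``class_label``, ``tissue``,
    ``dataset_id``.  The derived ``group`` column is CSP for control
    spleen, SMZL for SMZL, and TBCL for every other B-cell lymphoma
    subtype.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "class_label", "tissue", "dataset_id"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise AnnotationError(f"{path}: duplicate sample_id {dup!r}")
    ann["group"] = ann["class_label"].map(group_for_class)
    return ann


def write_sample_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def merge_datasets(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge several cohorts into one matrix for concurrent analysis.

    Genes are restricted to the intersection across inputs (keeping the
    first input's gene order); sample columns are concatenated in input
    order.  Sample ids must be globally unique.
    """
    if len(matrices) == 0:
        raise ValueError("merge_datasets requires at least one matrix")
    for m in matrices:
        validate_expression_matrix(m)
    if len(matrices) == 1:
        return matrices[0]

    shared = matrices[0].index
    for m in matrices[1:]:
        shared = shared[shared.isin(m.index)]
    if len(shared) == 0:
        raise ExpressionFormatError("empty gene intersection across datasets")

    seen: set[str] = set()
    for m in matrices:
        for s in m.columns:
            if s in seen:
                raise ExpressionFormatError(f"duplicate sample id across datasets: {s!r}")
            seen.add(s)

    merged = pd.concat([m.loc[shared] for m in matrices], axis=1)
    return validate_expression_matrix(merged)
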