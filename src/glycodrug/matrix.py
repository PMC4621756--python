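"""In-memory containers and TSV input/output.

Two pandas DataFrame orientations are used throughout:

* **count matrix** — rows are protein/feature accessions, columns are cell
  lines, values are non-negative spectral counts (reals; integers after
  simulation, possibly fractional after instrument rescaling);
* **expression matrix** — rows are cell lines, columns are features, values
  are log10(count + 1), the orientation regression code expects.

Functions here validate those conventions and read/write plain TSV with a
header row of cell-line names and the feature accession in the first column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FEATURE_COL = "feature_id"


class MatrixValidationError(ValueError):
    """Raised when a matrix violates the container conventions."""


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a features x cell-lines count matrix; returns it unchanged."""
    if counts.index.has_duplicates:
        raise MatrixValidationError("duplicate feature identifiers")
    if counts.columns.has_duplicates:
        raise MatrixValidationError("duplicate cell-line identifiers")
    values = counts.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise MatrixValidationError("counts must be finite")
    if np.any(values < 0):
        raise MatrixValidationError("counts must be non-negative")
    return counts


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check a cell-lines x features expression matrix; returns it unchanged."""
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise MatrixValidationError("duplicate identifiers")
    if not np.all(np.isfinite(expr.to_numpy(dtype=float))):
        raise MatrixValidationError("expression values must be finite")
    return expr


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_counts(df)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    validate_counts(counts)
    out = counts.copy()
    out.index.name = FEATURE_COL
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_expression(df)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    out = expr.copy()
    out.index.name = "cell_line"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_response_tsv(path) -> pd.DataFrame:
    """Drug-response table: rows cell lines, one column per drug (-log10 GI50)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_response_tsv(responses: pd.DataFrame, path) -> None:
    out = responses.copy()
    out.index.name = "cell_line"
    out.to_csv(path, sep="\t", float_format="%.10g")
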