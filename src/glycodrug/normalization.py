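"""Two-instrument merging and log-expression normalization.

The analysis-ready matrix is produced in the order the study design fixes:

1. fit a quantile-quantile line between the two instruments' pooled counts
   over shared cell lines and map the target instrument onto the reference
   scale (center + dispersion matching);
2. cell lines measured on the reference instrument are kept from it; cell
   lines with target-only data are rescaled by the ratio of Euclidean norms
   of the household-protein counts and appended;
3. features with a total count below a threshold across all cell lines are
   dropped;
4. values become log10(count + 1), transposed to cell lines x features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import validate_counts, validate_expression


class NormalizationError(ValueError):
    """Degenerate input to a normalization step."""


@dataclass(frozen=True)
class QQLine:
    """Least-squares line through matched empirical quantiles.

    Applying ``slope * x + intercept`` to a target-scale value maps it onto
    the reference scale.
    """

    slope: float
    intercept: float
    n_quantiles: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise NormalizationError("degenerate Q-Q line: slope is zero")


def fit_qq_line(reference, target, n_quantiles: int = 99) -> QQLine:
    """Fit reference-quantiles ~ target-quantiles by ordinary least squares.

    Quantiles at probabilities k/(n_quantiles+1), k=1..n_quantiles, of each
    pooled vector are matched; the regression uses the target quantiles as
    predictor so the line maps target values onto the reference scale.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if reference.size == 0 or target.size == 0:
        raise NormalizationError("empty input vector")
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be positive")

    probs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    q_ref = np.quantile(reference, probs)
    q_tgt = np.quantile(target, probs)
    if np.ptp(q_tgt) == 0:
        raise NormalizationError("constant target vector: Q-Q slope undefined")

    slope, intercept = np.polyfit(q_tgt, q_ref, 1)
    return QQLine(slope=float(slope), intercept=float(intercept), n_quantiles=n_quantiles)


def apply_qq_transform(matrix: pd.DataFrame, line: QQLine) -> pd.DataFrame:
    """Map every count through the fitted line, clipping negatives to zero."""
    validate_counts(matrix)
    out = np.clip(line.slope * matrix.to_numpy(dtype=float) + line.intercept, 0.0, None)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def coefficient_of_variation(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature sample CV (sd/mean, ddof=1) across cell lines."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    return pd.Series(cv, index=matrix.index)


def select_household_proteins(matrix: pd.DataFrame, k: int) -> list[str]:
    """The k features with the smallest CV across cell lines.

    Features with zero mean are excluded from candidacy; ties are broken by
    lexicographic feature id.
    """
    validate_counts(matrix)
    if k < 1:
        raise ValueError("k must be positive")
    cv = coefficient_of_variation(matrix)
    candidates = cv[np.isfinite(cv)]
    if len(candidates) < k:
        raise NormalizationError(f"only {len(candidates)} features with positive mean, need {k}")
    order = sorted(candidates.items(), key=lambda item: (item[1], item[0]))
    return [fid for fid, _ in order[:k]]


def household_norm(matrix: pd.DataFrame, household_ids) -> float:
    """Euclidean length of the concatenated household-protein counts."""
    missing = [h for h in household_ids if h not in matrix.index]
    if missing:
        raise NormalizationError(f"household proteins absent: {missing}")
    return float(np.linalg.norm(matrix.loc[list(household_ids)].to_numpy(dtype=float)))


def household_normalize(
    matrix: pd.DataFrame, household_ids, reference_length: float
) -> pd.DataFrame:
    """Rescale all counts so the household block's Euclidean norm equals
    ``reference_length``."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    length = household_norm(matrix, household_ids)
    if length == 0:
        raise NormalizationError("household-protein counts have zero Euclidean length")
    factor = reference_length / length
    return pd.DataFrame(
        matrix.to_numpy(dtype=float) * factor, index=matrix.index, columns=matrix.columns
    )


def filter_low_counts(matrix: pd.DataFrame, min_total: float = 100.0) -> pd.DataFrame:
    """Keep features whose total count across cell lines is >= min_total.

    "Fewer than min_total" features are dropped; the boundary (row sum equal
    to min_total) is kept.  Feature order is preserved.
    """
    validate_counts(matrix)
    keep = matrix.sum(axis=1).to_numpy(dtype=float) >= min_total
    out = matrix.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("all features dropped by the count filter", stacklevel=2)
    return out


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10(count + 1), transposed to cell lines x features."""
    validate_counts(matrix)
    values = np.log10(matrix.to_numpy(dtype=float) + 1.0)
    return validate_expression(pd.DataFrame(values.T, index=matrix.columns, columns=matrix.index))


@dataclass
class MergeDiagnostics:
    qq_line: QQLine
    household_ids: list[str]
    household_factor: float
    qq_residual_rms: float


def merge_instruments(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    target_only_cell_lines,
    household_k: int = 7,
    n_quantiles: int = 99,
    return_diagnostics: bool = False,
):
    """Combine two instruments' count matrices into one.

    Cell lines present on the reference instrument are taken from it; the
    Q-Q line fitted on the pooled shared-cell-line counts serves as a
    cross-check that the target maps affinely onto the reference scale (its
    residual RMS is reported in the diagnostics).  Target-only cell lines
    are rescaled by the ratio of household-protein Euclidean norms computed
    over the shared cell lines, then appended.
    """
    validate_counts(reference)
    validate_counts(target)
    target_only = [str(c) for c in target_only_cell_lines]
    missing_cols = [c for c in target_only if c not in target.columns]
    if missing_cols:
        raise NormalizationError(f"target-only cell lines absent from target: {missing_cols}")

    common_features = [f for f in reference.index if f in set(target.index)]
    if not common_features:
        raise NormalizationError("instruments share no features")
    shared_cells = [c for c in target.columns if c in set(reference.columns)]

    diagnostics = None
    if shared_cells:
        ref_block = reference.loc[common_features, shared_cells]
        tgt_block = target.loc[common_features, shared_cells]
        line = fit_qq_line(
            ref_block.to_numpy(dtype=float).ravel(),
            tgt_block.to_numpy(dtype=float).ravel(),
            n_quantiles=n_quantiles,
        )
        mapped = apply_qq_transform(tgt_block, line)
        resid = mapped.to_numpy(dtype=float) - ref_block.to_numpy(dtype=float)
        qq_rms = float(np.sqrt(np.mean(resid**2)))
    else:
        line = QQLine(slope=1.0, intercept=0.0, n_quantiles=n_quantiles)
        qq_rms = float("nan")

    merged = reference.copy()
    if target_only:
        household_ids = select_household_proteins(reference, household_k)
        absent = [h for h in household_ids if h not in target.index]
        if absent:
            raise NormalizationError(f"household proteins absent from target: {absent}")
        if shared_cells:
            # norms over the same cell lines are directly comparable
            ref_len = household_norm(reference[shared_cells], household_ids)
            tgt_len = household_norm(target[shared_cells], household_ids)
        else:
            # fall back to per-entry RMS so differing column counts cancel
            ref_len = household_norm(reference, household_ids) / np.sqrt(reference.shape[1])
            tgt_len = household_norm(target[target_only], household_ids) / np.sqrt(len(target_only))
        if tgt_len == 0:
            raise NormalizationError("household-protein counts have zero Euclidean length")
        factor = ref_len / tgt_len
        appended = target.loc[common_features, target_only] * factor
        merged = pd.concat([merged.loc[common_features], appended], axis=1)
        diagnostics = MergeDiagnostics(line, household_ids, float(factor), qq_rms)
    else:
        diagnostics = MergeDiagnostics(line, [], 1.0, qq_rms)

    if merged.columns.has_duplicates:
        raise NormalizationError("a cell line appears in both reference and target-only sets")
    validate_counts(merged)
    if return_diagnostics:
        return merged, diagnostics
    return merged


def normalize_pipeline(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    target_only_cell_lines,
    household_k: int = 7,
    min_total: float = 100.0,
    n_quantiles: int = 99,
) -> pd.DataFrame:
    """merge -> count filter -> log10(x+1), returning cell lines x features."""
    merged = merge_instruments(
        reference, target, target_only_cell_lines, household_k=household_k, n_quantiles=n_quantiles
    )
    return log_transform(filter_low_counts(merged, min_total=min_total))
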