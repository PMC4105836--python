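"""Detection-flag filtering and quantile normalization.

Mirrors the GeneSpring-style preprocessing of a pooled six-array design:
keep genes detected ("flagged Present") on at least ``min_flagged_arrays``
of the arrays, then force every array onto the common distribution of
mean order statistics.  Normalization operates on log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class FilterRule:
    """Keep genes detected on at least ``min_flagged_arrays`` arrays."""

    min_flagged_arrays: int = 2
    total_arrays: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.min_flagged_arrays <= self.total_arrays):
            raise ValueError(
                f"min_flagged_arrays must be in [0, {self.total_arrays}], "
                f"got {self.min_flagged_arrays}"
            )


def filter_by_flags(matrix: ExpressionMatrix, rule: FilterRule | None = None) -> ExpressionMatrix:
    """Retain exactly the genes with >= ``min_flagged_arrays`` detections.

    Gene order is preserved.  Raises if the matrix carries no flags.
    """
    if matrix.flags is None:
        raise ValueError("filter_by_flags requires detection flags")
    rule = rule or FilterRule(total_arrays=len(matrix.array_ids))
    n_detected = matrix.flags.to_numpy().sum(axis=1)
    keep = n_detected >= rule.min_flagged_arrays
    return ExpressionMatrix(
        values=matrix.values.loc[keep],
        flags=matrix.flags.loc[keep],
        design=matrix.design,
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every array onto the across-array mean of order statistics.

    After the operation each array's sorted values equal the mean sorted
    profile; ties within an array receive the mean of the normalized
    values they span, which makes the operation deterministic and
    idempotent.  Gene and array order are preserved.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_arrays = values.shape
    if n_arrays < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    if not np.isfinite(values).all():
        raise ValueError("quantile normalization requires finite values")
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_arrays):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = target
        # average assigned values over ties in the input column
        tied = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        flags=matrix.flags,
        design=matrix.design,
    )


def preprocess(
    matrix: ExpressionMatrix, min_flagged_arrays: int = 2
) -> ExpressionMatrix:
    """Flag filter followed by quantile normalization."""
    rule = FilterRule(
        min_flagged_arrays=min_flagged_arrays, total_arrays=len(matrix.array_ids)
    )
    return quantile_normalize(filter_by_flags(matrix, rule))
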