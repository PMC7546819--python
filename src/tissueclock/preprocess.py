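"""Expression preprocessing: quantile normalization and log2 transform.

Normalization is applied to a whole matrix before any model fitting or
cross-validation split, mirroring the usual preprocessing-first pipeline
order; the mild train/validation information sharing this implies is a
property of that pipeline, not corrected here.
"""

from __future__ import annotations

import numpy as np

from .datamodel import LOG2, RAW, ExpressionMatrix, TissueClockError, ValidationError


class DomainError(TissueClockError):
    """A value is outside the mathematical domain of an operation."""


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto a common reference distribution.

    The reference is the vector of row means of the column-sorted matrix.
    Each column's values are replaced by the reference values at their
    within-column ranks; tied values receive the mean of the reference
    values at their tied ranks, so the operation is permutation-equivariant
    and idempotent.
    """
    if matrix.scale != RAW:
        raise ValidationError("quantile normalization expects a raw-scale matrix")
    if matrix.n_samples < 2:
        raise ValidationError(
            "quantile normalization is undefined for a single sample"
        )
    if matrix.n_genes < 1:
        raise ValidationError("empty matrix")
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the assigned reference values over groups of tied inputs
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / counts)[inverse]
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=out,
        scale=RAW,
        tissue=matrix.tissue,
    )


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return log2(value + pseudocount); marks the matrix as log2-scale.

    The default pseudocount of 1 keeps zero expression at exactly 0 on the
    log scale and makes the transform defined for RPKM-style inputs that
    contain zeros.
    """
    if matrix.scale != RAW:
        raise ValidationError("log2_transform expects a raw-scale matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = matrix.values + pseudocount
    if (shifted <= 0).any():
        g, s = np.argwhere(shifted <= 0)[0]
        raise DomainError(
            f"log2 undefined for gene {matrix.gene_ids[g]!r}, sample "
            f"{matrix.sample_ids[s]!r} (value {matrix.values[g, s]}, "
            f"pseudocount {pseudocount})"
        )
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=np.log2(shifted),
        scale=LOG2,
        tissue=matrix.tissue,
    )
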