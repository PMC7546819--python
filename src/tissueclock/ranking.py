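"""Gene preselection by Pearson correlation with donor age.

Genes are ranked best-first by |r| so that genes whose expression falls
with age compete on equal terms with genes whose expression rises (the
fitted models contain coefficients of both signs). A ``key="signed"``
option ranks by r itself instead. Constant (zero-variance) genes have an
undefined correlation and are excluded from the ranking, with their count
recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import LOG2, ExpressionMatrix, ValidationError


@dataclass
class GeneRanking:
    """Ordered gene ranking: ``gene_ids[i]`` has correlation ``r[i]``."""

    gene_ids: np.ndarray
    r: np.ndarray
    n_samples_used: int
    n_degenerate: int = 0

    def __len__(self) -> int:
        return len(self.gene_ids)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Returns NaN (the degenerate flag) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"length mismatch: {x.shape} vs {y.shape} (need equal 1-D vectors)"
        )
    if len(x) < 3:
        raise ValidationError("correlation requires at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlation inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def correlations_with(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlation of every row of ``X`` (genes x samples) with ``y``.

    Vectorized helper used both here and in fold-internal reranking.
    Zero-variance rows get NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    sx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[(sx == 0.0) | (sy == 0.0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def rank_genes(matrix: ExpressionMatrix, ages, key: str = "abs") -> GeneRanking:
    """Rank genes of a log2 matrix by correlation with sample ages.

    ``key="abs"`` (default) orders by |r| descending; ``key="signed"``
    orders by r descending. Ties are broken lexicographically by gene id
    for determinism. Degenerate genes are dropped and counted.
    """
    if matrix.scale != LOG2:
        raise ValidationError("rank_genes expects a log2-scale matrix")
    ages = np.asarray(ages, dtype=float)
    if len(ages) != matrix.n_samples:
        raise ValidationError("ages not aligned with matrix columns")
    if matrix.n_samples < 3:
        raise ValidationError("ranking requires at least 3 samples")
    if key not in ("abs", "signed"):
        raise ValueError(f"unknown ranking key {key!r}")
    r = correlations_with(matrix.values, ages)
    ok = ~np.isnan(r)
    score = np.abs(r[ok]) if key == "abs" else r[ok]
    genes = matrix.gene_ids[ok]
    # lexsort: last key is primary (score desc), gene id breaks ties
    order = np.lexsort((genes.astype(str), -score))
    return GeneRanking(
        gene_ids=genes[order],
        r=r[ok][order],
        n_samples_used=matrix.n_samples,
        n_degenerate=int((~ok).sum()),
    )


def top_n(ranking: GeneRanking, n: int) -> list:
    """First min(n, available) gene ids of the ranking, warning if short."""
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if n > len(ranking):
        warnings.warn(
            f"requested top {n} genes but ranking has only {len(ranking)}",
            stacklevel=2,
        )
    return list(ranking.gene_ids[:n])


#: Feature-count grid used throughout: top 50 ... 6400 genes by powers of two
#: (with the 600 and 800 intermediates).
DEFAULT_N_GRID = (50, 100, 200, 400, 600, 800, 1600, 3200, 6400)
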