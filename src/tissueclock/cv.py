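"""Model selection: repeated 10-fold cross-validation with fold-internal
gene reranking, grid-searched over (N, alpha, lambda).

For every repeat the samples are re-partitioned into k folds; within each
fold the gene ranking is recomputed on the k-1 training folds only, the
top-N genes are selected, the elastic net is fitted on the training folds
and evaluated on the held-out fold. Validation RMSE and PCC are averaged
over all repeats x folds, and the (N, alpha, lambda) cell with the lowest
mean validation RMSE wins. Keeping the ranking inside the fold is what
prevents feature selection from leaking validation information into the
score.

The default of 100 repeats re-randomizes the fold split each time
(repeated CV); averaging over the repeats damps the variance that a single
random split would contribute. Sampling donors with replacement instead is
available via ``resample="bootstrap"``.

A dataset holds one or more feature *blocks* (one per tissue); each block
carries its own feature budget, so a paired-tissue dataset is just a
two-block dataset with budgets (N_A, N_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import LOG2, ExpressionMatrix, SampleTable, ValidationError
from .model import AgeModel, fit_elastic_net, pcc, predict_ages_matrix, rmse
from .ranking import DEFAULT_N_GRID, correlations_with

Budget = Union[int, Tuple[int, ...]]


@dataclass
class TissueBlock:
    """All candidate genes of one tissue, samples x genes."""

    tissue: str
    gene_ids: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.gene_ids):
            raise ValidationError("block X columns must align with gene_ids")


@dataclass
class CVDataset:
    """Aligned feature blocks plus the regression target (age in years).

    Rows are the unit of CV splitting: samples for a single tissue,
    donors for a paired-tissue dataset. Rows are kept in a canonical
    (sorted-unit-id) order so results do not depend on input order.
    """

    blocks: List[TissueBlock]
    ages: np.ndarray
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        n = len(self.ages)
        if len(self.unit_ids) != n:
            raise ValidationError("unit_ids not aligned with ages")
        for b in self.blocks:
            if b.X.shape[0] != n:
                raise ValidationError(f"block {b.tissue!r} rows not aligned with ages")
        order = np.argsort(self.unit_ids.astype(str), kind="stable")
        self.unit_ids = self.unit_ids[order]
        self.ages = self.ages[order]
        self.blocks = [
            TissueBlock(b.tissue, b.gene_ids, b.X[order]) for b in self.blocks
        ]

    @property
    def n(self) -> int:
        return len(self.ages)


def make_single_dataset(matrix: ExpressionMatrix, table: SampleTable) -> CVDataset:
    """Single-tissue dataset from an aligned log2 matrix and sample table."""
    if matrix.scale != LOG2:
        raise ValidationError("dataset requires a log2-scale matrix")
    ages = table.ages_for(matrix.sample_ids)
    block = TissueBlock(
        tissue=matrix.tissue or "", gene_ids=matrix.gene_ids, X=matrix.values.T
    )
    return CVDataset(blocks=[block], ages=ages, unit_ids=matrix.sample_ids)


@dataclass
class ParamGrid:
    """Joint hyperparameter lattice.

    Defaults follow the reference procedure: N over 50..6400, alpha from 0
    to 1 in steps of 0.01, lambda over powers of two from 2**-10 to 2**10.
    ``n_grid`` entries may be tuples for multi-block (paired) datasets.
    """

    n_grid: Sequence[Budget] = DEFAULT_N_GRID
    alpha_grid: Sequence[float] = field(
        default_factory=lambda: [round(a, 2) for a in np.arange(0.0, 1.005, 0.01)]
    )
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: [float(2.0**e) for e in range(-10, 11)]
    )

    def __post_init__(self) -> None:
        if not self.n_grid or not self.alpha_grid or not self.lambda_grid:
            raise ValidationError("all grids must be non-empty")
        for lam in self.lambda_grid:
            if lam <= 0:
                raise ValidationError(f"lambda grid values must be > 0, got {lam}")
        for a in self.alpha_grid:
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"alpha grid values must be in [0, 1], got {a}")


@dataclass
class CVResult:
    """Grid-search outcome: the full score table, the winning cell and the
    final model refit on all data at the winning parameters."""

    table: pd.DataFrame
    chosen: dict
    final_model: AgeModel
    k: int
    repeats: int
    base_seed: int


def kfold_split(n_samples: int, k: int, seed: int) -> List[np.ndarray]:
    """Random balanced partition of range(n_samples) into k folds.

    Fold sizes differ by at most one; deterministic for a given seed.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n_samples < k:
        raise ValidationError(f"cannot split {n_samples} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _normalize_budgets(blocks: List[TissueBlock], budgets: Budget) -> Tuple[int, ...]:
    if isinstance(budgets, (int, np.integer)):
        budgets = (int(budgets),) * len(blocks)
    budgets = tuple(int(b) for b in budgets)
    if len(budgets) != len(blocks):
        raise ValidationError(
            f"{len(budgets)} budgets for {len(blocks)} feature blocks"
        )
    if all(b <= 0 for b in budgets):
        raise ValidationError("at least one feature budget must be positive")
    return budgets


def _top_columns(
    X_train: np.ndarray, gene_ids: np.ndarray, ages_train: np.ndarray,
    n: int, key: str
) -> np.ndarray:
    """Column indices of the top-n genes ranked on training rows only."""
    r = correlations_with(X_train.T, ages_train)
    score = np.abs(r) if key == "abs" else r
    score = np.where(np.isnan(r), -np.inf, score)
    order = np.lexsort((gene_ids.astype(str), -score))
    order = order[np.isfinite(score[order])]
    return order[:n]


def cv_evaluate(
    dataset: CVDataset,
    budgets: Budget,
    alpha: float,
    lam: float,
    k: int = 10,
    repeats: int = 100,
    base_seed: int = 0,
    rank_key: str = "abs",
    resample: str = "reshuffle",
) -> Tuple[float, float]:
    """Mean validation (RMSE, PCC) of one (N, alpha, lambda) cell.

    Repeat r uses seed ``base_seed + r``. ``resample="reshuffle"`` redraws
    the k-fold partition each repeat; ``"bootstrap"`` first resamples the
    units with replacement, then splits.
    """
    budgets = _normalize_budgets(dataset.blocks, budgets)
    if resample not in ("reshuffle", "bootstrap"):
        raise ValueError(f"unknown resample mode {resample!r}")
    rmses, pccs = [], []
    for rep in range(repeats):
        seed = base_seed + rep
        if resample == "bootstrap":
            rng = np.random.default_rng(seed)
            rows = np.sort(rng.integers(0, dataset.n, dataset.n))
        else:
            rows = np.arange(dataset.n)
        folds = kfold_split(len(rows), k, seed)
        for fold in folds:
            val = rows[fold]
            train = rows[np.setdiff1d(np.arange(len(rows)), fold)]
            if len(train) < 3:
                raise ValidationError(
                    f"fold leaves only {len(train)} training samples"
                )
            y_tr, y_va = dataset.ages[train], dataset.ages[val]
            Xtr_parts, Xva_parts = [], []
            for block, n_feat in zip(dataset.blocks, budgets):
                if n_feat <= 0:
                    continue
                cols = _top_columns(
                    block.X[train], block.gene_ids, y_tr, n_feat, rank_key
                )
                Xtr_parts.append(block.X[np.ix_(train, cols)])
                Xva_parts.append(block.X[np.ix_(val, cols)])
            Xtr = np.hstack(Xtr_parts)
            Xva = np.hstack(Xva_parts)
            model = fit_elastic_net(Xtr, y_tr, alpha=alpha, lam=lam)
            pred = predict_ages_matrix(model, Xva)
            rmses.append(rmse(y_va, pred))
            if len(val) >= 3:
                pccs.append(pcc(y_va, pred))
    valid_pccs = np.asarray(pccs)[~np.isnan(pccs)] if pccs else np.array([])
    mean_pcc = float(valid_pccs.mean()) if valid_pccs.size else float("nan")
    return float(np.mean(rmses)), mean_pcc


def refit_full(
    dataset: CVDataset,
    budgets: Budget,
    alpha: float,
    lam: float,
    rank_key: str = "abs",
) -> AgeModel:
    """Refit at chosen parameters on all rows, ranking genes fold-free."""
    budgets = _normalize_budgets(dataset.blocks, budgets)
    parts, genes, tissues = [], [], []
    for block, n_feat in zip(dataset.blocks, budgets):
        if n_feat <= 0:
            continue
        cols = _top_columns(block.X, block.gene_ids, dataset.ages, n_feat, rank_key)
        parts.append(block.X[:, cols])
        genes.extend(block.gene_ids[cols])
        tissues.extend([block.tissue] * len(cols))
    X = np.hstack(parts)
    model = fit_elastic_net(
        X, dataset.ages, alpha=alpha, lam=lam, gene_ids=genes, tissues=tissues
    )
    model.meta.update({"budgets": budgets, "n_samples": dataset.n})
    return model


def _budget_total(b: Budget) -> int:
    return int(b) if isinstance(b, (int, np.integer)) else int(sum(b))


def grid_search(
    dataset: CVDataset,
    grid: Optional[ParamGrid] = None,
    k: int = 10,
    repeats: int = 100,
    base_seed: int = 0,
    strategy: str = "joint",
    rank_key: str = "abs",
    resample: str = "reshuffle",
) -> CVResult:
    """Search (N, alpha, lambda) for the lowest mean validation RMSE.

    ``strategy="joint"`` evaluates the full lattice (the reference
    behavior); ``"two_stage"`` first scans a coarse alpha subgrid with the
    full N and lambda grids, then refines alpha within +/-0.12 of the best
    coarse value. Equal-RMSE ties go to the smallest N, then the largest
    lambda, then the largest alpha (the sparsest, most regularized model).
    The final model is refit on all rows at the winning cell.
    """
    grid = grid or ParamGrid()
    if strategy not in ("joint", "two_stage"):
        raise ValueError(f"unknown strategy {strategy!r}")

    cache: dict = {}

    def evaluate(cells) -> None:
        for n, a, lam in cells:
            key = (n, round(float(a), 10), float(lam))
            if key not in cache:
                cache[key] = cv_evaluate(
                    dataset, n, a, lam, k=k, repeats=repeats,
                    base_seed=base_seed, rank_key=rank_key, resample=resample,
                )

    def best_cell():
        def sort_key(item):
            (n, a, lam), (mean_rmse, _) = item
            return (mean_rmse, _budget_total(n), -lam, -a)
        return min(cache.items(), key=sort_key)

    all_alphas = sorted(set(float(a) for a in grid.alpha_grid))
    if strategy == "joint" or len(all_alphas) <= 5:
        stage_alphas = all_alphas
    else:
        idx = np.unique(np.linspace(0, len(all_alphas) - 1, 5).round().astype(int))
        stage_alphas = [all_alphas[i] for i in idx]
    evaluate(
        (n, a, lam)
        for n in grid.n_grid
        for a in stage_alphas
        for lam in grid.lambda_grid
    )
    if strategy == "two_stage" and len(all_alphas) > 5:
        (_, best_alpha, _), _ = best_cell()
        refine = [a for a in all_alphas if abs(a - best_alpha) <= 0.12]
        evaluate(
            (n, a, lam)
            for n in grid.n_grid
            for a in refine
            for lam in grid.lambda_grid
        )

    rows = [
        {"n": n if isinstance(n, (int, np.integer)) else tuple(n),
         "alpha": a, "lambda": lam, "mean_rmse": r, "mean_pcc": p}
        for (n, a, lam), (r, p) in cache.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["mean_rmse", "alpha", "lambda"], kind="stable"
    ).reset_index(drop=True)
    (n_best, a_best, lam_best), (rmse_best, pcc_best) = best_cell()
    final = refit_full(dataset, n_best, a_best, lam_best, rank_key=rank_key)
    final.meta.update({"mean_rmse": rmse_best, "mean_pcc": pcc_best})
    chosen = {
        "n": n_best, "alpha": a_best, "lambda": lam_best,
        "mean_rmse": rmse_best, "mean_pcc": pcc_best,
    }
    return CVResult(
        table=table, chosen=chosen, final_model=final,
        k=k, repeats=repeats, base_seed=base_seed,
    )
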