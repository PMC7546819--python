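"""Two-tissue integration over shared donors.

Combining tissues can only use donors sampled in both; the reference
procedure requires at least 70 shared donors per pair. Each tissue
contributes its own top-ranked genes (budgets N_A, N_B), tagged by tissue
of origin so the same gene measured in both tissues stays two distinct
features. By default genes are ranked on the shared-donor subset only —
the donors that actually enter the model — rather than on each tissue's
full cohort; ``rank_on_shared=False`` restores full-cohort ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    LOG2,
    EmptyCohortError,
    ExpressionMatrix,
    SampleTable,
    ValidationError,
)
from .cv import CVDataset, TissueBlock
from .ranking import rank_genes, top_n

#: Minimum shared-donor count for a tissue pair to be modelled.
MIN_OVERLAP = 70


@dataclass
class PairedDataset:
    """Donor-aligned two-tissue feature matrix.

    One row per shared donor (sorted donor id); ``features`` tags every
    column with (gene, tissue). ``budgets`` records the requested
    per-tissue feature counts.
    """

    donor_ids: np.ndarray
    ages: np.ndarray
    X: np.ndarray
    features: pd.DataFrame
    budgets: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.donor_ids), len(self.features)):
            raise ValidationError("paired X shape must be donors x features")
        tissues = set(self.features["tissue"])
        if len(tissues) > 2:
            raise ValidationError(f"more than two tissue tags: {sorted(tissues)}")


def donor_overlap(table_a: SampleTable, table_b: SampleTable) -> Set[str]:
    """Donors with a sample in both tissues (exact set intersection)."""
    return table_a.donor_ids & table_b.donor_ids


def enumerate_pairs(
    tables: Dict[str, SampleTable], min_overlap: int = MIN_OVERLAP
) -> List[Tuple[str, str, int]]:
    """All unordered tissue pairs with donor overlap >= min_overlap,
    sorted by descending overlap then lexicographic tissue names."""
    pairs = []
    for a, b in combinations(sorted(tables), 2):
        n = len(donor_overlap(tables[a], tables[b]))
        if n >= min_overlap:
            pairs.append((a, b, n))
    return sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))


def _restrict_to_donors(
    matrix: ExpressionMatrix, table: SampleTable, donors: List[str]
) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Matrix columns for the given donors (in donor order) plus their ages."""
    df = table.df.set_index("donor_id")
    sample_ids = [df.loc[d, "sample_id"] for d in donors]
    ages = np.asarray([df.loc[d, "age"] for d in donors], dtype=float)
    return matrix.subset_samples(sample_ids), ages


def paired_cv_dataset(
    mat_a: ExpressionMatrix,
    table_a: SampleTable,
    mat_b: ExpressionMatrix,
    table_b: SampleTable,
) -> CVDataset:
    """Two-block CV dataset over shared donors, all candidate genes kept.

    Feature budgets are applied later, fold-internally, by the CV engine;
    the unit of splitting is the donor.
    """
    for m in (mat_a, mat_b):
        if m.scale != LOG2:
            raise ValidationError("paired datasets require log2-scale matrices")
    shared = sorted(
        donor_overlap(table_a, table_b)
        & _donors_in_matrix(mat_a, table_a)
        & _donors_in_matrix(mat_b, table_b)
    )
    if not shared:
        raise EmptyCohortError("no shared donors between the two tissues")
    sub_a, ages = _restrict_to_donors(mat_a, table_a, shared)
    sub_b, ages_b = _restrict_to_donors(mat_b, table_b, shared)
    if not np.array_equal(ages, ages_b):
        raise ValidationError("inconsistent ages for shared donors across tissues")
    blocks = [
        TissueBlock(tissue=mat_a.tissue or "A", gene_ids=sub_a.gene_ids, X=sub_a.values.T),
        TissueBlock(tissue=mat_b.tissue or "B", gene_ids=sub_b.gene_ids, X=sub_b.values.T),
    ]
    return CVDataset(
        blocks=blocks, ages=ages, unit_ids=np.asarray(shared, dtype=object)
    )


def _donors_in_matrix(matrix: ExpressionMatrix, table: SampleTable) -> Set[str]:
    present = set(matrix.sample_ids)
    return set(
        table.df.loc[table.df["sample_id"].isin(present), "donor_id"]
    )


def build_paired_dataset(
    mat_a: ExpressionMatrix,
    table_a: SampleTable,
    mat_b: ExpressionMatrix,
    table_b: SampleTable,
    n_a: int,
    n_b: int,
    rank_on_shared: bool = True,
) -> PairedDataset:
    """Concatenate each tissue's top-N genes into one donor-level matrix.

    Ranking is computed on the shared donors (default) or on each
    tissue's full cohort. Returns N_A + N_B tagged features, or fewer
    (with a warning) when a tissue has fewer rankable genes than its
    budget.
    """
    if n_a < 0 or n_b < 0:
        raise ValidationError("feature budgets must be non-negative")
    if n_a == 0 and n_b == 0:
        raise ValidationError("at least one tissue needs a positive feature budget")
    dataset = paired_cv_dataset(mat_a, table_a, mat_b, table_b)
    donors = dataset.unit_ids
    ages = dataset.ages
    parts, feat_rows = [], []
    for block, budget, full_mat, full_table in (
        (dataset.blocks[0], n_a, mat_a, table_a),
        (dataset.blocks[1], n_b, mat_b, table_b),
    ):
        if budget == 0:
            continue
        if rank_on_shared:
            shared_mat = ExpressionMatrix(
                block.gene_ids, donors, block.X.T, scale=LOG2, tissue=block.tissue
            )
            ranking = rank_genes(shared_mat, ages)
        else:
            full_ages = full_table.ages_for(full_mat.sample_ids)
            ranking = rank_genes(full_mat, full_ages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = top_n(ranking, budget)
        if len(chosen) < budget:
            warnings.warn(
                f"tissue {block.tissue!r}: only {len(chosen)} rankable genes "
                f"for a budget of {budget}", stacklevel=2,
            )
        gene_index = {g: i for i, g in enumerate(block.gene_ids)}
        cols = [gene_index[g] for g in chosen]
        parts.append(block.X[:, cols])
        feat_rows.extend({"gene": g, "tissue": block.tissue} for g in chosen)
    return PairedDataset(
        donor_ids=donors,
        ages=ages,
        X=np.hstack(parts),
        features=pd.DataFrame(feat_rows),
        budgets=(n_a, n_b),
    )
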