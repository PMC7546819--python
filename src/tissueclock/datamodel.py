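"""Core containers for expression data and sample metadata.

The two central objects are :class:`ExpressionMatrix` (genes x samples,
either raw or log2 scale) and :class:`SampleTable` (per-sample donor,
tissue, age and sex). A donor may contribute samples to several tissues,
but at most one sample per tissue; that invariant is what later makes a
donor the unit of cross-validation splitting for paired-tissue models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class TissueClockError(Exception):
    """Base class for errors raised by this package."""


class FormatError(TissueClockError):
    """A file does not conform to its declared format."""


class ValidationError(TissueClockError):
    """Data violates a structural invariant (duplicates, NaN, bad ages...)."""


class EmptyCohortError(TissueClockError):
    """A subsetting operation produced no samples."""


RAW = "raw"
LOG2 = "log2"

_SEXES = ("male", "female", "unknown")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``scale`` records whether values are on the raw (non-negative) or the
    log2 scale that the regression model operates on. ``tissue`` is an
    optional label for single-tissue matrices.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    scale: str = RAW
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        ngenes, nsamples = self.values.shape
        if len(self.gene_ids) != ngenes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {ngenes} value rows"
            )
        if len(self.sample_ids) != nsamples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {nsamples} value columns"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Series(ids).value_counts()
                dupes = list(dupes.index[dupes > 1][:5])
                raise ValidationError(f"duplicate {label} ids: {dupes}")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains NaN values")
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.scale == RAW and (self.values < 0).any():
            raise ValidationError("raw-scale expression values must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            sample_ids=np.asarray(list(sample_ids), dtype=object),
            values=self.values[:, cols].copy(),
            scale=self.scale,
            tissue=self.tissue,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            list(self.gene_ids) == list(other.gene_ids)
            and list(self.sample_ids) == list(other.sample_ids)
            and self.scale == other.scale
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SampleTable:
    """Per-sample metadata: donor, tissue, age (years) and sex.

    Backed by a DataFrame with columns sample_id, donor_id, tissue, age,
    sex. sample_id is unique and each (donor_id, tissue) pair occurs at
    most once.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "donor_id", "tissue", "age")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        df["sample_id"] = df["sample_id"].astype(str)
        df["donor_id"] = df["donor_id"].astype(str)
        df["tissue"] = df["tissue"].astype(str).str.strip()
        df["sex"] = (
            df["sex"].astype(str).str.strip().str.lower()
        ).where(lambda s: s.isin(_SEXES), "unknown")
        age = pd.to_numeric(df["age"], errors="coerce")
        if age.isna().any():
            bad = df.loc[age.isna(), "sample_id"].tolist()[:5]
            raise ValidationError(f"non-numeric age for samples {bad}")
        if not np.isfinite(age).all() or (age <= 0).any():
            bad = df.loc[~np.isfinite(age) | (age <= 0), "sample_id"].tolist()[:5]
            raise ValidationError(f"age must be finite and > 0; offending samples {bad}")
        df["age"] = age.astype(float)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
            raise ValidationError(f"duplicate sample ids: {dupes}")
        pair_dupes = df.duplicated(subset=["donor_id", "tissue"])
        if pair_dupes.any():
            bad = df.loc[pair_dupes, ["donor_id", "tissue"]].values.tolist()[:5]
            raise ValidationError(f"duplicate (donor, tissue) pairs: {bad}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tissues(self) -> list:
        return sorted(self.df["tissue"].unique())

    @property
    def donor_ids(self) -> set:
        return set(self.df["donor_id"])

    def for_tissue(self, tissue: str) -> "SampleTable":
        sub = self.df[self.df["tissue"] == tissue.strip()]
        if sub.empty:
            raise EmptyCohortError(f"no samples for tissue {tissue!r}")
        return SampleTable(sub)

    def ages_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.df["sample_id"], self.df["age"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples not in table: {missing[:5]}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=float)
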