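"""Reading and writing expression matrices (GCT 1.2 / TSV) and sample tables.

GCT 1.2 is the tab-delimited format GTEx distributes: a ``#1.2`` version
line, a ``<n_genes>\\t<n_samples>`` dimensions line, then a header row
``Name\\tDescription\\t<sample ids...>`` and one row per gene. The
Description column is carried but ignored by the analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import (
    RAW,
    EmptyCohortError,
    ExpressionMatrix,
    FormatError,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_expression(path: PathLike, format: str = "auto") -> ExpressionMatrix:
    """Read a genes x samples expression matrix from a GCT 1.2 or TSV file.

    ``format`` is "gct", "tsv" or "auto" (sniff: GCT starts with "#1.2").
    Values are taken to be on the raw scale.
    """
    path = Path(path)
    if format == "auto":
        with open(path) as fh:
            first = fh.readline()
        format = "gct" if first.startswith("#1.2") else "tsv"
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown expression format {format!r}")


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version.strip() != "#1.2":
            raise FormatError(
                f"{path}: expected GCT version line '#1.2', got {version!r}"
            )
        dims_line = fh.readline().rstrip("\n")
        parts = dims_line.split("\t")
        try:
            ngenes, nsamples = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise FormatError(
                f"{path}: malformed GCT dimensions line {dims_line!r}"
            ) from None
        df = pd.read_csv(fh, sep="\t", header=0, dtype={0: str, 1: str},
                         float_precision="round_trip")
    if df.shape[1] != nsamples + 2:
        raise ValidationError(
            f"{path}: dimensions line declares {nsamples} samples but header "
            f"has {df.shape[1] - 2} sample columns"
        )
    if df.shape[0] != ngenes:
        raise ValidationError(
            f"{path}: dimensions line declares {ngenes} genes but file has "
            f"{df.shape[0]} data rows"
        )
    gene_ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    sample_ids = np.asarray([str(c) for c in df.columns[2:]], dtype=object)
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=RAW)


def _read_tsv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                     float_precision="round_trip")
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty expression TSV")
    gene_ids = np.asarray([str(g) for g in df.index], dtype=object)
    sample_ids = np.asarray([str(c) for c in df.columns], dtype=object)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=RAW)


def write_expression(
    matrix: ExpressionMatrix, path: PathLike, format: str = "tsv"
) -> None:
    """Write a matrix as GCT 1.2 or plain TSV (UTF-8, '.' decimal)."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)
    )
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    elif format == "gct":
        with open(path, "w", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
            for gid, row in zip(matrix.gene_ids, matrix.values):
                fh.write(str(gid) + "\t" + str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_sample_table(path: PathLike) -> SampleTable:
    """Read a sample-attribute TSV (sample_id, donor_id, tissue, age[, sex])."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = [c for c in SampleTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample table missing columns {missing}")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: PathLike) -> None:
    out = table.df.copy()
    # integer ages print without a trailing .0 so round-trips are byte-stable
    if (out["age"] == out["age"].round()).all():
        out["age"] = out["age"].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def subset_by_tissue(
    matrix: ExpressionMatrix, table: SampleTable, tissue: str
) -> Tuple[ExpressionMatrix, SampleTable]:
    """Restrict matrix and table to one tissue's samples (table order).

    Samples listed in the table but absent from the matrix are dropped with
    a log message; an empty intersection raises :class:`EmptyCohortError`.
    """
    sub = table.for_tissue(tissue)
    in_matrix = set(matrix.sample_ids)
    keep = [s for s in sub.df["sample_id"] if s in in_matrix]
    dropped = [s for s in sub.df["sample_id"] if s not in in_matrix]
    if dropped:
        logger.info(
            "subset_by_tissue(%s): dropping %d samples absent from matrix: %s",
            tissue, len(dropped), dropped[:5],
        )
    if not keep:
        raise EmptyCohortError(
            f"no samples of tissue {tissue!r} are present in the expression matrix"
        )
    out_table = SampleTable(sub.df[sub.df["sample_id"].isin(keep)])
    out_matrix = matrix.subset_samples(keep)
    out_matrix.tissue = tissue.strip()
    return out_matrix, out_table


def summarize_cohort(table: SampleTable) -> pd.DataFrame:
    """Per-tissue cohort summary: sample count, age range/median/mean and
    sex composition, in the layout of the published GTEx V6 cohort table.

    The male:female ratio is reported as NaN when a tissue has no female
    donors (printed as NA), and is rounded to 3 decimals.
    """
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty sample table")
    rows = []
    for tissue, grp in table.df.groupby("tissue", sort=True):
        n_male = int((grp["sex"] == "male").sum())
        n_female = int((grp["sex"] == "female").sum())
        ratio = round(n_male / n_female, 3) if n_female > 0 else np.nan
        rows.append(
            {
                "Tissue": tissue,
                "Number": len(grp),
                "Minimum": grp["age"].min(),
                "Maximum": grp["age"].max(),
                "Median": grp["age"].median(),
                "Mean": grp["age"].mean(),
                "NumMen": n_male,
                "NumWomen": n_female,
                "Proportion": ratio,
            }
        )
    return pd.DataFrame(rows)
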