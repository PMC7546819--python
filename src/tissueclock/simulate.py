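"""Synthetic multi-tissue expression cohorts with known ground truth.

The generator emulates the structure of a GTEx-like cohort: donors aged
20-70, several tissues with partial donor overlap, and a minority of
genes whose log2 expression depends linearly on age. Generative model for
gene g, donor s, tissue t:

    log2 x_gst = mu_g + delta_gt + beta_gt * a_st + eps,   eps ~ N(0, noise_sd^2)

where a_st = (transcriptomic age of donor s in tissue t - midpoint) /
half-range is standardized age, and the transcriptomic age is the
chronological age plus an independent per-donor, per-tissue Gaussian
deviation (``tissue_age_noise_sd``, in years). That deviation models
heterogeneous aging rates across tissues: it is the irreducible error
floor of any single-tissue predictor, while being independent across
tissues, so combining tissues can average part of it away. Raw expression
is 2**(log2 value), so exported matrices are non-negative raw-scale data
that flow through the same preprocessing as real data.

Causal genes are the first ``n_shared_age_genes`` (same slope in every
tissue) followed by per-tissue blocks of ``n_specific_age_genes`` (slope
in one tissue only); all other genes have slope 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import RAW, ExpressionMatrix, SampleTable, ValidationError
from .io import write_expression, write_sample_table


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults describe the reference condition used throughout the test
    suite: 300 donors aged 20-70, two tissues each sampling 80% of
    donors, 2,000 genes of which 50 carry a shared linear age effect
    (slope sd 2 log2-units per standardized age), log-scale residual
    noise sd 0.5, and a 3-year per-tissue transcriptomic-age deviation.
    """

    n_donors: int = 300
    tissues: Sequence[Tuple[str, float]] = (("tissueA", 0.8), ("tissueB", 0.8))
    n_genes: int = 2000
    n_shared_age_genes: int = 50
    n_specific_age_genes: Union[int, Dict[str, int]] = 0
    effect_size_sd: float = 2.0
    effect_size_floor: float = 0.0
    noise_sd: float = 0.5
    tissue_age_noise_sd: float = 3.0
    baseline_log2_mean: float = 5.0
    baseline_mean_sd: float = 2.0
    tissue_offset_sd: float = 0.5
    age_range: Tuple[float, float] = (20.0, 70.0)
    integer_ages: bool = True
    sex_ratio: float = 1.7
    seed: int = 0

    def specific_counts(self) -> Dict[str, int]:
        if isinstance(self.n_specific_age_genes, dict):
            return {label: int(self.n_specific_age_genes.get(label, 0))
                    for label, _ in self.tissues}
        return {label: int(self.n_specific_age_genes) for label, _ in self.tissues}

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ValidationError("need at least 2 donors")
        if self.n_genes < 1:
            raise ValidationError("need at least 1 gene")
        if not self.tissues:
            raise ValidationError("need at least one tissue")
        for label, p in self.tissues:
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"tissue {label!r}: inclusion probability must be in (0, 1]"
                )
        counts = self.specific_counts()
        total_causal = self.n_shared_age_genes + sum(counts.values())
        if self.n_shared_age_genes < 0 or any(c < 0 for c in counts.values()):
            raise ValidationError("causal gene counts must be non-negative")
        if total_causal > self.n_genes:
            raise ValidationError(
                f"{total_causal} causal genes exceed {self.n_genes} total genes"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range minimum must be below maximum")
        if lo <= 0:
            raise ValidationError("ages must be positive")
        for name in ("effect_size_sd", "noise_sd", "tissue_age_noise_sd",
                     "baseline_mean_sd", "tissue_offset_sd", "effect_size_floor"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sex_ratio <= 0:
            raise ValidationError("sex_ratio must be > 0")


@dataclass
class GroundTruth:
    """True generative quantities: per-(gene, tissue) slopes, donor ages and
    the realized per-sample transcriptomic ages (chronological age plus the
    tissue-specific deviation) that the slopes actually act on."""

    slopes: pd.DataFrame  # columns: gene, tissue, beta
    donor_ages: pd.DataFrame  # columns: donor_id, age, sex
    sample_ages: pd.DataFrame  # columns: sample_id, tissue, transcriptomic_age
    config: SimulationConfig

    def causal_genes(self, tissue: str) -> List[str]:
        sub = self.slopes[(self.slopes["tissue"] == tissue) & (self.slopes["beta"] != 0)]
        return list(sub["gene"])


@dataclass
class Cohort:
    matrices: Dict[str, ExpressionMatrix]
    table: SampleTable
    truth: GroundTruth


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a cohort from the generative model; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0

    donor_ids = [f"D{i:04d}" for i in range(config.n_donors)]
    if config.integer_ages:
        ages = rng.integers(int(lo), int(hi) + 1, config.n_donors).astype(float)
    else:
        ages = rng.uniform(lo, hi, config.n_donors)
    p_male = config.sex_ratio / (1.0 + config.sex_ratio)
    sexes = np.where(rng.random(config.n_donors) < p_male, "male", "female")

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    mu = rng.normal(config.baseline_log2_mean, config.baseline_mean_sd, config.n_genes)

    labels = [label for label, _ in config.tissues]
    specific = config.specific_counts()
    # causal layout: shared block first, then one specific block per tissue
    betas: Dict[str, np.ndarray] = {label: np.zeros(config.n_genes) for label in labels}
    shared_raw = rng.normal(0.0, config.effect_size_sd, config.n_shared_age_genes)
    shared_beta = _apply_floor(shared_raw, config.effect_size_floor)
    pos = config.n_shared_age_genes
    for label in labels:
        betas[label][: config.n_shared_age_genes] = shared_beta
        n_spec = specific[label]
        spec_beta = _apply_floor(
            rng.normal(0.0, config.effect_size_sd, n_spec), config.effect_size_floor
        )
        betas[label][pos: pos + n_spec] = spec_beta
        pos += n_spec

    # donor inclusion per tissue; every donor must land in >= 1 tissue
    inclusion = {
        label: rng.random(config.n_donors) < p for (label, p) in config.tissues
    }
    orphan = ~np.logical_or.reduce([inclusion[label] for label in labels])
    if orphan.any():
        assign = rng.integers(0, len(labels), int(orphan.sum()))
        for j, donor_idx in enumerate(np.flatnonzero(orphan)):
            inclusion[labels[assign[j]]][donor_idx] = True

    matrices: Dict[str, ExpressionMatrix] = {}
    records = []
    sample_age_rows = []
    for label in labels:
        members = np.flatnonzero(inclusion[label])
        if len(members) == 0:
            raise ValidationError(f"tissue {label!r} received no donors")
        delta = rng.normal(0.0, config.tissue_offset_sd, config.n_genes)
        tissue_age = ages[members] + rng.normal(
            0.0, config.tissue_age_noise_sd, len(members)
        )
        a_std = (tissue_age - mid) / half
        noise = rng.normal(0.0, config.noise_sd, (config.n_genes, len(members)))
        log2x = (
            mu[:, None]
            + delta[:, None]
            + betas[label][:, None] * a_std[None, :]
            + noise
        )
        sample_ids = [f"{donor_ids[i]}-{label}" for i in members]
        matrices[label] = ExpressionMatrix(
            gene_ids=np.asarray(gene_ids, dtype=object),
            sample_ids=np.asarray(sample_ids, dtype=object),
            values=np.power(2.0, log2x),
            scale=RAW,
            tissue=label,
        )
        for j, (i, sid) in enumerate(zip(members, sample_ids)):
            records.append(
                {"sample_id": sid, "donor_id": donor_ids[i], "tissue": label,
                 "age": ages[i], "sex": sexes[i]}
            )
            sample_age_rows.append(
                {"sample_id": sid, "tissue": label,
                 "transcriptomic_age": tissue_age[j]}
            )

    table = SampleTable(pd.DataFrame(records))
    slopes = pd.DataFrame(
        [
            {"gene": g, "tissue": label, "beta": betas[label][gi]}
            for label in labels
            for gi, g in enumerate(gene_ids)
        ]
    )
    donor_df = pd.DataFrame(
        {"donor_id": donor_ids, "age": ages, "sex": sexes}
    )
    return Cohort(
        matrices=matrices,
        table=table,
        truth=GroundTruth(slopes=slopes, donor_ages=donor_df,
                          sample_ages=pd.DataFrame(sample_age_rows), config=config),
    )


def _apply_floor(beta: np.ndarray, floor: float) -> np.ndarray:
    """Push slope magnitudes away from zero (effect-size floor)."""
    if floor <= 0 or len(beta) == 0:
        return beta
    sign = np.where(beta >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(beta), floor)


def export_fixture(cohort: Cohort, out_dir) -> Dict[str, Path]:
    """Write GCT matrices, the sample table and the ground-truth slopes.

    Returns the written paths; re-running with the same cohort (same seed)
    produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for label, matrix in cohort.matrices.items():
        p = out_dir / f"expression_{label}.gct"
        write_expression(matrix, p, format="gct")
        paths[f"expression_{label}"] = p
    p = out_dir / "samples.tsv"
    write_sample_table(cohort.table, p)
    paths["samples"] = p
    p = out_dir / "ground_truth.tsv"
    cohort.truth.slopes.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["ground_truth"] = p
    return paths
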