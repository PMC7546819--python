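"""Elastic-net age regression: fitting, prediction, metrics, serialization.

The model minimizes

    sum_i (Age_i - w0 - sum_j x_ij w_j)^2
        + lambda * (alpha * sum_j |w_j| + (1 - alpha)/2 * sum_j w_j^2)

over samples i and preselected genes j, where x_ij is log2 expression,
alpha in [0, 1] mixes the lasso (alpha=1) and ridge (alpha=0) penalties
and lambda > 0 is the overall penalty strength. Note the residual term is
an unscaled sum of squares: lambda is defined on that scale, which is the
scale on which a grid of 2**-10 ... 2**10 is meaningful. Common solver
conventions divide the residual by 2M; the adapter below converts
(lambda_internal = lambda / (2M) for scikit-learn's ElasticNet,
lambda / 2 for its Ridge) and the mapping is verified against closed-form
oracles in the test suite.

Features are standardized (training mean 0, variance 1) before the
penalized fit and coefficients are back-transformed, so the exported model
is a plain linear equation on the original log2 scale:
``age = w0 + sum_j x_j w_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge

from .datamodel import TissueClockError, ValidationError
from .ranking import pearson_correlation

PathLike = Union[str, Path]


class MissingGeneError(TissueClockError):
    """Prediction was asked for without values for some model genes."""


@dataclass
class AgeModel:
    """A fitted linear age predictor on the log2 expression scale.

    ``coefficients`` has columns (gene, coefficient, tissue); tissue tags
    distinguish features drawn from different tissues in paired models.
    """

    intercept: float
    coefficients: pd.DataFrame
    alpha: float
    lam: float
    n_features_requested: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = {"gene", "coefficient", "tissue"}
        if not cols.issubset(self.coefficients.columns):
            raise ValidationError(f"coefficient table needs columns {sorted(cols)}")
        keys = list(zip(self.coefficients["gene"], self.coefficients["tissue"]))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (gene, tissue) coefficient entries")

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients["coefficient"] != 0).sum())

    def feature_keys(self) -> list:
        """(gene, tissue) pairs, or bare gene ids when they are unique."""
        genes = list(self.coefficients["gene"])
        if len(set(genes)) == len(genes):
            return genes
        return list(zip(genes, self.coefficients["tissue"]))


def fit_elastic_net(
    X: np.ndarray,
    ages: np.ndarray,
    alpha: float,
    lam: float,
    gene_ids: Optional[Sequence] = None,
    tissues: Optional[Sequence] = None,
    standardize: bool = True,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> AgeModel:
    """Fit the penalized age regression on samples x features ``X``.

    The intercept is never penalized. Coefficients are returned on the
    input scale regardless of internal standardization. ``tol`` is the
    coordinate-descent duality-gap tolerance (scikit-learn convention);
    failure to converge within ``max_iter`` sweeps warns, never errors.
    """
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(ages):
        raise ValidationError("X rows must align with ages")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples to fit")
    if np.isnan(X).any() or np.isnan(ages).any():
        raise ValidationError("NaN in training data")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    n, p = X.shape
    if gene_ids is None:
        gene_ids = [f"feature_{j}" for j in range(p)]
    if tissues is None:
        tissues = [""] * p
    gene_ids = list(gene_ids)
    tissues = list(tissues)

    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0.0
        sd_safe = np.where(constant, 1.0, sd)
        Xw = (X - mu) / sd_safe
    else:
        mu = np.zeros(p)
        sd_safe = np.ones(p)
        constant = np.zeros(p, dtype=bool)
        Xw = X

    if alpha == 0.0:
        # pure ridge: RSS + (lam/2) * ||w||^2  <=>  sklearn Ridge(alpha=lam/2)
        est = Ridge(alpha=lam / 2.0, fit_intercept=True, solver="cholesky")
        est.fit(Xw, ages)
    else:
        # sklearn ElasticNet minimizes RSS/(2n) + a*l1*|w| + a*(1-l1)/2*|w|^2;
        # dividing the objective above by 2n gives a = lam/(2n), l1 = alpha.
        est = ElasticNet(
            alpha=lam / (2.0 * n),
            l1_ratio=alpha,
            fit_intercept=True,
            max_iter=max_iter,
            tol=tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xw, ages)

    coef_std = np.asarray(est.coef_, dtype=float)
    coef_std[constant] = 0.0
    coef = coef_std / sd_safe
    intercept = float(est.intercept_) - float(coef_std @ (mu / sd_safe))
    table = pd.DataFrame(
        {"gene": gene_ids, "coefficient": coef, "tissue": tissues}
    )
    return AgeModel(
        intercept=intercept,
        coefficients=table,
        alpha=float(alpha),
        lam=float(lam),
        n_features_requested=p,
    )


def predict_age(
    model: AgeModel,
    expression: Mapping,
    zero_missing: bool = False,
) -> float:
    """Evaluate ``age = w0 + sum_j x_j w_j`` for one sample.

    ``expression`` maps feature keys (gene id, or (gene, tissue) when a
    gene appears under several tissues) to log2 values. Missing genes
    raise :class:`MissingGeneError` unless ``zero_missing`` is set, the
    diagnostic mode in which absent genes contribute 0 (so an empty map
    returns the intercept).
    """
    keys = model.feature_keys()
    coefs = model.coefficients["coefficient"].to_numpy(dtype=float)
    if not zero_missing:
        missing = [k for k in keys if k not in expression]
        if missing:
            raise MissingGeneError(
                f"{len(missing)} model genes missing from expression: {missing[:10]}"
            )
    x = np.asarray([float(expression.get(k, 0.0)) for k in keys])
    return float(model.intercept + coefs @ x)


def predict_ages_matrix(model: AgeModel, X: np.ndarray) -> np.ndarray:
    """Vectorized prediction for samples x features ``X`` aligned with the
    model's coefficient order."""
    coefs = model.coefficients["coefficient"].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(coefs):
        raise ValidationError(
            f"X has {X.shape[1]} features but model has {len(coefs)}"
        )
    return model.intercept + X @ coefs


def objective(model: AgeModel, X: np.ndarray, ages: np.ndarray) -> float:
    """Value of the penalized training objective at the model's coefficients
    (on the original feature scale, matching ``standardize=False`` fits)."""
    w = model.coefficients["coefficient"].to_numpy(dtype=float)
    resid = ages - predict_ages_matrix(model, X)
    penalty = model.lam * (
        model.alpha * np.abs(w).sum() + (1 - model.alpha) / 2.0 * (w @ w)
    )
    return float(resid @ resid + penalty)


def rmse(truth, predicted) -> float:
    """Root-mean-square error in years."""
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if truth.shape != predicted.shape:
        raise ValidationError("truth and predicted must have equal length")
    if truth.size < 1:
        raise ValidationError("rmse needs at least one pair")
    d = truth - predicted
    return float(np.sqrt(np.mean(d * d)))


def pcc(truth, predicted) -> float:
    """Pearson correlation between truth and predictions (NaN if degenerate)."""
    return pearson_correlation(truth, predicted)


# -- serialization (published-table layout) ---------------------------------

_HEADER = "Gene symbol\tCoefficient\tTissue"


def write_model(model: AgeModel, path: PathLike, precision: int = 7) -> None:
    """Write a model TSV: header, an Intercept row, then one row per gene
    with its coefficient (7 significant digits) and tissue of origin."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER + "\n")
        fh.write(f"Intercept\t{model.intercept:.{precision}g}\n")
        for _, row in model.coefficients.iterrows():
            fh.write(
                f"{row['gene']}\t{row['coefficient']:.{precision}g}\t{row['tissue']}\n"
            )


def read_model(path: PathLike, alpha: float = float("nan"), lam: float = float("nan")) -> AgeModel:
    """Read a model TSV written by :func:`write_model` (header optional)."""
    path = Path(path)
    intercept = None
    genes, coefs, tissues = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower().startswith("gene"):
                continue
            if parts[0].strip().lower() == "intercept":
                intercept = float(parts[1])
                continue
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed model row {line!r}")
            genes.append(parts[0].strip())
            coefs.append(float(parts[1]))
            tissues.append(parts[2].strip() if len(parts) > 2 else "")
    if intercept is None:
        raise ValidationError(f"{path}: model file has no Intercept row")
    table = pd.DataFrame({"gene": genes, "coefficient": coefs, "tissue": tissues})
    return AgeModel(
        intercept=intercept,
        coefficients=table,
        alpha=alpha,
        lam=lam,
        n_features_requested=len(table),
    )


def load_packaged_model() -> AgeModel:
    """The published best two-tissue (pituitary + skeletal muscle) model:
    intercept 49.1 years and the 50 largest-|coefficient| genes, with
    alpha=0 (ridge) and lambda=0.5 as reported."""
    path = Path(__file__).parent / "data" / "pituitary_muscle_model.tsv"
    return read_model(path, alpha=0.0, lam=0.5)


def load_packaged_cohort_summary() -> pd.DataFrame:
    """The published 46-tissue GTEx V6 cohort summary table."""
    path = Path(__file__).parent / "data" / "gtex_v6_cohort_summary.tsv"
    return pd.read_csv(path, sep="\t")
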