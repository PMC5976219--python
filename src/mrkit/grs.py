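"""Genetic-risk-score (GRS) arm: weighted allele scores, covariate-adjusted
association with continuous imaging phenotypes, score-quartile contrasts,
and first-principal-component derivation of tract-wise diffusion metrics.

The score for individual i is ``S_i = sum_j ln(OR_j) * G_ij`` over the
instrument set, with G the dosage of the effect allele. Associations use
ordinary least squares of the phenotype on the score (or quartile
indicators) plus covariates; coefficients are reported both raw and
exponentiated, since per-unit-score effects on continuous phenotypes are
conventionally published on the OR-like exp scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import Z95
from .summary_io import CohortTable, ValidationError

logger = logging.getLogger("mrkit")


@dataclass(frozen=True)
class WeightEntry:
    """Per-variant score weight: the exposure odds ratio for one copy of
    the effect allele."""

    variant_id: str
    odds_ratio: float
    effect_allele: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not (self.odds_ratio > 0):
            raise ValidationError(f"{self.variant_id}: odds ratio must be > 0")


@dataclass
class ScoreResult:
    individual_id: str
    score: float
    quartile: int | None = None
    n_imputed: int = 0


def read_weights(path: str | Path) -> list[WeightEntry]:
    """Read a weights file (SNP, EA, OR, optional EAF)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "EA": str})
    out = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "EAF", None)
        out.append(
            WeightEntry(
                variant_id=row.SNP,
                odds_ratio=float(row.OR),
                effect_allele=row.EA.upper(),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
            )
        )
    return out


def write_weights(weights: Sequence[WeightEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "SNP": w.variant_id,
                "EA": w.effect_allele,
                "OR": repr(w.odds_ratio),
                "EAF": "NA" if w.eaf is None else repr(w.eaf),
            }
            for w in weights
        ],
        columns=["SNP", "EA", "OR", "EAF"],
    ).to_csv(path, sep="\t", index=False)


def compute_scores(
    cohort: CohortTable, weights: Sequence[WeightEntry]
) -> list[ScoreResult]:
    """Weighted allele score per individual.

    Dosages are re-aligned to each weight's effect allele (``2 - G`` when
    the cohort file counts the other allele). A missing dosage is imputed
    as twice the weight file's effect-allele frequency when available,
    else the cohort mean dosage; imputations are counted per individual.
    Weight variants absent from the cohort are excluded (logged) for all
    individuals alike, keeping the variant set consistent.
    """
    used: list[tuple[str, float, float]] = []  # (variant, ln OR, impute value)
    cols: list[np.ndarray] = []
    for w in weights:
        if w.variant_id not in cohort.dosages.columns:
            logger.warning("score variant %s absent from cohort, excluded", w.variant_id)
            continue
        g = cohort.dosages[w.variant_id].to_numpy(dtype=float)
        if cohort.counted_alleles[w.variant_id] != w.effect_allele:
            g = 2.0 - g
        if w.eaf is not None:
            fill = 2.0 * w.eaf
        else:
            fill = float(np.nanmean(g)) if np.isfinite(g).any() else 0.0
        used.append((w.variant_id, math.log(w.odds_ratio), fill))
        cols.append(g)
    if not used:
        raise ValidationError("no weight variant present in the cohort")
    G = np.column_stack(cols)
    missing = ~np.isfinite(G)
    fills = np.array([u[2] for u in used])
    G = np.where(missing, fills[None, :], G)
    logw = np.array([u[1] for u in used])
    scores = G @ logw
    n_imp = missing.sum(axis=1)
    results = [
        ScoreResult(individual_id=iid, score=float(s), n_imputed=int(k))
        for iid, s, k in zip(cohort.individual_ids, scores, n_imp)
    ]
    assign_quartiles(results)
    return results


def assign_quartiles(scores: list[ScoreResult]) -> None:
    """Label each score with its quartile (1-4).

    Boundaries are the empirical 25/50/75% quantiles under the linear
    interpolation rule (NumPy's default, R type 7); a score tied with a
    boundary goes to the lower quartile.
    """
    vals = np.array([s.score for s in scores])
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    for s in scores:
        s.quartile = 1 + int(s.score > q1) + int(s.score > q2) + int(s.score > q3)


@dataclass(frozen=True)
class AssocResult:
    """One regression coefficient with normal-theory 95% CI, raw and
    exponentiated."""

    term: str
    beta: float
    se: float
    pvalue: float
    n_used: int

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))


def _design(
    cohort: CohortTable,
    phenotype: str,
    covariates: Sequence[str],
    extra: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Assemble y and X with listwise deletion of incomplete rows."""
    for name in (phenotype, *covariates):
        if name not in cohort.pheno.columns:
            raise ValidationError(f"column {name!r} not in the phenotype table")
    df = pd.concat([cohort.pheno[[phenotype, *covariates]], extra], axis=1)
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("listwise deletion removed %d incomplete rows", n_dropped)
    y = complete[phenotype]
    X = sm.add_constant(complete.drop(columns=[phenotype]), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose QR pivot vanishes
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
    return y, X, len(complete)


def score_regression(
    scores: Sequence[ScoreResult],
    cohort: CohortTable,
    phenotype: str,
    covariates: Sequence[str] = (),
) -> AssocResult:
    """OLS of a continuous phenotype on the genetic score plus covariates.

    Returns the score coefficient with SE, two-sided p (normal reference)
    and exponentiated scale.
    """
    svec = pd.Series(
        {s.individual_id: s.score for s in scores}, name="score"
    ).reindex(cohort.pheno.index)
    y, X, n_used = _design(cohort, phenotype, covariates, svec.to_frame())
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        term="score",
        beta=float(fit.params["score"]),
        se=float(fit.bse["score"]),
        pvalue=float(fit.pvalues["score"]),
        n_used=n_used,
    )


def quartile_contrasts(
    scores: Sequence[ScoreResult],
    cohort: CohortTable,
    phenotype: str,
    covariates: Sequence[str] = (),
) -> list[AssocResult]:
    """Quartile contrasts Q2 vs Q1, Q3 vs Q1, Q4 vs Q1.

    The phenotype is regressed on three quartile indicator variables plus
    covariates, with the bottom quartile as the omitted reference.
    """
    if len(scores) < 8:
        raise ValidationError("quartile contrasts need at least 8 individuals")
    quart = pd.Series(
        {s.individual_id: s.quartile for s in scores}
    ).reindex(cohort.pheno.index)
    counts = quart.value_counts()
    empty = [q for q in (1, 2, 3, 4) if counts.get(q, 0) == 0]
    if empty:
        raise ValidationError(
            f"degenerate quartile boundaries: quartile(s) {empty} empty "
            "(scores tied at a boundary)"
        )
    indicators = pd.DataFrame(
        {f"Q{q}": (quart == q).astype(float) for q in (2, 3, 4)},
        index=cohort.pheno.index,
    )
    y, X, n_used = _design(cohort, phenotype, covariates, indicators)
    fit = sm.OLS(y, X).fit()
    return [
        AssocResult(
            term=f"Q{q}_vs_Q1",
            beta=float(fit.params[f"Q{q}"]),
            se=float(fit.bse[f"Q{q}"]),
            pvalue=float(fit.pvalues[f"Q{q}"]),
            n_used=n_used,
        )
        for q in (2, 3, 4)
    ]


@dataclass
class FirstPCResult:
    """Leading principal component of a tract-metric matrix."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: float
    kept_columns: list[int]


def first_pc_phenotype(tract_matrix: np.ndarray | pd.DataFrame) -> FirstPCResult:
    """Scalar phenotype: first principal component of per-tract means.

    Columns are standardized (correlation-based PCA, so the result is
    invariant to per-tract scaling); zero-variance columns are dropped
    with a warning. The leading eigenvector's sign is fixed so its loading
    sum is positive, and the projection is rescaled to unit variance.
    """
    X = np.asarray(
        tract_matrix.to_numpy() if isinstance(tract_matrix, pd.DataFrame) else tract_matrix,
        dtype=float,
    )
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need at least 2 individuals and 2 tracts")
    if not np.isfinite(X).all():
        raise ValidationError("missing cells: listwise-delete before calling")
    sd = X.std(axis=0, ddof=1)
    kept = np.nonzero(sd > 0)[0]
    if len(kept) < X.shape[1]:
        logger.warning("dropping %d zero-variance tract columns", X.shape[1] - len(kept))
    if len(kept) < 2:
        raise ValidationError("fewer than 2 tracts with variance")
    Z = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    corr = Z.T @ Z / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    proj = Z @ lead
    psd = proj.std(ddof=1)
    if psd > 0:
        proj = proj / psd
    return FirstPCResult(
        scores=proj,
        loadings=lead,
        explained_variance_ratio=float(eigvals[-1] / eigvals.sum()),
        kept_columns=list(kept),
    )


def scores_to_frame(scores: Sequence[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "IID": [s.individual_id for s in scores],
            "score": [s.score for s in scores],
            "quartile": [s.quartile for s in scores],
            "n_imputed": [s.n_imputed for s in scores],
        }
    )


__all__ = [
    "WeightEntry",
    "ScoreResult",
    "AssocResult",
    "FirstPCResult",
    "read_weights",
    "write_weights",
    "compute_scores",
    "assign_quartiles",
    "score_regression",
    "quartile_contrasts",
    "first_pc_phenotype",
    "scores_to_frame",
]
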