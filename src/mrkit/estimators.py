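"""Two-sample MR estimators and pleiotropy diagnostics.

Given harmonized per-variant associations (beta_exposure, se_exposure,
beta_outcome, se_outcome), this module computes per-instrument Wald ratio
estimates and combines them with the four estimators of the study design:

* **IVW** — fixed-effect inverse-variance weighted mean of the ratio
  estimates (identically: the zero-intercept weighted-least-squares slope
  of outcome betas on exposure betas with weights se_outcome^-2). An
  optional multiplicative random-effects flag scales the SE by
  ``max(1, sqrt(Q / (J - 1)))``.
* **Weighted median** — the 50th percentile of the weighted empirical
  distribution of ratio estimates, consistent when instruments carrying
  under half of the total weight are invalid; SE by parametric bootstrap.
* **Penalized weighted median** — the same after down-weighting
  heterogeneity outliers via a one-sided chi-square(1) tail penalty.
* **MR-Egger** — weighted regression of outcome on exposure betas with an
  unconstrained intercept; the intercept estimates average directional
  pleiotropy (nonzero intercept = directional pleiotropy under InSIDE),
  the slope the causal effect.

Ratio standard errors are first order (se_outcome / |beta_exposure|),
ignoring the exposure-side sampling error — standard two-sample practice
with strong instruments. IVW and median p-values use the normal reference;
Egger p-values use Student t with J - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import DROPPED, HarmonizedPair

logger = logging.getLogger("mrkit")

#: two-sided 95% normal quantile, fixed for reproducibility
Z95 = 1.959964

IVW = "ivw"
WEIGHTED_MEDIAN = "weighted_median"
PENALIZED_WEIGHTED_MEDIAN = "penalized_weighted_median"
EGGER_SLOPE = "egger_slope"
METHODS = (IVW, WEIGHTED_MEDIAN, PENALIZED_WEIGHTED_MEDIAN, EGGER_SLOPE)


class EstimationError(ValueError):
    """An estimator's contract is violated (too few instruments, singular
    design, ...)."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-instrument Wald ratio: outcome effect over exposure effect."""

    variant_id: str
    theta: float
    s: float

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise EstimationError(f"{self.variant_id}: ratio SE must be > 0")

    @property
    def weight(self) -> float:
        return self.s**-2


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds (or trait-unit) scale,
    with its exponentiated counterpart for OR-style reporting."""

    method: str
    beta_hat: float
    se: float
    pvalue: float
    n_instruments: int
    ci_multiplier: float = Z95

    @property
    def ci_low(self) -> float:
        return self.beta_hat - self.ci_multiplier * self.se

    @property
    def ci_high(self) -> float:
        return self.beta_hat + self.ci_multiplier * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — exp of the log-scale triple."""
        return (math.exp(self.beta_hat), math.exp(self.ci_low), math.exp(self.ci_high))


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: MREstimate


def _usable(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.status != DROPPED]


def ratio_estimates(pairs: Sequence[HarmonizedPair]) -> list[RatioEstimate]:
    """Wald ratios with first-order SEs; instruments with a zero exposure
    effect are excluded (ratio undefined) with a logged reason."""
    out: list[RatioEstimate] = []
    for p in _usable(pairs):
        if p.beta_exposure == 0:
            logger.warning(
                "instrument %s excluded: zero exposure effect", p.variant_id
            )
            continue
        out.append(
            RatioEstimate(
                variant_id=p.variant_id,
                theta=p.beta_outcome / p.beta_exposure,
                s=p.se_outcome / abs(p.beta_exposure),
            )
        )
    return out


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def ivw(
    ratios: Sequence[RatioEstimate], *, random_effects: bool = False
) -> MREstimate:
    """Inverse-variance weighted estimate of the causal effect.

    Fixed-effect by default: ``beta_hat = sum(w theta) / sum(w)`` with
    ``w = s^-2`` and ``se = sum(w)^-1/2``. With ``random_effects`` the SE
    is inflated by ``max(1, sqrt(Q/(J-1)))`` (multiplicative model).
    """
    if not ratios:
        raise EstimationError("ivw requires at least one instrument")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta_hat = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if random_effects and len(ratios) >= 2:
        q, df, _ = cochran_q(ratios, beta_hat)
        se *= max(1.0, math.sqrt(q / df))
    return MREstimate(
        method=IVW,
        beta_hat=beta_hat,
        se=se,
        pvalue=_normal_p(beta_hat / se),
        n_instruments=len(ratios),
    )


def cochran_q(
    ratios: Sequence[RatioEstimate], center: float
) -> tuple[float, int, list[float]]:
    """Cochran's heterogeneity statistic about ``center``.

    Returns (Q, J - 1, per-instrument contributions in input order).
    """
    if not ratios:
        raise EstimationError("cochran_q requires at least one instrument")
    per = [r.weight * (r.theta - center) ** 2 for r in ratios]
    return float(sum(per)), len(ratios) - 1, per


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median with midpoint interpolation.

    Order statistics theta_(1) <= ... <= theta_(J) get cumulative weight
    midpoints p_j = cumsum(w')_j - w'_j / 2 (w' normalized); the estimate
    interpolates linearly between the order statistics bracketing p = 0.5,
    returning theta_(j) exactly when some p_j = 0.5.
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2.0
    exact = np.nonzero(p == 0.5)[0]
    if exact.size:
        return float(th[exact[0]])
    if p[0] > 0.5:
        return float(th[0])
    if p[-1] < 0.5:
        return float(th[-1])
    j = int(np.searchsorted(p, 0.5) - 1)
    return float(th[j] + (th[j + 1] - th[j]) * (0.5 - p[j]) / (p[j + 1] - p[j]))


def _weighted_median_rows(theta_mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for the bootstrap (same rule, vectorized)."""
    order = np.argsort(theta_mat, axis=1, kind="stable")
    th = np.take_along_axis(theta_mat, order, axis=1)
    wn = (w / w.sum())[order]
    p = np.cumsum(wn, axis=1) - wn / 2.0
    nrow = theta_mat.shape[0]
    out = np.empty(nrow)
    # searchsorted has no batched form; rows are short so a loop is cheap
    for i in range(nrow):
        out[i] = _interp_row(th[i], p[i])
    return out


def _interp_row(th: np.ndarray, p: np.ndarray) -> float:
    exact = np.nonzero(p == 0.5)[0]
    if exact.size:
        return float(th[exact[0]])
    if p[0] > 0.5:
        return float(th[0])
    if p[-1] < 0.5:
        return float(th[-1])
    j = int(np.searchsorted(p, 0.5) - 1)
    return float(th[j] + (th[j + 1] - th[j]) * (0.5 - p[j]) / (p[j + 1] - p[j]))


def weighted_median(
    ratios: Sequence[RatioEstimate],
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    weights: np.ndarray | None = None,
    _method_label: str = WEIGHTED_MEDIAN,
) -> MREstimate:
    """Weighted median of the ratio estimates.

    Consistent when instruments carrying < 50% of the total weight are
    invalid. The SE is the standard deviation of the estimator over
    ``n_boot`` parametric-bootstrap replicates theta_j* ~ N(theta_j, s_j)
    (weights held fixed); ``seed`` makes the bootstrap reproducible.

    ``weights`` overrides the default inverse-variance weights (used by the
    penalized variant); bootstrap draws always use the original s_j.
    """
    if len(ratios) < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    theta = np.array([r.theta for r in ratios])
    s = np.array([r.s for r in ratios])
    w = np.array([r.weight for r in ratios]) if weights is None else np.asarray(weights, float)
    beta_hat = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, s, size=(n_boot, len(ratios)))
    boot = _weighted_median_rows(draws, w)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")
    p = _normal_p(beta_hat / se) if se > 0 else float("nan")
    return MREstimate(
        method=_method_label,
        beta_hat=beta_hat,
        se=se,
        pvalue=p,
        n_instruments=len(ratios),
    )


def penalized_weights(
    ratios: Sequence[RatioEstimate], penalty_scale: float = 20.0
) -> np.ndarray:
    """Down-weight heterogeneity outliers.

    Each instrument's contribution q_j = w_j (theta_j - theta_WM)^2 to
    Cochran's Q about the unpenalized weighted median is referred to the
    chi-square(1) upper tail; weights become w_j * min(1, scale * p_j), so
    concordant instruments (p near 1) are untouched and gross outliers are
    suppressed.
    """
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    center = _weighted_median_point(theta, w)
    q = w * (theta - center) ** 2
    p_tail = stats.chi2.sf(q, df=1)
    return w * np.minimum(1.0, penalty_scale * p_tail)


def penalized_weighted_median(
    ratios: Sequence[RatioEstimate],
    n_boot: int = 1000,
    seed: int | None = None,
    penalty_scale: float = 20.0,
) -> MREstimate:
    """Weighted median under outlier-penalized weights."""
    if len(ratios) < 3:
        raise EstimationError("penalized weighted median requires at least 3 instruments")
    w_star = penalized_weights(ratios, penalty_scale)
    return weighted_median(
        ratios,
        n_boot=n_boot,
        seed=seed,
        weights=w_star,
        _method_label=PENALIZED_WEIGHTED_MEDIAN,
    )


def egger(pairs: Sequence[HarmonizedPair]) -> EggerResult:
    """MR-Egger regression.

    Instruments are oriented so every exposure effect is non-negative
    (flipping both betas where needed — the ratio is invariant, the
    intercept is not). Outcome betas are regressed on exposure betas with
    an intercept, weights se_outcome^-2. Standard errors come from the
    unscaled WLS covariance multiplied by ``max(1, sigma_hat)`` where
    sigma_hat^2 is the weighted residual mean square (overdispersion is
    absorbed, underdispersion is not rewarded). Both p-values use Student
    t with J - 2 degrees of freedom.
    """
    usable = _usable(pairs)
    if len(usable) < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    bx = np.array([p.beta_exposure for p in usable])
    by = np.array([p.beta_outcome for p in usable])
    sy = np.array([p.se_outcome for p in usable])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise EstimationError(
            "MR-Egger design is singular: all exposure effects equal after orientation"
        )
    w = sy**-2.0
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ (X.T @ (w * by))
    resid = by - X @ coef
    df = len(usable) - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    scale = max(1.0, math.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    tdist = stats.t(df)
    t_mult = float(tdist.ppf(0.975))
    intercept_p = float(2.0 * tdist.sf(abs(coef[0] / se[0])))
    slope_p = float(2.0 * tdist.sf(abs(coef[1] / se[1])))
    slope = MREstimate(
        method=EGGER_SLOPE,
        beta_hat=float(coef[1]),
        se=float(se[1]),
        pvalue=slope_p,
        n_instruments=len(usable),
        ci_multiplier=t_mult,
    )
    return EggerResult(
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=intercept_p,
        slope=slope,
    )


@dataclass
class EstimateTable:
    """All estimators for one exposure-outcome pair, plus diagnostics."""

    estimates: dict[str, MREstimate | None]
    egger: EggerResult | None
    q_statistic: float | None
    q_df: int | None
    n_instruments: int

    def to_frame(self, outcome: str = "") -> pd.DataFrame:
        rows = []
        for method in METHODS:
            est = self.estimates.get(method)
            if est is None:
                rows.append(
                    {"outcome": outcome, "method": method, "status": "not_estimable"}
                )
                continue
            orv, lo, hi = est.or_scale
            rows.append(
                {
                    "outcome": outcome,
                    "method": method,
                    "status": "ok",
                    "beta": est.beta_hat,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "OR": orv,
                    "OR_ci_low": lo,
                    "OR_ci_high": hi,
                    "pvalue": est.pvalue,
                    "n_instruments": est.n_instruments,
                }
            )
        return pd.DataFrame(rows)


def estimate_all(
    pairs: Sequence[HarmonizedPair],
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    penalty_scale: float = 20.0,
    random_effects: bool = False,
) -> EstimateTable:
    """Run every estimator that is defined for the instrument set.

    With fewer than 3 instruments the median estimators and MR-Egger are
    reported as not estimable rather than raising.
    """
    ratios = ratio_estimates(pairs)
    if not ratios:
        raise EstimationError("no usable instruments")
    estimates: dict[str, MREstimate | None] = {m: None for m in METHODS}
    estimates[IVW] = ivw(ratios, random_effects=random_effects)
    if len(ratios) >= 3:
        estimates[WEIGHTED_MEDIAN] = weighted_median(ratios, n_boot=n_boot, seed=seed)
        estimates[PENALIZED_WEIGHTED_MEDIAN] = penalized_weighted_median(
            ratios, n_boot=n_boot, seed=seed, penalty_scale=penalty_scale
        )
    egger_result = None
    if len(ratios) >= 3:
        try:
            egger_result = egger(pairs)
            estimates[EGGER_SLOPE] = egger_result.slope
        except EstimationError as exc:
            logger.warning("MR-Egger not estimable: %s", exc)
    q, qdf, _ = (
        cochran_q(ratios, estimates[IVW].beta_hat) if len(ratios) >= 2 else (None, None, None)
    )
    return EstimateTable(
        estimates=estimates,
        egger=egger_result,
        q_statistic=q,
        q_df=qdf,
        n_instruments=len(ratios),
    )


__all__ = [
    "RatioEstimate",
    "MREstimate",
    "EggerResult",
    "EstimateTable",
    "EstimationError",
    "ratio_estimates",
    "ivw",
    "cochran_q",
    "weighted_median",
    "penalized_weighted_median",
    "penalized_weights",
    "egger",
    "estimate_all",
    "Z95",
    "IVW",
    "WEIGHTED_MEDIAN",
    "PENALIZED_WEIGHTED_MEDIAN",
    "EGGER_SLOPE",
    "METHODS",
]
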