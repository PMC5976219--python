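"""Repeated-simulation calibration studies.

Runs the full pipeline (generate → harmonize → estimate) over many seeded
replicates of a scenario and summarizes estimator behaviour: bias,
confidence-interval coverage, type-I error, MR-Egger pleiotropy detection,
and weighted-median robustness. These are the package's own validity
checks; both the test-bench and the reporting script drive them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .estimators import RatioEstimate, egger, ivw, ratio_estimates, weighted_median
from .harmonize import build_instruments
from .simulate import Scenario, ld_pairs_from_panel, simulate_study
from .summary_io import LDTable


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one base seed
    (kept below 2**31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def study_pairs(scenario: Scenario, seed: int):
    """One replicate through the real pipeline: simulate both samples,
    then clump + harmonize with the generative LD table."""
    study = simulate_study(scenario, seed=seed)
    ld = LDTable(ld_pairs_from_panel(study.panel))
    pairs = build_instruments(study.exposure_stats, study.outcome_stats, ld)
    return study, pairs


@dataclass
class IvwReplicates:
    estimates: np.ndarray
    ses: np.ndarray
    covered: np.ndarray  # CI covers the true causal effect
    rejected: np.ndarray  # p < 0.05

    @property
    def mean(self) -> float:
        return float(self.estimates.mean())

    @property
    def mc_se_of_mean(self) -> float:
        return float(self.estimates.std(ddof=1) / np.sqrt(len(self.estimates)))

    @property
    def coverage(self) -> float:
        return float(self.covered.mean())

    @property
    def rejection_rate(self) -> float:
        return float(self.rejected.mean())


def ivw_replicates(scenario: Scenario, n_reps: int, base_seed: int) -> IvwReplicates:
    """IVW over seeded replicates of a scenario."""
    beta = scenario.beta_causal
    est = np.empty(n_reps)
    ses = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    rejected = np.empty(n_reps, dtype=bool)
    for i, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        _, pairs = study_pairs(scenario, seed)
        e = ivw(ratio_estimates(pairs))
        est[i], ses[i] = e.beta_hat, e.se
        covered[i] = e.ci_low <= beta <= e.ci_high
        rejected[i] = e.pvalue < 0.05
    return IvwReplicates(est, ses, covered, rejected)


@dataclass
class EggerReplicates:
    intercepts: np.ndarray
    intercept_significant: np.ndarray  # p < 0.05
    intercept_covers_zero: np.ndarray
    slopes: np.ndarray

    @property
    def detection_rate(self) -> float:
        return float(self.intercept_significant.mean())

    @property
    def intercept_coverage_of_zero(self) -> float:
        return float(self.intercept_covers_zero.mean())

    @property
    def slope_mean(self) -> float:
        return float(self.slopes.mean())

    @property
    def slope_mc_se_of_mean(self) -> float:
        return float(self.slopes.std(ddof=1) / np.sqrt(len(self.slopes)))


def egger_replicates(scenario: Scenario, n_reps: int, base_seed: int) -> EggerReplicates:
    """MR-Egger intercept/slope behaviour over seeded replicates."""
    intercepts = np.empty(n_reps)
    signif = np.empty(n_reps, dtype=bool)
    covers = np.empty(n_reps, dtype=bool)
    slopes = np.empty(n_reps)
    for i, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        _, pairs = study_pairs(scenario, seed)
        res = egger(pairs)
        intercepts[i] = res.intercept
        signif[i] = res.intercept_p < 0.05
        half = res.slope.ci_multiplier * res.intercept_se
        covers[i] = res.intercept - half <= 0.0 <= res.intercept + half
        slopes[i] = res.slope.beta_hat
    return EggerReplicates(intercepts, signif, covers, slopes)


@dataclass
class MedianVsIvw:
    ivw_errors: np.ndarray
    median_errors: np.ndarray

    @property
    def median_wins_fraction(self) -> float:
        """Fraction of replicates where the weighted median is closer to
        the true effect than IVW."""
        return float((np.abs(self.median_errors) < np.abs(self.ivw_errors)).mean())

    @property
    def ivw_mean_bias(self) -> float:
        return float(self.ivw_errors.mean())

    @property
    def median_mean_bias(self) -> float:
        return float(self.median_errors.mean())


def median_vs_ivw_replicates(
    scenario: Scenario, n_reps: int, base_seed: int
) -> MedianVsIvw:
    """Per-replicate comparison of weighted-median and IVW errors under
    invalid instruments (point estimates; bootstrap SEs not needed)."""
    beta = scenario.beta_causal
    ivw_err = np.empty(n_reps)
    med_err = np.empty(n_reps)
    for i, seed in enumerate(replicate_seeds(base_seed, n_reps)):
        _, pairs = study_pairs(scenario, seed)
        ratios = ratio_estimates(pairs)
        ivw_err[i] = ivw(ratios).beta_hat - beta
        med_err[i] = weighted_median(ratios, n_boot=2, seed=seed).beta_hat - beta
    return MedianVsIvw(ivw_err, med_err)


def ivw_three_route_max_discrepancy(n_sets: int, base_seed: int) -> float:
    """Maximum absolute disagreement between three algebraically equivalent
    IVW computations over random instrument sets: the meta-analysis
    formula, the zero-intercept WLS normal equation, and a direct weighted
    mean via numpy."""
    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for _ in range(n_sets):
        j = int(rng.integers(2, 30))
        bx = rng.normal(0.1, 0.05, j)
        bx[np.abs(bx) < 1e-3] = 1e-3
        by = rng.normal(0.02, 0.05, j)
        sy = rng.uniform(0.01, 0.2, j)
        theta, s = by / bx, sy / np.abs(bx)
        ratios = [
            RatioEstimate(variant_id=f"v{i}", theta=float(theta[i]), s=float(s[i]))
            for i in range(j)
        ]
        route_meta = ivw(ratios).beta_hat
        w = sy**-2.0
        route_wls = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        route_avg = float(np.average(theta, weights=s**-2.0))
        worst = max(
            worst,
            abs(route_meta - route_wls),
            abs(route_meta - route_avg),
            abs(route_wls - route_avg),
        )
    return worst


def reduced(scenario: Scenario, n: int) -> Scenario:
    """The same design at a smaller per-sample size (both GWAS samples)."""
    return dataclasses.replace(scenario, n_exposure_sample=n, n_outcome_sample=n)


__all__ = [
    "IvwReplicates",
    "EggerReplicates",
    "MedianVsIvw",
    "replicate_seeds",
    "study_pairs",
    "ivw_replicates",
    "egger_replicates",
    "median_vs_ivw_replicates",
    "ivw_three_route_max_discrepancy",
    "reduced",
]
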