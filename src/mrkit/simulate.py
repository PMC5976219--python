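"""Synthetic two-sample MR studies with known ground truth.

The generator draws individual-level genotypes for two non-overlapping
GWAS samples (and optionally a third individual-level cohort for the
risk-score arm), builds exposure and outcome traits from an explicit
structural model, and reduces each sample to per-variant summary
statistics — so every downstream stage (harmonization, estimation, risk
scores) can be exercised against a known causal effect.

Structural model (per individual):

    X = sum_j gamma_j G_j + c_U * U + eps_X        Var(X) = 1
    Y = beta * X + sum_{j in invalid} alpha_j G_j + c_U * U + eps_Y

with U a standard-normal confounder shared by both traits, gamma drawn
half-normal (effect alleles are coded exposure-increasing, the risk-allele
convention of published instrument lists) and rescaled so the instruments
explain exactly ``h2_exposure`` of the exposure variance in expectation.
Direct (pleiotropic) effects ``alpha_j ~ N(mu, tau^2)`` are drawn
independently of gamma, so the InSIDE condition holds by construction in
both balanced (mu = 0) and directional (mu > 0) modes.

Genotypes are Binomial(2, f). Within an LD block every variant shares the
block allele frequency and copies a latent block haplotype with
probability ``r2**0.25`` per haplotype, giving every within-block pair the
target r² exactly in expectation (positively phased, equicorrelated
blocks). Binary traits arise by thresholding a liability at the target
case fraction, with per-variant logistic score-test summary statistics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import CohortTable, LDPair, SummaryRecord

#: base-pair spacing between independent loci / within an LD block
LOCUS_SPACING_BP = 1_000_000
BLOCK_SPACING_BP = 10_000


@dataclass(frozen=True)
class Scenario:
    """Full generative specification of a synthetic two-sample experiment.

    Defaults mirror the study design being emulated: 84 exposure
    instruments jointly explaining 5-10% of exposure variance (default
    7.5%), GWAS samples of 50 000 per trait, and an individual-level
    cohort of 8357 for the risk-score arm.
    """

    n_variants: int = 84
    n_exposure_sample: int = 50_000
    n_outcome_sample: int = 50_000
    n_cohort: int = 8357
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.075
    beta_causal: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    confounder_loading: float = 0.3
    binary_exposure: bool = False
    exposure_case_fraction: float = 0.1
    binary_outcome: bool = False
    outcome_case_fraction: float = 0.1
    instrument_strength_floor: float = 1.0
    ld_blocks: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.invalid_fraction < 1.0):
            raise ValueError("invalid_fraction must be in [0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.h2_exposure < 1.0):
            raise ValueError("h2_exposure must be in [0, 1)")
        if self.h2_exposure + self.confounder_loading**2 >= 1.0:
            raise ValueError("h2_exposure + confounder variance must be < 1")
        if sum(size for size, _ in self.ld_blocks) > self.n_variants:
            raise ValueError("ld_blocks exceed n_variants")


@dataclass(frozen=True)
class VariantPanel:
    """Variant identities, positions and generative allele frequencies."""

    ids: tuple[str, ...]
    chrom: tuple[str, ...]
    pos: tuple[int, ...]
    freq: np.ndarray
    block_of: np.ndarray  # -1 for independent variants
    block_r2: tuple[float, ...]


@dataclass(frozen=True)
class EffectSet:
    """True per-variant effects: gamma (variant -> exposure), alpha
    (direct variant -> outcome) on the invalid set."""

    gamma: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray  # boolean mask


def draw_variant_panel(scenario: Scenario, rng: np.random.Generator) -> VariantPanel:
    """Lay out variants along one chromosome: independent loci 1 Mb apart,
    LD-block members 10 kb apart sharing the block allele frequency."""
    m = scenario.n_variants
    lo, hi = scenario.maf_range
    freq = rng.uniform(lo, hi, size=m)
    block_of = np.full(m, -1, dtype=int)
    block_r2 = []
    idx = 0
    for b, (size, r2) in enumerate(scenario.ld_blocks):
        if not (0.0 <= r2 <= 1.0):
            raise ValueError("block r2 must be in [0, 1]")
        freq[idx : idx + size] = freq[idx]  # matched frequencies within a block
        block_of[idx : idx + size] = b
        block_r2.append(float(r2))
        idx += size
    ids, chrom, pos = [], [], []
    locus = 0
    prev_block = -1
    p = 0
    for j in range(m):
        if block_of[j] == -1 or block_of[j] != prev_block:
            locus += 1
            p = locus * LOCUS_SPACING_BP
        else:
            p += BLOCK_SPACING_BP
        prev_block = block_of[j]
        ids.append(f"rs{j + 1}")
        chrom.append("1")
        pos.append(p)
    return VariantPanel(
        ids=tuple(ids),
        chrom=tuple(chrom),
        pos=tuple(pos),
        freq=freq,
        block_of=block_of,
        block_r2=tuple(block_r2),
    )


def _max_feasible_corr(f1: float, f2: float) -> float:
    lo, hi = min(f1, f2), max(f1, f2)
    return math.sqrt(lo * (1 - hi) / (hi * (1 - lo)))


def simulate_genotypes(
    panel: VariantPanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x m dosage matrix.

    Independent variants are Binomial(2, f) via a single inverse-CDF
    uniform per cell. Block members copy a latent block haplotype with
    probability ``r2**0.25``, so each within-block pair has correlation
    sqrt(r2), i.e. squared correlation r2.
    """
    m = len(panel.ids)
    f = panel.freq
    G = np.empty((n, m), dtype=np.float64)
    indep = panel.block_of == -1
    if indep.any():
        fi = f[indep]
        u = rng.random((n, int(indep.sum())))
        q0 = (1 - fi) ** 2
        q1 = q0 + 2 * fi * (1 - fi)
        G[:, indep] = (u >= q0).astype(np.float64) + (u >= q1)
    for b, r2 in enumerate(panel.block_r2):
        members = np.nonzero(panel.block_of == b)[0]
        fb = f[members[0]]
        for other in members[1:]:
            if not math.isclose(f[other], fb):
                raise ValueError(
                    "LD block requires matched allele frequencies; "
                    f"got {fb} vs {f[other]} — use a shared block frequency"
                )
        c = r2**0.25
        k = len(members)
        hap = np.empty((n, 2, k))
        for h in range(2):
            anchor = (rng.random(n) < fb).astype(np.float64)
            copy = rng.random((n, k)) < c
            fresh = (rng.random((n, k)) < fb).astype(np.float64)
            hap[:, h, :] = np.where(copy, anchor[:, None], fresh)
        G[:, members] = hap.sum(axis=1)
    return G


def ld_pairs_from_panel(panel: VariantPanel) -> list[LDPair]:
    """The generative LD table: exact target r² for within-block pairs."""
    pairs = []
    for b, r2 in enumerate(panel.block_r2):
        members = np.nonzero(panel.block_of == b)[0]
        for i_pos, i in enumerate(members):
            for j in members[i_pos + 1 :]:
                pairs.append(
                    LDPair(
                        variant_a=panel.ids[i],
                        variant_b=panel.ids[j],
                        r2=r2,
                        distance_bp=abs(panel.pos[i] - panel.pos[j]),
                    )
                )
    return pairs


def draw_effects(scenario: Scenario, panel: VariantPanel, rng: np.random.Generator) -> EffectSet:
    """Draw gamma and alpha for one replicate.

    gamma ~ floor + |N(0, 1)| rescaled so the theoretical genetic variance
    sum_j gamma_j^2 2 f_j (1 - f_j) equals ``h2_exposure``. The additive
    strength floor emulates instrument selection: published instrument
    lists contain only robustly (genome-wide significantly) associated
    variants, so the generator should not produce effectively null
    instruments whose estimated effect sign is a coin flip. The invalid
    set is a simple random sample of round(invalid_fraction * m) variants
    with alpha ~ N(mu, tau^2) drawn independently of gamma (InSIDE).
    """
    m = scenario.n_variants
    gamma = scenario.instrument_strength_floor + np.abs(rng.standard_normal(m))
    var_g = 2.0 * panel.freq * (1.0 - panel.freq)
    raw = float(np.sum(gamma**2 * var_g))
    if scenario.h2_exposure > 0:
        if raw <= 0:
            raise ValueError("cannot rescale effects: zero raw genetic variance")
        gamma *= math.sqrt(scenario.h2_exposure / raw)
    else:
        gamma[:] = 0.0
    invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    n_invalid = int(round(scenario.invalid_fraction * m))
    if scenario.pleiotropy_mode != "none" and n_invalid > 0:
        chosen = rng.choice(m, size=n_invalid, replace=False)
        invalid[chosen] = True
        mu = scenario.pleiotropy_mean if scenario.pleiotropy_mode == "directional" else 0.0
        alpha[chosen] = rng.normal(mu, scenario.pleiotropy_sd, size=n_invalid)
    return EffectSet(gamma=gamma, alpha=alpha, invalid=invalid)


@dataclass
class TraitSample:
    """One sample's genotypes and traits (latent continuous + observed)."""

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    exposure_liability: np.ndarray
    realized_h2: float


def simulate_traits(
    genotypes: np.ndarray,
    effects: EffectSet,
    scenario: Scenario,
    rng: np.random.Generator,
) -> TraitSample:
    """Generate exposure and outcome for one genotype sample.

    Both traits share the confounder U; the outcome receives the causal
    path ``beta * X`` (X on the liability scale when the exposure is
    binary) plus direct effects of the invalid instruments. Binary traits
    are liability thresholded at the configured case fraction.
    """
    n = genotypes.shape[0]
    c_u = scenario.confounder_loading
    u = rng.standard_normal(n)
    g_score = genotypes @ effects.gamma
    eps_x_var = 1.0 - scenario.h2_exposure - c_u**2
    x = g_score + c_u * u + rng.normal(0.0, math.sqrt(eps_x_var), n)
    var_x = float(np.var(x))
    realized_h2 = float(np.var(g_score) / var_x) if var_x > 0 else 0.0
    exposure = x
    if scenario.binary_exposure:
        thr = np.quantile(x, 1.0 - scenario.exposure_case_fraction)
        exposure = (x > thr).astype(np.float64)
    direct = genotypes[:, effects.invalid] @ effects.alpha[effects.invalid]
    y = scenario.beta_causal * x + direct + c_u * u + rng.standard_normal(n)
    if scenario.binary_outcome:
        thr = np.quantile(y, 1.0 - scenario.outcome_case_fraction)
        y = (y > thr).astype(np.float64)
    return TraitSample(
        genotypes=genotypes,
        exposure=exposure,
        outcome=y,
        exposure_liability=x,
        realized_h2=realized_h2,
    )


def derive_summary_stats(
    genotypes: np.ndarray,
    trait: np.ndarray,
    panel: VariantPanel,
    *,
    binary: bool = False,
    effect_increasing: np.ndarray | None = None,
) -> list[SummaryRecord]:
    """Per-variant association summary statistics for one trait.

    Continuous traits use simple linear regression per variant (exact
    closed form); binary traits use the logistic score-test approximation
    ``beta = U/V, se = V^{-1/2}`` with ``U = sum (g - gbar)(y - ybar)``
    and ``V = ybar (1 - ybar) sum (g - gbar)^2`` — the convention of
    large consortium case-control GWAS. A monomorphic variant yields a
    record with NaN effect (written as NA) flagged by se = NaN.
    """
    n, m = genotypes.shape
    y = np.asarray(trait, dtype=float)
    gbar = genotypes.mean(axis=0)
    gc = genotypes - gbar
    sxx = np.einsum("ij,ij->j", gc, gc)
    yc = y - y.mean()
    sxy = gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        if binary:
            ybar = y.mean()
            v = ybar * (1.0 - ybar) * sxx
            beta = sxy / v
            se = v**-0.5
            z = beta / se
            pval = 2.0 * stats.norm.sf(np.abs(z))
        else:
            beta = sxy / sxx
            syy = float(yc @ yc)
            # floor at a tiny positive value: cancellation can push the
            # residual sum fractionally negative in the noiseless limit
            sigma2 = np.maximum((syy - beta * sxy) / (n - 2), 1e-300)
            se = np.sqrt(sigma2 / sxx)
            tstat = beta / se
            pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    eaf = gbar / 2.0
    records = []
    for j in range(m):
        mono = sxx[j] == 0
        records.append(_make_record(panel, j, eaf[j], beta[j], se[j], pval[j], n, mono))
    return records


def _make_record(
    panel: VariantPanel,
    j: int,
    eaf: float,
    beta: float,
    se: float,
    pval: float,
    n: int,
    mono: bool,
) -> SummaryRecord:
    # effect allele is the dosage-counted (exposure-increasing by gamma
    # coding) allele, labelled A; other allele G — synthetic biallelic SNP
    if not mono and np.isfinite(beta) and se > 0:
        return SummaryRecord(
            variant_id=panel.ids[j],
            chrom=panel.chrom[j],
            pos=panel.pos[j],
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf),
            beta=float(beta),
            se=float(se),
            pvalue=float(max(pval, 5e-324)),
            n=float(n),
        )
    # monomorphic: NA-flagged record (bypasses the se > 0 invariant on purpose)
    rec = SummaryRecord.__new__(SummaryRecord)
    for name, value in (
        ("variant_id", panel.ids[j]),
        ("chrom", panel.chrom[j]),
        ("pos", panel.pos[j]),
        ("effect_allele", "A"),
        ("other_allele", "G"),
        ("eaf", float(eaf)),
        ("beta", float("nan")),
        ("se", float("nan")),
        ("pvalue", float("nan")),
        ("n", float(n)),
    ):
        object.__setattr__(rec, name, value)
    return rec


@dataclass
class StudyData:
    """Everything one replicate produces."""

    panel: VariantPanel
    effects: EffectSet
    exposure_stats: list[SummaryRecord]
    outcome_stats: list[SummaryRecord]
    realized_h2_exposure: float
    exposure_ids: tuple[str, ...] = ()
    outcome_ids: tuple[str, ...] = ()


def simulate_study(scenario: Scenario, seed: int | None = None) -> StudyData:
    """One full two-sample replicate: draw the panel and effects once,
    then two disjoint samples — exposure associations from the first,
    outcome associations from the second."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    panel = draw_variant_panel(scenario, rng)
    effects = draw_effects(scenario, panel, rng)
    gx = simulate_genotypes(panel, scenario.n_exposure_sample, rng)
    sx = simulate_traits(gx, effects, scenario, rng)
    gy = simulate_genotypes(panel, scenario.n_outcome_sample, rng)
    sy = simulate_traits(gy, effects, scenario, rng)
    exposure_stats = derive_summary_stats(
        gx, sx.exposure, panel, binary=scenario.binary_exposure
    )
    outcome_stats = derive_summary_stats(
        gy, sy.outcome, panel, binary=scenario.binary_outcome
    )
    return StudyData(
        panel=panel,
        effects=effects,
        exposure_stats=exposure_stats,
        outcome_stats=outcome_stats,
        realized_h2_exposure=sx.realized_h2,
        exposure_ids=tuple(f"E{i}" for i in range(scenario.n_exposure_sample)),
        outcome_ids=tuple(f"O{i}" for i in range(scenario.n_outcome_sample)),
    )


def simulate_cohort(
    scenario: Scenario,
    panel: VariantPanel,
    effects: EffectSet,
    rng: np.random.Generator,
    *,
    score_effect: float = 0.0,
    phenotypes: Sequence[str] = ("pheno",),
) -> CohortTable:
    """A third, disjoint individual-level sample for the risk-score arm.

    Each phenotype is ``score_effect`` times the (true-gamma) genetic
    score plus covariate effects and unit noise; covariates are genotyping
    batch, age, sex, BMI, systolic blood pressure and two ancestry PCs.
    """
    n = scenario.n_cohort
    g = simulate_genotypes(panel, n, rng)
    gscore = g @ effects.gamma
    batch = rng.integers(0, 2, n).astype(float)
    age = rng.normal(60.0, 7.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.0, n)
    sbp = rng.normal(135.0, 15.0, n)
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)
    pheno = {}
    for name in phenotypes:
        pheno[name] = (
            score_effect * gscore
            + 0.02 * (age - 60.0)
            + 0.1 * sex
            + 0.05 * batch
            + rng.standard_normal(n)
        )
    ids = [f"C{i}" for i in range(n)]
    dosages = pd.DataFrame(g, index=pd.Index(ids, name="IID"), columns=list(panel.ids))
    phe = pd.DataFrame(
        {
            **pheno,
            "batch": batch,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "sbp": sbp,
            "pc1": pc1,
            "pc2": pc2,
        },
        index=pd.Index(ids, name="IID"),
    )
    counted = {vid: "A" for vid in panel.ids}
    return CohortTable(dosages=dosages, counted_alleles=counted, pheno=phe)


# ---------------------------------------------------------------------------
# Presets and config serialization
# ---------------------------------------------------------------------------


def scenario_presets() -> dict[str, Scenario]:
    """Named study designs used throughout the test-bench.

    * ``null`` — no causal effect, no pleiotropy.
    * ``causal_valid`` — causal effect 0.14 (log 1.15), all instruments valid.
    * ``balanced_pleiotropy`` — half the instruments carry direct effects
      with mean zero (InSIDE holds).
    * ``directional_pleiotropy_inside`` — half carry positive-mean direct
      effects, still independent of instrument strength.
    * ``median_robust`` — 30% invalid weight with strong directional
      direct effects, the regime where the weighted median stays
      consistent while IVW is biased.
    * ``clump_test`` — dense LD blocks for exercising clumping and proxy
      search.
    """
    return {
        "null": Scenario(beta_causal=0.0, seed=101),
        "causal_valid": Scenario(beta_causal=0.14, seed=202),
        "balanced_pleiotropy": Scenario(
            beta_causal=0.0,
            pleiotropy_mode="balanced",
            pleiotropy_sd=0.015,
            invalid_fraction=0.5,
            seed=303,
        ),
        "directional_pleiotropy_inside": Scenario(
            beta_causal=0.0,
            pleiotropy_mode="directional",
            pleiotropy_mean=0.05,
            pleiotropy_sd=0.015,
            invalid_fraction=0.95,
            seed=404,
        ),
        "median_robust": Scenario(
            beta_causal=0.14,
            pleiotropy_mode="directional",
            pleiotropy_mean=0.05,
            pleiotropy_sd=0.01,
            invalid_fraction=0.3,
            n_exposure_sample=10_000,
            n_outcome_sample=10_000,
            seed=505,
        ),
        "clump_test": Scenario(
            n_variants=24,
            ld_blocks=((4, 0.8), (4, 0.5), (3, 0.95), (2, 0.3)),
            n_exposure_sample=5_000,
            n_outcome_sample=5_000,
            seed=606,
        ),
    }


def scenario_to_dict(scenario: Scenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["maf_range"] = list(scenario.maf_range)
    d["ld_blocks"] = [list(b) for b in scenario.ld_blocks]
    return d


def scenario_from_dict(d: dict) -> Scenario:
    d = dict(d)
    d["maf_range"] = tuple(d.get("maf_range", (0.05, 0.5)))
    d["ld_blocks"] = tuple(tuple(b) for b in d.get("ld_blocks", ()))
    return Scenario(**d)


__all__ = [
    "Scenario",
    "VariantPanel",
    "EffectSet",
    "TraitSample",
    "StudyData",
    "draw_variant_panel",
    "draw_effects",
    "simulate_genotypes",
    "simulate_traits",
    "derive_summary_stats",
    "simulate_study",
    "simulate_cohort",
    "ld_pairs_from_panel",
    "scenario_presets",
    "scenario_to_dict",
    "scenario_from_dict",
]
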