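# Methods

`mrkit` implements a two-sample Mendelian randomization (MR) analysis
pipeline of the kind used to ask whether a cardiometabolic exposure (the
motivating application is type 2 diabetes) causally affects downstream
phenotypes such as cerebral small vessel disease markers: lacunar stroke,
intracerebral hemorrhage, white matter hyperintensity volume, and
diffusion-tensor metrics (fractional anisotropy, mean diffusivity). This
note records the models, the numerical conventions, and the design
choices made where the design was genuinely open.

## The two-sample MR model

Each instrument j is a genetic variant with an estimated per-allele
association with the exposure, (β̂_Xj, σ_Xj), from one GWAS sample, and
with the outcome, (β̂_Yj, σ_Yj), from a non-overlapping sample. Under the
instrumental-variable assumptions the per-variant Wald ratio
θ̂_j = β̂_Yj / β̂_Xj estimates the causal effect β. The estimators:

* **IVW.** β̂ = Σ w_j θ̂_j / Σ w_j with w_j = s_j⁻², s_j = σ_Yj/|β̂_Xj|
  (first-order SE, exposure-side error ignored — standard practice with
  strong instruments, and the reason for the small attenuation discussed
  under *Known limitations*). Fixed-effect SE (Σ w_j)^(−1/2); an optional
  multiplicative random-effects flag inflates the SE by
  max(1, √(Q/(J−1))), Q being Cochran's statistic about β̂. Identical to
  the origin-constrained WLS slope of β̂_Y on β̂_X with weights σ_Yj⁻²; the
  test-bench asserts agreement of three routes to 1e-10.
* **Weighted median.** The 50th percentile of the weighted empirical
  distribution of ratios, interpolating linearly between order statistics
  at cumulative-weight midpoints p_j = Σ_{k≤j} w′_k − w′_j/2; consistent
  when instruments carrying <50% of weight are invalid. SE by parametric
  bootstrap: θ*_j ~ N(θ̂_j, s_j), weights fixed, n_boot = 1000 by default,
  seed mandatory in the pipeline config.
* **Penalized weighted median.** One-step down-weighting of
  heterogeneity outliers: q_j = w_j (θ̂_j − θ̂_WM)², one-sided χ²(1) tail
  p_j, penalized weights w_j · min(1, 20 p_j). The penalty constant 20
  follows the originating construction. Note the limit "scale → ∞
  recovers the plain weighted median" holds only while the χ² tail is
  representable; a gross outlier whose tail probability underflows to 0
  stays excluded at any scale.
* **MR-Egger.** WLS of β̂_Y on β̂_X with an unconstrained intercept,
  weights σ_Yj⁻², after orienting every instrument so β̂_Xj ≥ 0 (the
  ratio is orientation-invariant; the intercept is not). The intercept
  estimates average directional pleiotropy under InSIDE; the slope the
  causal effect. SEs use the unscaled WLS covariance times
  max(1, σ̂_resid) — overdispersion from pleiotropy widens the intervals,
  underdispersion is not rewarded — and p-values use Student t with J−2
  df. IVW and median p-values use the normal reference; these follow the
  originating methods' conventions and are stated here because they are
  otherwise an arbitrary choice.

95% CIs use the fixed multiplier 1.959964 (normal) or the t quantile
where the t reference is declared. For binary outcomes estimates
exponentiate to odds ratios; for continuous outcomes both the raw linear
estimate and its exponential are reported, labelled, without asserting
which scale a given publication used.

## Harmonization

Outcome records are aligned to the exposure effect allele: direct match,
swapped alleles (negate β, flip frequency), or strand complement.
Palindromic variants (A/T, G/C) cannot be resolved by labels; they are
oriented by effect-allele frequency when both samples' frequencies fall
outside the ambiguity window [0.42, 0.58] (the conventional zone,
configurable) and dropped otherwise. Missing outcome variants are
replaced by the available proxy with the highest r² strictly above 0.7;
ties break by smaller pair distance, then variant id. Instrument
independence is enforced by greedy clumping: visit variants by ascending
p-value (ties: position, then id), retain, and remove same-chromosome
variants within 100 kb whose r² is strictly above 0.1. Both thresholds
are strict inequalities, matching the conventional "r² > 0.7" / "r² >
0.1" phrasing; the window is |pos_a − pos_b| ≤ 100 kb between variant
positions (PLINK convention). Unknown r² counts as 0 with a logged
warning so sparse LD tables never stall the clump. An LD table carries
no correlation sign, so a substituted proxy assumes positively phased
LD; the synthetic generator produces positively phased blocks, making
the assumption exact there.

## Genetic risk score arm

S_i = Σ_j ln(OR_j) · G_ij over the instrument set, G the effect-allele
dosage (realigned as 2 − G when the cohort file counts the other
allele). Missing dosages are mean-imputed — 2·EAF from the weights file
when present, else the cohort mean — preserving the score's expectation.
Associations with continuous phenotypes use OLS with covariate
adjustment (default covariate set: genotyping batch, age, sex, BMI,
blood pressure, ancestry PCs) and listwise deletion of incomplete rows
(counts logged). Quartile contrasts regress the phenotype on indicators
for quartiles 2–4 with quartile 1 as reference; quartile boundaries use
the type-7 (linear interpolation) quantile rule with ties assigned to
the lower quartile — stated explicitly because no rule is canonical.
Phenotype columns are used as supplied; any log or z transform is the
caller's choice. The diffusion phenotype is the first principal
component of per-tract means: correlation-based PCA (so per-tract
scaling is irrelevant), zero-variance tracts dropped with a warning,
eigenvector sign fixed by positive loading sum, projection rescaled to
unit variance.

## The synthetic generator

The generator exists so every stage can be validated against known
ground truth; its defaults are the emulated study's conditions: 84
instruments, target instrument h² = 0.075 (within the 5–10% range such
instrument panels explain), GWAS samples of 50 000 per trait, an
individual-level cohort of 8357, MAF uniform on [0.05, 0.5]. Per
individual,

    X = Σ_j γ_j G_j + c_U·U + ε_X,   Var(X) = 1
    Y = β·X + Σ_{j∈invalid} α_j G_j + c_U·U + ε_Y

with U a shared standard-normal confounder (loading 0.3 — confounding is
the scenario MR exists to defeat, so the generator must include it).
Genotypes are Binomial(2, f); LD blocks share an allele frequency and
copy a latent block haplotype with probability r2^(1/4), giving every
within-block pair the target r² in expectation (equicorrelated,
positively phased; unequal frequencies in a block are rejected because
the target correlation can be infeasible). Binary traits threshold a
liability at the case fraction (default 10%); their summary statistics
use the per-variant logistic score-test approximation (U/V with
V = ȳ(1−ȳ)·S_gg), the large-sample convention of consortium
case-control GWAS. Continuous traits use exact per-variant simple
regression.

Instrument effects are drawn γ_j ∝ 1 + |N(0, 1)|, then rescaled so
Σ γ_j² · 2f_j(1−f_j) equals the target h² exactly in expectation (the
realized h² is reported per replicate). Two deliberate departures from
a plain normal draw, both reflecting how instrument panels are built:
effect alleles are coded exposure-increasing (risk-allele convention of
published instrument lists), and the additive strength floor keeps the
generator from emitting effectively null instruments — panels contain
only robustly associated variants, and near-null instruments have
coin-flip estimated signs whose orientation errors corrupt the Egger
intercept (a flipped invalid instrument is a high-leverage point at
x ≈ 0, y ≈ −μ). Direct effects α_j ~ N(μ, τ²) are drawn independently
of γ on a random invalid subset, so InSIDE holds by construction;
balanced mode has μ = 0, directional μ > 0.

Preset scenarios fix the study designs used by the test-bench: `null`
(β = 0), `causal_valid` (β = 0.14 ≈ log 1.15, all instruments valid),
`balanced_pleiotropy` (τ = 0.015, half the instruments invalid),
`directional_pleiotropy_inside` (μ = 0.05, τ = 0.015, 95% of
instruments invalid — the classical directional-InSIDE construction in
which essentially every instrument carries a positive-mean direct
effect; with a 50/50 split the valid/invalid bimodality itself inflates
the Egger residual variance and caps intercept power near
√(J/(1 + x̄²/var x̄)), so the near-complete invalid set is what makes
the preset exhibit cleanly detectable directional pleiotropy),
`median_robust` (30% invalid with strong
directional effects, μ = 0.05, at reduced samples of 10 000 — the
regime where the weighted median stays near the truth while IVW is
badly biased), and `clump_test` (dense LD blocks). Replicate studies in
the test-bench use 400–2000 replicates with per-replicate seeds spawned
from one base seed; the type-I-error study runs the null design at
samples of 10 000 per trait.

What the generator does **not** emulate: realistic human LD maps,
population structure and relatedness, genotyping/imputation error,
winner's-curse bias in the instrument weights, and sample overlap
between the two GWAS. Passing tests therefore validate the estimators
and plumbing under a clean causal diagram, not robustness to those
real-data pathologies.

## Numerical choices and degenerate inputs

Floats are written with `repr` so file round-trips are bit-exact. A
residual variance that cancellation drives fractionally negative in the
noiseless limit is floored at 1e-300. Monomorphic variants yield
NA-flagged records that readers reject row-wise (row counts always
satisfy accepted + rejected = total). Zero exposure effects exclude an
instrument from ratio estimation with a logged reason. The weighted
median returns the extreme order statistic when 0.5 falls outside the
midpoint range, and the exact order statistic when a midpoint hits 0.5.
Egger refuses singular designs (all β̂_X equal after orientation) and
fewer than 3 instruments; the median estimators likewise need 3. Rank
deficiency in GRS regressions raises an error naming the collinear
columns. All randomness flows through numpy Generators seeded from
explicit arguments; identical seed + scenario reproduces outputs
byte-identically.

## Known limitations

* First-order ratio SEs ignore exposure-side sampling error. The
  matching first-order phenomenon is weak-instrument regression
  dilution: with m instruments and exposure sample n, IVW is attenuated
  by roughly 1/(1 + m/(n·h²)) — about 2% (measured 2–4%) under the
  `causal_valid` design. This is inherent to IVW as practiced, visible
  in the calibration study's mean estimate, and the reason the
  mean-recovery check is the strictest in the test-bench.
* The multiplicative random-effects/overdispersion treatment models
  heterogeneity as proportional to per-instrument variances; strongly
  additive pleiotropy heterogeneity is only approximately captured.
* Proxy substitution assumes positive LD phasing (no signed LD input).
* The quartile tie rule can empty a quartile when scores are heavily
  discrete; this raises an explicit error rather than silently merging
  groups.
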