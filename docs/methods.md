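# Methods

## The causal model

`mrkit` implements two-sample Mendelian randomization (MR) from GWAS summary
statistics. The underlying structural model for a variant *i* with genotype
dosage Gᵢ ∈ {0, 1, 2}, exposure X, outcome Y, and unobserved confounder U is

    X = γᵢ Gᵢ + ξₓ U + eₓ
    Y = β X + αᵢ Gᵢ + ξᵧ U + eᵧ

so the reduced-form variant-outcome effect is Γᵢ = αᵢ + β γᵢ. β is the causal
effect of interest; γᵢ is instrument strength; αᵢ is horizontal pleiotropy (a
direct path from variant to outcome). A variant is a valid instrument when it
is relevant (γᵢ ≠ 0), exclusion-restricted (αᵢ = 0), and exchangeable (Gᵢ ⊥ U).
The weaker InSIDE condition — αᵢ distributed independently of γᵢ — is what
MR-Egger needs instead of exclusion.

Estimation uses only per-variant summary pairs (γ̂ᵢ, se(γ̂ᵢ)) from an exposure
GWAS and (Γ̂ᵢ, se(Γ̂ᵢ)) from a disjoint outcome GWAS, harmonized to a common
effect allele. Throughout, weights are wᵢ = 1/se(Γ̂ᵢ)²; uncertainty in γ̂ᵢ is
ignored by the estimators (the usual summary-data treatment; with the strong
instruments the selection stage admits, the attenuation this causes is a
fraction of a percent).

* **Wald ratio**: β̂ᵢ = Γ̂ᵢ/γ̂ᵢ, SE by the first-order delta method
  se(Γ̂ᵢ)/|γ̂ᵢ|. A second-order SE adding the γ̂ uncertainty term is available
  behind a flag.
* **IVW**: β̂ = Σ wᵢ γ̂ᵢ Γ̂ᵢ / Σ wᵢ γ̂ᵢ², the wᵢγ̂ᵢ²-weighted average of the Wald
  ratios and identically the no-intercept weighted regression of Γ̂ on γ̂.
  Fixed-effect SE (Σ wᵢ γ̂ᵢ²)^(−1/2).
* **MR-Egger**: weighted regression Γ̂ᵢ = β₀ + β γ̂ᵢ after flipping pairs so
  every γ̂ᵢ ≥ 0 (the intercept's sign is otherwise convention-dependent). β₀
  estimates average directional pleiotropy; β₀/se(β₀) is the pleiotropy test.
  With β₀ constrained to zero the slope reduces to IVW — kept as an explicit
  option because it is a sharp numerical cross-check.
* **Cochran's Q**: Q = Σ wᵢ (Γ̂ᵢ − β̂₀·[Egger] − β̂ γ̂ᵢ)² about the fixed-effect
  fit, χ² with L−1 (IVW) or L−2 (Egger) df under homogeneity.
* **Random effects**: multiplicative overdispersion — SEs scaled by
  max(1, √(Q/df)). The point estimate is unchanged and the random-effect SE
  can never fall below the fixed-effect SE.

Inference is normal-theory by default (CIs β̂ ± z·se); Student-t with L−2 df
is available for Egger via `df_policy="t"`. The published intervals this
package reproduces are ±1.96·se intervals, while the published Egger p-value
is consistent with the t reference — hence the split default.

## Instrument selection and harmonization

Selection keeps exposure variants with p strictly below 5×10⁻⁸ (configurable).
Gene-level validation guards against winner's curse/selection bias: a gene
counts as replicated when it holds a genome-wide-significant variant in the
main exposure GWAS *and* in at least one additional exposure GWAS; instruments
outside replicated genes are dropped. Genes rather than variants are compared
because independent GWASs rarely type identical SNPs. Greedy p-ordered pruning
then enforces pairwise r² < 0.001 (default), keeping the most significant
variant of each correlated group; ties break by (chrom, pos) then id.
Variants absent from the LD matrix pass through with an audit flag rather than
being dropped — an incomplete LD input should not silently shrink the
instrument set.

Harmonization aligns the outcome record to the exposure's effect allele:
matching orientation is kept, swapped labels negate the outcome effect, and
reverse-complement pairs are strand-flipped first. Palindromic variants (A/T,
C/G) carry no strand information in their letters; by default they are
oriented by minor-allele matching (`infer_by_eaf`) and removed when either
frequency lies within 0.08 of 0.5 or is missing (the `drop` policy removes
them all). The recorded `action` names the net numeric transformation.
Removals are never silent: the report partitions the instrument set into kept
and removed-with-reason.

## Outlier screen

The screen is an independent implementation of the simulation-based
(MR-PRESSO-style) global heterogeneity and outlier test. Observed statistic:
RSS = Σ wᵢ (Γ̂ᵢ − β̂₍₋ᵢ₎ γ̂ᵢ)² with β̂₍₋ᵢ₎ the leave-one-out fixed IVW estimate.
Each of n_sim (default 1000) parametric replicates redraws
Γ̂ᵢ* ~ N(β̂₍₋ᵢ₎ γ̂ᵢ, se(Γ̂ᵢ)²) and recomputes the statistic with its own
leave-one-out fits. The global p-value is the +1-corrected rank
(1 + #{RSS* ≥ RSS})/(n_sim + 1), so it can never be zero; per-variant
p-values rank each observed term against its simulated distribution.

Design choices: a variant is flagged only when the global test rejects *and*
its Bonferroni-adjusted per-variant p-value clears the threshold (default
0.05). Gating on the global test follows the cited procedure's own usage and
keeps the family-wise false-flag rate well below the nominal level; ungated
Bonferroni flagging would sit exactly at it. The distortion test of the
original procedure is not implemented (the analyses here refit after removal
explicitly instead); manual removal of the extreme Wald ratios is exposed as
a separate, clearly-labelled pipeline option (`drop_extreme_wald`) because
forest-plot-based outlier removal is an analyst judgement, not a test. The
seed is a mandatory part of the configuration — the screen is the pipeline's
only stochastic stage.

## The synthetic-data generator

The generator exists so every stage is testable without GWAS downloads. It
emulates the study design of a menarche-timing → pubertal-growth analysis:
a large exposure GWAS, a much smaller outcome GWAS, replicate exposure GWASs
for validation, gene annotations, and block LD.

Defaults (chosen once as the study conditions):

| parameter | default | why |
|---|---|---|
| `n_exposure` | 182,413 | exposure-GWAS scale being emulated |
| `n_outcome` | 5,756 | outcome-GWAS scale being emulated |
| `n_snps` | 1000 | enough nulls to exercise selection at desk scale |
| `gamma_dist` | 5% non-null, \|γ\| ∈ [0.08, 0.15] SD/allele | planted instruments clear 5×10⁻⁸ at the exposure n with near-certainty; nulls essentially never do |
| `maf_range` | (0.05, 0.5) | common variants, as instrument panels are |
| `alpha_dist` | `none` | exclusion restriction holds unless a test asks otherwise |
| `xi_x`, `xi_y` | 0.3 | moderate confounding, enough to bias naive regression |
| `confounder_sd`, `e_x_sd`, `e_y_sd` | 1.0 | unit scale; traits are in SD units (nominally years / cm) |
| `beta` | 0.5 | the causal effect recovered throughout the test suite |
| `palindromic_fraction` | 0.2 | exercises the harmonization policies |
| `ld_block_size`, `ld_within_r2` | 5, 0.3 | gives pruning and gene-validation real work |

Two generation paths share the same per-seed truth. The individual-level path
draws genotypes (binomial, or blockwise-correlated through a Gaussian-copula
threshold construction), builds X and Y from the structural equations in two
disjoint cohorts, and runs per-variant least-squares regressions — the
two-sample design holds by construction. The summary-direct path draws
γ̂ᵢ ~ N(γᵢ, seᵢ²) and Γ̂ᵢ ~ N(αᵢ + βγᵢ, seᵢ²) with the asymptotic SE
√(var(trait)/(n·2·maf·(1−maf))) and is used for calibration at scale; the
test suite verifies the two paths agree in distribution.

Numerical notes on the copula LD: the latent correlation is solved per block
from the bivariate-normal orthant probability so that the thresholded-allele
correlation hits √r²; variants within a block share their MAF (tight blocks
do in reality, and the calibration is exact only when frequencies match).
Block-mean empirical r² lands within ±0.1 of the target; individual pairs
scatter somewhat wider. Between-block r² is exactly zero, which real genomes
only approximate.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: realistic allele-frequency spectra and
polygenicity, sample overlap between the two GWASs, population stratification,
assortative mating, cryptic relatedness, imputation error, or winner's curse
beyond what explicit selection induces. Tests show the machinery is correct
under the stated model, not that the model is a complete account of any real
pair of cohorts.

## Problem sizes and determinism

Simulation-backed tests use 100–500 replicates at 20–50 instruments
(summary-direct) or cohorts of 500–50,000 (individual-level), sizes at which
every Monte-Carlo assertion has comfortable margin; the acceptance script
uses 500 replicates for estimator calibration, 2×50 seeded runs of the
outlier screen, and one full cohort-level pipeline run. All randomness flows
from explicit seeds (`numpy.random.default_rng`); reruns are bit-identical,
and the hypothesis property tests run derandomized.

## Known limitations

* Weighted-median, mode-based, and multivariable MR estimators are out of
  scope, as are Steiger filtering, radial MR, and proxy-variant lookup.
* Var(Γ̂ᵢ) is the squared reported SE; no second-order or overlap-corrected
  variance.
* The pipeline assumes biallelic SNVs; indels and multi-character alleles are
  rejected at parse time.
* LD pruning requires an externally supplied r² matrix; there is no clumping
  against a genotype reference panel, and no coordinate-based gene
  annotation — the gene map is an input.
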