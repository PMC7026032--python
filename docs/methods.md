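# Methods

`grsmr` implements an individual-level Mendelian-randomisation (MR) analysis
of three behavioural exposures — neuroticism, educational attainment and
habitual physical activity — on a 1–6 job-satisfaction outcome, together
with a synthetic biobank-style cohort generator that reproduces the
statistical structure such an analysis assumes. This note records the
models, the calibration of the generator, the estimator conventions, and the
choices made where the design was genuinely open.

## Structural model of the synthetic cohort

Genotypes. Each trait has a panel of biallelic SNPs (defaults 136, 70 and
22 variants). Effect-allele frequencies are drawn uniformly from
`maf_range` (default (0.05, 0.5]) and dosages from Binomial(2, p) —
Hardy–Weinberg equilibrium, no linkage disequilibrium. Missing calls are
applied completely at random at `missing_genotype_rate` (default 0);
ambiguous-strand allele pairs (A/T, C/G) are avoided by construction.

Exposures. With S_j the population-standardised unweighted GRS of trait j,
U an unmeasured standard-normal confounder and F a latent factor vector
with correlation matrix R (`exposure_correlation`):

    X_j = sqrt(r_j) S_j + c_j U + sqrt(1 − r_j − c_j²) F_j

so each latent exposure has unit variance. Each latent is then mapped
monotonically to its questionnaire-style field:

* neuroticism: quantile binning onto 0–12 with a Binomial(12, 0.35)
  marginal (right-tailed, EPQ-N-like);
* education: six ordered qualification categories (population shares
  0.17/0.26/0.12/0.22/0.05/0.18), later mapped to leaving ages 15–21;
* physical activity: a log-normal weekly MET total
  (max(exp(7.2 + X₃) − 30, 0)), decomposed into walking/moderate/vigorous
  days (1–7) and minutes at fixed 0.4/0.4/0.2 MET shares with IPAQ
  coefficients 3.3/4.0/8.0.

Calibration on the analysis scale. `target_r2` (defaults 0.0114, 0.0063,
0.0003 — the variance-explained presets of the emulated study) is defined
as the R² of the *observed z-scored trait* on its GRS, because that is the
quantity the analysis measures. Discretisation attenuates the
latent–observed correlation (λ ≈ 0.983 for the 13-level neuroticism
binning, ≈ 0.935 for the 6-category education mapping, ≈ 0.999 for the MET
transform), so the latent GRS share is set to `target_r2 / λ²`, with λ
computed in closed form from truncated-normal moments (Gauss–Hermite
quadrature for the MET map). Rounding of questionnaire minutes contributes
a further, negligible attenuation that is not compensated.

Outcome. The latent outcome acts on the standardised *observed* exposures
(the analysis scale), so `true_effects` is exactly the estimand the MR
stages target:

    Y = Σ_j β_j X̃_j + c_y U + Σ_{v invalid} δ (d_v − 2 p_v)
        + γ_age (age − 55) + γ_sex sex + γ_tdi TDI + ε

Defaults: β = (−0.31, 0, 0); confounder loadings c = (0.2, 0.2, 0.2) on the
exposures and c_y = 0.3 on the outcome, giving an observational
(omitted-variable) bias of ≈ +0.06 per exposure — mirroring the emulated
study's gap between its observational (−0.25) and causal (−0.31)
neuroticism estimates; γ are small covariate effects (0.004/yr, 0.05,
0.02) so covariate adjustment is non-trivial. ε is scaled so the latent
outcome has unit variance (floor 0.5 SD). Under `outcome_scale="likert6"`
the latent outcome is discretised onto {1..6} by fixed quantile cut-points
(marginal 2/4/9/25/40/20%); this attenuates every regression coefficient
multiplicatively, so parameter-recovery work uses the default continuous
scale. Unemployed participants (employment ~ Bernoulli(0.8)) get a missing
outcome. Pleiotropic ("invalid") variants are the first `n_invalid` of a
panel and add a direct per-allele effect δ (`invalid_effect`, default 0.05)
to the outcome.

Covariates and attrition. Age ~ U(37, 73) years; sex ~ Bernoulli(0.53)
(1 = female); ten assessment centres with fixed unequal shares; TDI
Gumbel-shaped (mean ≈ −1.3, right-skewed); BMI log-normal around 27 kg/m².
The six exclusion flags (consent withdrawal, sex mismatch, relatedness,
non-British ancestry, ICD-10 mental/neurological history, missing
neuroticism) are independent Bernoullis whose default rates reproduce the
emulated study's attrition fractions. The source study gives no
distribution for TDI or centre sizes; those defaults are stated here as
the package's own choices and are configurable.

All randomness flows from one integer seed; each component (genotypes,
exposures, covariates, outcome) draws from a deterministic sub-stream, so a
fixed seed yields a bit-identical cohort.

## Phenotype derivation

Performed in the study's order: (1) the exclusion cascade, attributing a
multiply-flagged participant to the earliest-listed criterion; (2) the
±3.29 z-score rule applied once to each raw activity duration over
non-missing eligible rows — values strictly beyond the threshold are set
missing while the participant is retained (the alternative, dropping the
row, is configurable); (3) MET-minutes/week = 3.3·walk + 4.0·moderate +
8.0·vigorous (days × minutes), where "days" counts questionnaire days with
≥10-minute bouts per IPAQ short-form scoring; (4) qualification → leaving
age via a configurable mapping (default none→15, CSE/GCSE→16, A-level→18,
NVQ/HND→19, other professional→20, degree→21); (5) job satisfaction set
missing for the unemployed and for declined answers; (6) natural-log
transforms — log(BMI), log(MET + 1) so zero activity is representable —
and z-scores computed on the post-exclusion analysis sample with the n−1
divisor. The neuroticism SD is always computed empirically and reported,
never assumed.

## Risk scores

Unweighted GRS = Σ effect-allele dosages over a trait panel, after (a)
call-rate QC — variants strictly below 90% are dropped, exactly-90% kept —
and (b) effect-allele alignment: a dosage counted on the other allele is
complemented (2 − d); allele-pair mismatches are dropped with a warning
rather than strand-flipped; ambiguous A/T and C/G pairs are dropped in
strict mode. Missing dosages are mean-imputed as 2·EAF (in-sample) by
default, with a drop-per-sample mode provided since scoring tools differ
and the emulated workflow does not state its choice. Variance explained is
the incremental R² of the trait on the GRS over an age+sex baseline, with
the GRS slope and SE reported alongside.

## Estimators

All estimators share one linear-algebra core (QR least squares with
explicit rank checks). Categorical covariates (assessment centre) are
reference-coded against the first sorted level.

OLS. Classical SEs with the n−k divisor.

TSLS. First stage: exposure on instrument(s) + covariates; second stage:
outcome on the predicted exposure + covariates. SEs use the standard IV
correction — residuals from the *observed* exposure,
σ̂² = ‖y − [X, W]β̂‖²/(n−k), and Var(β̂) = σ̂²(Ẑ'Ẑ)⁻¹ with Ẑ the projected
design. The divisor is configurable (`dof="n"` reproduces tools that divide
by n); estimates are divisor-invariant, SEs scale by √((n−k)/n). CIs are
estimate ± 1.96·SE (normal approximation); p-values are two-sided from the
t distribution with n−k dof. No heteroskedasticity-robust option is on by
default.

MVMR. Two instrumenting modes: `own` (default) predicts each exposure from
its own GRS only — the multi-stage procedure natural when there is exactly
one score per trait — and `all` is textbook 2SLS with the full instrument
set. Both are consistent here because instruments are trait-specific; they
differ in finite samples when an instrument is weak (the all-instrument
mode shows the usual many-weak-instrument shift toward the observational
estimate on the weakest exposure).

Diagnostics. The first-stage F is the partial F of the excluded
instrument(s) (equal to the squared first-stage t for one instrument). The
Sanderson–Windmeijer conditional F for exposure j: estimate its relation to
the other exposures by 2SLS with the full instrument set, residualise with
the observed other exposures, regress the residual on all instruments +
covariates, and report the instruments' joint F with numerator degrees of
freedom (#instruments − #exposures + 1). With one exposure this reduces
exactly to the standard F. If an exposure is an exact linear function of
the others the residual vanishes and the conditional F is reported as 0.

## Instrument-validity screen

Each variant is tested for (a) association with its trait
(trait ~ SNP + age + sex) and (b) direct association with the outcome
(outcome ~ SNP + trait + age + sex + centre + TDI; a minimal age/sex
adjustment is available since the emulated covariate set is not fully
enumerated). Retention requires p_trait < 0.05 and p_outcome ≥ 0.05 — the
nominal thresholds, with no multiple-testing correction by default (a
Bonferroni switch exists). A zero-variance dosage is excluded as
`weak_with_trait`. The sensitivity GRS is the unweighted score over
retained variants.

## Power

mRnd-style normal approximation for a continuous outcome:
NCP = n·R²_gx·β², power = 1 − Φ(z₁₋α/₂ − √NCP) + Φ(−z₁₋α/₂ − √NCP),
two-sided, with β in standardised units (a converter β·σ_x/σ_y is provided
because raw-scale reports rarely print the outcome SD). `mr_min_n` inverts
the monotone power curve by integer bisection.

## Validation problem sizes

The test suite validates the pipeline at sizes chosen to give Monte-Carlo
error well below the effects being checked: generator moments at
n = 40,000–200,000 single draws; TSLS parameter recovery and CI coverage
over 200 cohorts of n = 20,000 under confounding (observational bias
≈ +0.06); MVMR direct-effect recovery over 200 cohorts of n = 50,000 with
exposure correlation 0.3 and effects (−0.32, 0, 0); rejection-rate
calibration against the analytic power over 1,000 cohorts of n = 2,000;
and the pleiotropy screen over 20 cohorts of n = 50,000 with 10 invalid
variants planted among 136. For the screen, the panel R² is set to 0.08 so
each variant's trait test has power ≈ 0.999 (per-variant NCP ≈ 29),
making expected valid retention ≈ 0.95 — the "strongly trait-associated"
regime — while δ = 0.10 gives the outcome test on planted variants a
worst-case NCP ≈ 47 even at the minimum allele frequency (2pq ≈ 0.095),
i.e. exclusion power ≈ 1 across all 200 planted-variant tests. These
constants follow from the non-central F/t power calculation at the least
favourable allele frequency, not from tuning against observed runs.

## Known limitations

The generator omits linkage disequilibrium, imputation uncertainty, family
structure, genotyping batch effects, assortative mating and
population stratification; instruments are valid by construction except
for the explicitly planted pleiotropic variants, so passing recovery tests
demonstrates estimator correctness under the stated model, not robustness
to real-data violations. The likert6 outcome attenuates coefficients and
is not used as an estimation target. Two-sample summary-statistic MR
estimators (IVW, MR-Egger, median, PRESSO), non-linear MR and
binary-outcome power are out of scope.
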