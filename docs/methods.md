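# Methods

This note documents the models behind `lifeclocks`: what the synthetic
generator simulates and why, how each statistical stage is defined, and the
numerical choices made where the design was genuinely open.  Every number
quoted here is either a configurable default or a quantity the test suite /
`scripts/acceptance.py` computes at run time.

## 1. The synthetic cohort generator

The generator emulates a same-birth-week cohort observed across the life
course and sampled for plasma proteomics in late midlife.

**Demographics and exposure marginals.** Defaults (all in
`lifeclocks.config.CohortConfig`): n = 1803; sampling age ~ N(63.2, 1.1²)
years; 49.4% male.  Exposures reproduce the cohort's published marginal
table: birthweight ~ N(3.35, 0.45²) kg giving 2.9% below the 2.5 kg
low-birthweight line; six-level paternal occupational class with the
published frequencies (the top three classes define "higher childhood
SES"); 63.7% with secondary-school qualifications; adolescent BMI normal
with sex-specific means chosen so 10.5% exceed the overweight cut-offs
(23.5 female / 22.7 male, cut-off inclusive); smoking zero-inflated (35%
never-smokers; ever-smokers split 35/65 into ceased-by-43 vs continued,
with gamma pack-year intensities of mean 4 and 21.3 yielding a marginal
mean of 9.9 and SD ≈ 15 pack-years); alcohol log-normal at four adult
timepoints with a persistent person effect (per-timepoint mean 16.8, SD
15.0 units/week; within-person correlation ≈ 0.7); the number of active
timepoints (0–4) and the number of life periods with adversity (0–4) drawn
from the published distributions, with period-specific adversity components
(overcrowding, childhood illness, unemployment, divorce, conflict with
children, work crisis, social isolation, financial troubles) attached to
flagged periods.

**Dependence structure.** The joint distribution of exposures is not
published, so exposures share a single-factor Gaussian copula with
equicorrelation ρ = 0.15, oriented so that disadvantage clusters (lower
SES, less education, lower birthweight, higher BMI, more smoking, less
activity, more adversity).  This is a stand-in for an unknown joint
distribution, not an inference; analyses that require a correctly specified
regression therefore include the other planted exposures as covariates.

**Latent organ ages.** For each clock c,

    A_ic = age_i + Σ_e β_{e,c}·x_{ie}/u_e + F_i + T_i·1[c ∈ triad] + ε_ic

with shared frailty F ~ N(0, 2²) years, organ noise ε ~ N(0, 3.5²), and an
extra shared factor T ~ N(0, 1.2²) tying brain, immune and liver ageing —
the organ trio observed to co-occur most.  These variance components put
every pairwise organ age-gap correlation below the observed ceiling of 0.4
while matching the reported extreme-ager prevalences (~44% with ≥ 1
extreme organ, ~16–17% with ≥ 2) — both are recomputed, not asserted.
Planted effect magnitudes β default to the published regression
coefficients (+1.13 y adolescent overweight, −0.52 y education, −0.79 y
sustained activity, +0.59 y per 20 pack-years on the Conventional, liver,
kidney and immune clocks; −0.27 y per 7 units/week alcohol on the brain
clock; the six adversity components on the Conventional clock), with unit
scales u_e of 20 pack-years and 7 units/week.

**Protein panel.** Each organ contributes p proteins (default 40/organ —
a deliberate scale-down of the real 201-brain/103-liver panel; counts are
configurable).  Protein j of organ o has
log₁₀ RFU = bⱼ + lⱼ·A_io + ηⱼ, with baselines bⱼ ~ U(3, 4) (RFU 10³–10⁴),
loadings lⱼ ~ U(0.004, 0.02) per year and assay noise η ~ N(0, 0.02²).
The *true clock* shipped with the panel uses reference means bⱼ + lⱼ·63.2,
reference SDs √((lⱼσ_A)² + σ_η²) and weights wⱼ = σⱼ/(p·lⱼ), so that the
clock prediction equals A + (1/p)Σⱼ ηⱼ/lⱼ — exact inversion when σ_η = 0
(the clock oracle) and ~0.3–0.8 y of clock noise at the defaults.
Zero-loading proteins get weight 0.  The raw matrix is divided by
per-protein scaling factors ~ U(0.5, 2), which the clock engine must
re-apply — mirroring the assay-version scaling step — and four extra
QC-flagged dummy samples mirror the real 1807 → 1803 exclusion.

**Mortality.** Event times follow a proportional-hazards model with
exponential baseline (Gompertz optional; both invert in closed form).  The
linear predictor sums per-clock gap coefficients (defaults put the largest
weight on heart ageing), an optional per-extreme-organ gradient and an
optional protective-factor term; the baseline is calibrated by root-finding
so the expected death fraction is 15.6% over the 15.1-year horizon.
Observed death times are recorded at month resolution (deaths dated to
month and year), censoring is administrative at the horizon, and a
`logistic` mode draws a death-by-horizon indicator instead of times when a
planted odds ratio is the relevant truth.  The generator plants no direct
PFS → mortality path — protection acts entirely through the organ gaps —
so organ-specific proportions mediated on default synthetic data are larger
than the real-data values; mediation recovery is instead tested against an
explicitly planted pathway (§5).

**Missingness.** MCAR masks uniformly at the requested rate; MAR masks
through a logistic model on an observed covariate with the intercept
calibrated to preserve the marginal rate.  Outcome, survival and
demographic fields are protected and can never be masked.

**What the generator does not emulate:** assay chemistry and plate
structure, non-linear exposure–age relationships, time-varying hazards,
informative censoring, genetic inheritance of longevity, and any real
biological covariance between specific proteins beyond the latent-age
factor structure.  Passing tests therefore demonstrate correctness of the
*estimators* under the stated generative model, not validity of the
scientific conclusions on real data.

## 2. Clock engine

Clocks are linear models on reference-z-scored transformed abundances
(log₁₀ default, identity selectable per clock file).  Age gaps are raw by
default; an optional cohort-mean centering flag exists because in a
near-constant-age cohort the usual age-trend (LOWESS) re-centering reduces
to a constant shift.  The gap identity (gap = predicted − chronological) is
enforced bit-exactly.

## 3. Extreme agers and heterogeneity

The extreme-ager threshold is the empirical 90th percentile of each clock's
gap distribution, computed with the type-7 (linear-interpolation)
convention; gaps at or above the threshold are flagged, so threshold ties
are resolved inclusively.  A degenerate (constant) distribution warns and
flags nobody.  Multi-organ counts run over the seven organ clocks only —
the Conventional clock is reported separately, and the "two or more organs"
phrasing is read as organs proper.  Co-occurrence tabulates exact flagged
organ sets among participants with ≥ k flags.

## 4. Survival and exposure models

Cox models use Efron tie handling by default (month-resolution death dates
produce many ties; Efron is the less biased approximation), with a damped
Newton retry because undamped steps can overshoot on heavily tied data.  A
Breslow Newton–Raphson solver (analytic gradient/Hessian, SEs from the
inverse information) is included; the two agree exactly when no ties exist.
Wald CIs are computed on the log-hazard scale.  Monotone likelihood /
separation raises an error rather than returning a silent estimate.

Exposure associations are OLS of a clock's age gap on one exposure in its
reporting unit, adjusted for sex, chronological age and childhood SES
(SES is dropped as a covariate when it is itself the exposure).  BH
correction is applied within each exposure's family of eight clocks.
Sensitivity scenarios follow the published follow-up analyses; where the
exact covariate sets live in unavailable supplementary material, documented
defaults stand in (the extended alcohol model adjusts for childhood and
adult SES, education, social support, mid-adult overweight and activity).

## 5. Protective factor score and mediation

PFS thresholds are explicit: birthweight ≥ 2.5 kg; top-three paternal
occupation classes; adolescent BMI strictly below the sex cut-off; O-level
qualifications; zero lifetime pack-years ("non-smoking" read as
never-smoking); mean alcohol intake across available timepoints within the
inclusive band [7, 21] units/week; activity at ≥ 2 of 4 timepoints;
adversity in < 3 of 4 life periods.  Group cut-points are ≤3/4/5/6/≥7.
Outcome models are logistic, adjusted for sex and age.

Mediation follows the quasi-Bayesian algorithm: fit the linear mediator
model and logistic outcome model, draw both parameter vectors from their
asymptotic normal distributions (1000 draws by default), simulate potential
mediator values (including residual noise at the fitted σ) for a one-unit
PFS contrast at observed covariates, and average potential-outcome
probabilities to get per-draw ACME and ADE on the risk-difference scale,
averaged over both treatment arms.  The proportion mediated is the median
of per-draw ACME/total ratios with percentile CIs, flagged unstable when
the total effect changes sign in > 5% of draws.  A `continuous` outcome
variant reduces, in the fully linear case, to the product of coefficients —
the closed-form oracle used in testing.  The logit link and one-unit
contrast are documented defaults (the original outcome-model family is not
printed).

## 6. FIBA

For each clock protein, the column is permuted across participants (within-
column permutation preserves the marginal), predicted ages and gaps are
recomputed, the exposure association is refitted, and the FIBA coefficient
is β_orig − β_perm averaged over 5 randomisations.  Because the design
matrix is unchanged, each refit is a single inner product with a
precomputed pseudo-inverse row.  Zero-weight proteins yield bit-exact
zeros.  Per-protein sub-seeds derive from (master seed, protein index), so
results are reproducible protein-by-protein.

## 7. Proteome-wide analyses

Differential abundance log₁₀-transforms and z-scores each protein, then
fits either a vectorized linear model against a score (with sex/age
adjustment by default — the conservative choice where the covariate list is
unprinted; unadjusted is selectable) or a per-protein Cox model against
mortality, with BH across all tested proteins.  Zero-variance proteins are
skipped with a warning.

The longevity model is elastic-net-penalized Cox with the mixing parameter
fixed at 0.5 and a 100-point log-spaced penalty path (path lower bound at
1% of λ_max).  Folds are stratified by event status; the penalty maximizing
the mean 10-fold cross-validated concordance index is selected and its
nonzero coefficients reported.  Because the *maximum* of noisy CV curves is
an optimistically biased performance estimate (under a pure-noise panel it
sits a few points above 0.5), the package also provides
`nested_cv_cindex`: an outer CV loop in which each training set chooses its
own penalty by inner CV and concordance is scored on the held-out fold.
This nested estimate is the honest performance number and is what the
calibration tests use; the plain CV maximum remains the selection
criterion.

Decile biomarker analysis flags the bottom (or top) abundance decile and
fits a logistic death model adjusted for sex and age, with an optional
side-by-side comparator coefficient (e.g. ≥ 15 pack-years vs never); a
decile whose ties span more than 20% of samples is rejected as degenerate.

## 8. Multiple imputation

Chained equations visit incomplete columns in ascending missingness order.
Continuous fields use Bayesian linear regression with predictive mean
matching (type-1: observed predictions at the posterior mean, missing
predictions at a posterior draw; k = 5 nearest donors; imputed values are
always observed donor values).  Binary fields use logistic draws,
categorical fields multinomial draws; both fall back to observed-frequency
draws if a fit fails to converge.  The predictor matrix defaults to all
other analysis variables including the study outcomes.  Test-scale defaults
are m = 5 imputations × 10 iterations (the original 30 × 50 is selectable
by flag).  Pooling follows Rubin's rules — total variance = within +
(1 + 1/m)·between — with Barnard–Rubin small-sample degrees of freedom when
a complete-data df is supplied.

## 9. Problem sizes and recovery experiments

The test suite and acceptance script run at the study's own scale wherever
that is what is being tested: n = 1803 cohorts for effect recovery (400
replicates for CI-coverage calibration), the graded-hazard experiment
(100 replicates; the planted per-extreme-organ gradient is log 2.5, sized
by a power analysis so that estimate ordering is informative rather than
noise-dominated at ~280 events), mediation coverage (100 replicates of a
planted PFS → kidney-gap → death pathway whose true proportion mediated,
computed by a potential-outcome Monte-Carlo oracle at the true parameters,
is 0.23), and the elastic-net experiment (10 hazard proteins of 500 at
log-HR 0.3 per SD).  Null-calibration checks use larger panels
(10⁴ proteins × 200 replicate scores for FDR; n = 6000 for the nested
concordance, where the concordance SE is small enough for a ±0.02 band).
The protein panel defaults to 40 proteins per organ, a scale-down chosen to
keep full-matrix analyses comfortably interactive while preserving ~0.3 y
clock precision.

## 10. Known limitations

Exposure–gap confounding is real on synthetic data too: single-exposure
models inherit bias from the copula correlation with other planted
exposures, which is why recovery tests use correctly specified designs.
The Breslow solver is Newton-based without step-halving and is intended for
well-conditioned problems.  `MNLogit`-based categorical imputation can be
unstable on sparse categories (it then falls back to frequency draws).
Mediation assumes sequential ignorability; no sensitivity analysis for that
assumption is provided.
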