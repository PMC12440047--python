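# lifeclocks

Proteomic organ ageing clocks, life-course exposure models and longevity
analyses — implemented end to end on synthetic birth-cohort data with fully
recorded ground truth.

## The scientific problem

Plasma proteomic clocks estimate a person's *biological age* — overall
("Conventional") and per organ (brain, heart, lung, liver, kidney, immune
system, arteries) — as a linear model over organ-enriched protein
abundances.  The **age gap**, Δ = predicted age − chronological age,
summarises how much older (+) or younger (−) a person's proteome looks.
In a birth cohort whose members share a single birth week, chronological age
is essentially constant, so age gaps isolate biological heterogeneity: who
carries extreme ageing in which organs, which life-course exposures
(birthweight, childhood social class, adolescent BMI, education, smoking,
alcohol, physical activity, cumulative adversity) shape those gaps, and how
strongly multi-organ extreme ageing predicts death over the following
~15 years.

Because the underlying cohort data are restricted-access, this package pairs
every analysis with a **synthetic-data generator** that emulates the study
conditions — a cohort of 1,803 sampled at 63.2 ± 1.1 years, exposure
marginals matching the published demographic table, organ-enriched protein
signals driven by latent organ ages with planted exposure effects of the
published magnitudes, and a proportional-hazards mortality process with
~15.6% deaths over 15.1 years.  Every planted parameter is recorded, so each
estimator can be tested for *recovery of a known truth* rather than
eyeballed against published numbers.

It is intended for biostatisticians and epidemiologists who want a tested,
reproducible reference implementation of this analysis family.

## What is implemented

| Stage | Model / statistic |
| --- | --- |
| Clock engine | predicted age = intercept + Σⱼ wⱼ·(t(xⱼ) − μⱼ)/σⱼ with t = log₁₀ (assay-version scaling and sample QC included) |
| Extreme agers | oldest decile of each clock's age-gap distribution (type-7 quantile, ties included); multi-organ counts and co-occurrence |
| Survival | Kaplan–Meier product-limit curves; Cox PH (Efron ties default, Breslow solver included) for extreme-vs-rest and graded 1/2/3/≥4-organ models, adjusted for sex and age |
| Exposures | OLS of age gap on each exposure in reporting units (per 20 pack-years, per 7 units/week, per life period), adjusted for sex, age, childhood SES; BH correction across the eight clocks per exposure family; six sensitivity scenarios; adversity-component multivariable model |
| Protective factor score | count of eight favourable factors with explicit thresholds; logistic models (per-unit and ≥7 vs ≤3 group odds ratios); mutually adjusted factor decomposition |
| Mediation | quasi-Bayesian causal mediation (linear mediator model, logistic outcome model), ACME/ADE on the risk-difference scale, proportion mediated with percentile CIs |
| FIBA | permutation feature importance for biological ageing: β_orig − mean(β_permuted) per clock protein over 5 randomisations |
| Proteome-wide | per-protein differential abundance (linear vs a score, Cox vs mortality) with BH FDR; cross-timepoint consistency; elastic-net Cox (α = 0.5, λ by 10-fold cross-validated C-index, plus an honest nested-CV performance estimate); decile biomarker odds ratios |
| Imputation | chained-equations multiple imputation (predictive mean matching for continuous, logistic for binary, multinomial for categorical fields) and Rubin's-rules pooling with Barnard–Rubin df |

## Worked example

```python
import pandas as pd
import lifeclocks as lc

cohort, matrix, clocks, latent, truth = lc.simulate_study(seed=1)
scaled = lc.apply_scaling_factors(matrix)          # assay-version scaling
filtered, removed = lc.qc_filter_samples(scaled)   # drop flagged samples
preds = pd.DataFrame({c.name: lc.estimate_biological_age(filtered, c) for c in clocks})
profile = lc.flag_extreme_agers(lc.compute_age_gaps(preds, cohort))
counts, prevalence = lc.count_extreme_organs(profile)

print(f"QC-excluded samples: {len(removed)}")
print(profile.summary().round(2))
print(f"extreme ageing in >=1 organ: {prevalence.loc[1, 'prevalence']:.1%}")

hr = lc.extreme_ager_hazard(profile, cohort)
print(hr[hr["model"] == "organ_count"][["term", "hr", "ci_low", "ci_high"]].round(2))
```

prints

```
QC-excluded samples: 4
              mean    sd    min    max
Conventional  1.06  4.13 -16.86  14.18
Brain        -0.62  4.30 -14.14  13.63
Heart        -0.03  4.04 -13.16  13.15
Lung         -0.17  4.04 -12.95  16.31
Liver        -0.27  4.20 -13.05  15.85
Kidney       -0.58  4.03 -16.25  14.03
Immune       -0.17  4.32 -13.10  14.08
Artery        0.09  4.03 -15.19  14.62
extreme ageing in >=1 organ: 42.9%
         term   hr  ci_low  ci_high
    extreme_1 1.62    1.21     2.16
    extreme_2 2.65    1.90     3.70
    extreme_3 2.94    1.95     4.41
extreme_4plus 3.76    2.07     6.84
```

Four assay-flagged samples are excluded (1807 → 1803); each clock's age-gap
distribution spans roughly three decades despite near-identical
chronological ages; about 43% of participants are extreme agers in at least
one organ; and mortality hazard rises monotonically with the number of
extremely aged organs — the graded-risk pattern the planted per-organ
hazard gradient implies.

A command-line interface mirrors the library
(`lifeclocks simulate|apply-clocks|profiles|survival|exposures|impute`).

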