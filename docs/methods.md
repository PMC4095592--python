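# Methods

## Study design being emulated

The package implements the analysis pipeline of a nested case-control study
of breast cancer inside a prospective cohort of Singapore Chinese women aged
45–74. Incident cases were identified through registry follow-up; for each
case, up to three controls were risk-set sampled from cohort members still
free of breast cancer at the case's diagnosis date, matched on age at
enrollment (±3 years), dialect group (Hokkien/Cantonese), menopausal status,
enrollment date (±2 years) and blood-draw date (±6 months). Subjects were
genotyped at a 51-SNP panel of GWAS-established susceptibility loci; the
published panel (risk-allele frequencies in controls and cases, per-allele
odds ratios with standard errors, pooled odds ratios, FDR-adjusted
heterogeneity P values) ships with the package and drives both the score
weights and the synthetic generator.

## Synthetic cohort generator

`simulate.simulate_cohort` draws, per woman: age ~ N(54.9, 7.5²) truncated
to [45, 74]; dialect Hokkien with probability 0.6 (the cohort is
Hokkien-majority; the published tables do not give the split); menopausal
status from a menopause age ~ N(49.5, 4.3²) compared with age at enrollment
(published control mean menopause age 49.2); enrollment dates uniform over a
5-year window and blood draws 0.5–8 years later, in integer days; Gail-model
covariates (education, age at first live birth, age at menarche, family
history, biopsy history, estrogen use) at the published control category
frequencies; BMI ~ N(23.2, 3.2²); genotypes Binomial(2, RAF) at the
published control risk-allele frequencies, with 2% of calls set missing to
emulate the study's ~98% call rate.

Time to diagnosis is exponential with rate
λ₀·exp(Σ β_snp·g + Σ β_cov − mean), i.e. the linear predictor is centred at
its cohort mean so that `baseline_hazard` (default 0.002/person-year) sets
the marginal hazard; this yields five-year risks near 1% and ~3% ever-cases
over the 15-year follow-up, the regime of the study. True SNP effects are
the published pooled log odds ratios (the local estimate for the one SNP
without an applicable pooled OR); covariate effects mirror the published
multivariable estimates. Administrative censoring at end of follow-up; no
competing mortality.

Risk-set sampling follows the study's calipers exactly (closed intervals on
integer-day dates). When more than three controls are eligible, three are
drawn uniformly without replacement — the study does not state its sampling
law, and uniform is the neutral choice. A subject may serve as control in
more than one risk set, and a future case may act as an earlier case's
control, as risk-set sampling requires; cases with fewer than two eligible
controls are dropped with a warning. Features of real data the generator
does not attempt: secular trends, competing risks, covariate measurement
error, population stratification and linkage disequilibrium between panel
SNPs (loci were LD-pruned in the study, so independence is the intended
state). Passing tests therefore demonstrate internal statistical
correctness of the pipeline, not robustness to those real-data features.

## Quality control

Subjects below a 90% genotype call rate are removed; a failing case takes
its whole matched set, a failing control only itself (the set survives with
≥1 control, which remains informative for the conditional likelihood).
SNP-level filters: minor allele frequency < 1% (computed on cases+controls;
a 5% selection-time threshold is available against a user-supplied reference
column) and Hardy-Weinberg deviation in controls at P < 0.0007 by a 1-df
chi-square goodness-of-fit test (an exact test is available behind
`QcThresholds(hwe_method="exact")`; which test the study used is unstated,
and chi-square is the era's default). LD pruning is greedy on composite
(dosage-correlation) r² with a 0.8 ceiling, keeping the most significant SNP
first; a precomputed r² matrix can substitute for dosage-derived LD.
The HWE type-I error calibration test simulates null SNPs at MAF ~
Uniform(0.1, 0.5), typical of the panel and inside the chi-square
approximation's comfort zone at n ≈ 1,200.

## Conditional logistic core

One case per set gives the closed softmax likelihood; the fitter is
Newton–Raphson from β = 0 with analytic gradient/Hessian, step-halving on a
likelihood decrease, convergence at gradient max-norm < 1e-8 within 50
iterations, and a separation guard at |β| > 15 that names the offending
terms. Wald 95% CIs use z = 1.96. Columns without within-set variation are
unestimable and raise an error at the core level; the pipeline layer instead
drops such terms — and terms the separation guard names in a bootstrap
replicate — with a warning, because a rare indicator level (family history,
past biopsy) is routinely concordant or quasi-separated in a resampled
small matched sample and aborting the replicate would waste the remainder
of the model.

## Meta-analysis and the genetic risk score

Pooling is fixed-effects with inverse-variance weights. (The source
describes weighting by "the inverse of the standard errors"; Cochran's Q as
defined there requires inverse-variance weights, so those are the default
for internal consistency, with an `inverse_se` scheme behind a flag.)
Heterogeneity uses Q ~ χ²(k−1), k = number of studies (Q = 0, P = 1 for a
single study), with Benjamini–Hochberg adjustment across the panel and a
0.007 exclusion threshold applied to the adjusted P by default (both the
raw-P and threshold knobs are exposed). Overridden SNPs stay in the score
with their local-study weight, modelling a locus kept on biological grounds
despite between-study inconsistency.

The score is Σ log(pOR)·g over retained SNPs, each SNP oriented so its
weight is positive (dosage flipped g → 2−g when pOR < 1), normalised by the
mean absolute weight: with equal weights the normalised score is exactly
the risk-allele count, and with the published panel it spans ≈ 25–65 for
controls, matching the published control quartile scale (boundaries
43.6/47.1/50.6 printed vs ≈ 41.9/45.3/48.7 simulated). The residual ~1.8-unit
offset is the irreducible uncertainty of reconstructing the study's exact
weights from a table rounded to two decimals, and is exactly the size of a
single orientation ambiguity at the panel's one high-frequency protective
locus; the scale check in the acceptance tests is therefore qualitative
(quartile occupancy, boundaries inside the simulated range, endpoints within
2.5 units). Missing dosages are imputed with the expected dosage
2 × control allele frequency before summation (`missing_policy="zero"`
available); quartiles are linear-interpolation 25/50/75 percentiles of the
control scores, intervals left-closed with the top interval unbounded.

## Absolute risk and reclassification

Biopsy history, observed for ~13% of subjects, is completed by logistic
imputation (biopsy ~ BMI + estrogen + family history on the observed
subset; five Bernoulli draws per missing record, majority vote — five draws
so no ties), falling back to the observed prevalence when the observed
stratum is one-class or the fit degenerates. S_t is Kaplan–Meier on the
full simulated cohort from enrollment, event = diagnosis, censoring at end
of follow-up. C_i = exp[Σ β_j (x_ij − μ_j)] takes β from the multivariable
conditional-logistic fit — treating matched-sample odds ratios as
rate-ratio surrogates, the same approximation the study design implies —
and μ_j as control means of the coded terms. Bands are half-open
left-closed ([1.0, 1.5) etc.), so a risk of exactly 1.5% falls in the
1.5–<2.0 band. The GRS enters the "with GRS" model as quartile indicators
(a continuous option exists).

The categorical NRI is computed from 5×5 band cross-tabulations per group;
significance by the Pencina asymptotic z. Optimism correction resamples
matched sets (not subjects — preserving the design is the point of the
matched bootstrap) with replacement, refits both models per replicate,
and averages NRI(replicate model on replicate) − NRI(replicate model on
original) over B = 500 replicates by default (200 in the end-to-end runs;
the source does not state its replicate count). Replicates whose refit
fails are skipped and counted, with an error if more than 10% fail.

## Problem sizes and determinism

Default end-to-end runs use a 5,000-woman cohort (~165 cases, ~650-subject
matched sample) with B = 200; calibration checks use 200,000 null SNPs at
n = 1,212 (HWE), 10,000 null replicates (Cochran's Q), 100 replicates of
400 sets (parameter recovery) and 10,000 simulated controls (score scale).
All randomness flows through numpy Generators seeded from a single
configured seed; the pipeline fans that seed out to per-stage offsets so
stages are independently reproducible, and reruns are byte-identical.

## Known limitations

Odds-ratio-as-rate-ratio is an approximation that degrades as risks grow;
the KM anchor ignores competing mortality, so absolute risks are slightly
overstated in the oldest ages; the NRI inherits its dependence on the band
cut-points; and the published-panel weights are reconstructed from rounded
tables, so score scales match the study qualitatively, not digit-for-digit.
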