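# Methods

## Study design being modelled

The package implements a two-sample Mendelian randomisation (MR) design:
instrument–exposure associations are estimated in an individual-level,
richly phenotyped multi-study cohort (exposure sample), while
instrument–outcome associations come from consortium summary statistics
(outcome sample).  The exposure is kidney function (eGFR, ml/min/1.73 m²)
and the outcome coronary heart disease (CHD, binary).  The instrument is a
gene score over 17 eGFR-associated SNPs, used in unweighted (allele-count)
and weighted (regression-slope) form.

## eGFR derivation

eGFR is derived from serum creatinine with the IDMS-traceable 4-variable
MDRD Study equation (coefficient 175), the standard creatinine-based "MDRD
model":

```
eGFR = 175 · creat^-1.154 · age^-0.203 · 0.742^female · 1.212^black
```

Creatinine is mg/dL at every interface; a µmol/L helper (÷ 88.4) exists
but is never applied implicitly, because silent unit mixing is the classic
eGFR bug.  The ethnicity term is implemented but defaults to "not black"
(the emulated cohorts are largely of European ancestry).  eGFR is left
untransformed.  Clinical bands use the CKD staging conventions <60
(low), [60, 90) (intermediate), ≥90 (normal/high); 60 belongs to the
intermediate band and 90 to normal/high.

## Gene scores and instrument strength

Per-SNP weights are slopes of OLS regressions of eGFR on allele count
(additive coding) with study as a categorical covariate — only study, not
age/sex, is adjusted, keeping the first stage minimal.  Each SNP is
oriented so the eGFR-increasing allele is counted; an exactly zero slope
is oriented to the alphabetically first allele and flagged.  An external
direction catalog can override orientations (larger external studies
resolve direction more reliably); catalog alleles matching neither of a
SNP's alleles flag a strand/label error.  Missing genotypes are
mean-imputed from the SNP's non-missing counts within study, keeping the
score scale comparable across subjects; a subject missing every genotype
gets a missing score.  Weights are estimated once on the full
eGFR-available sample, not per study.  Instrument strength is the score's
partial R² in the study-adjusted eGFR regression and its single-predictor
F = t²; F ≫ 10 indicates negligible weak-instrument bias.

## Causal estimator

With per-SNP outcome log odds ratios `b_Yj` (SE `s_Yj`) and predetermined
weights `w_j`, the pooled causal effect is

```
beta_hat = Σ w_j b_Yj s_Yj⁻² / Σ w_j² s_Yj⁻² ,   se = (Σ w_j² s_Yj⁻²)^-½
```

the origin-constrained weighted-least-squares form of the
inverse-variance-weighted allelic-score estimator; `w_j = 1` gives the
unweighted variant.  Two-sided p-values compare `beta_hat/se` to a
standard normal; 95% CIs use 1.96 exactly.  Harmonisation aligns each
summary row to the exposure-increasing allele by label, flipping the sign
when the effect allele is the other allele; rows matching neither allele
are excluded; palindromic (A/T, C/G) SNPs are harmonised by label only
and flagged — no allele-frequency strand inference is attempted.  When a
SNP is reported by several sub-meta-analyses, the most precise
(smallest-SE) row is used; instrument SNPs absent from the summary set
are dropped from estimation (but retained in cohort scores) with a
ledger entry.

Sensitivity analyses: leave-one-out (flagging exclusions that cross the
α = 0.05 boundary), named-SNP exclusions, an external-direction variant of
the unweighted score, and a low-eGFR subgroup in which weights are
re-estimated; subgroup results carry an explicit bias caveat because
conditioning on the exposure can bias MR estimates.  Reverse MR swaps the
roles: published CHD log odds ratios become the weights and cohort-side
per-SNP eGFR slopes the outcome statistics; the package reports the
estimate in eGFR units and attaches no odds-ratio interpretation.
Beyond detecting the presence of an effect, no causal-effect-size
interpretation is attached to the weighted estimate.

## Confounder and pleiotropy screening

Each trait is tested against a target in a study-adjusted, complete-case
model: trait-on-target linear regression for continuous targets (logistic
when the trait is binary, e.g. sex), and logistic regression of CHD on
the trait for the binary outcome.  P-values are two-sided Wald,
Benjamini-Hochberg adjusted *within each scan family* (exposure scan,
outcome scan, score scan — not jointly), with rejection at adjusted
p ≤ 0.05.  BH adjustment delegates to statsmodels' `fdr_bh`.  Candidate
confounders are the intersection of exposure- and outcome-scan
rejections, minus (i) named renally cleared biomarkers (default
`ntprobnp`), which sit on the causal pathway rather than behind it, and
(ii) traits measured in fewer than 2 studies; both exclusion rules are
configuration, not hard-coded science.  A permutation procedure checks
that trait correlation does not break the FDR guarantee: the target is
permuted within study (preserving study-level trait differences while
enforcing the global null), the scan + BH is re-run per permutation, and
the distribution of rejection counts is summarised.  This within-study
permutation design is this package's own calibration scheme.

## Synthetic-data generator

The generator defines the study conditions.  Genotypes are
Hardy-Weinberg `binomial(2, f_j)` draws with no linkage disequilibrium
(the instrument set is pre-pruned by construction).  eGFR is
`mean + study offset + Σ δ_j g_ij + confounder effects + N(0, σ²)` with
σ = 15 ml/min/1.73 m², mean 70, study offsets spread over ±4; per-SNP
effects δ_j are rescaled *jointly* so the population score R² equals the
target (default 1.5%, the instrument-strength anchor of this design);
relative effect sizes vary ~7-fold across SNPs, with `rs653178`
deliberately weakest.  Serum creatinine is obtained by inverting the MDRD
equation, so derived eGFR round-trips exactly; creatinine is set missing
outside the eGFR-measuring studies (4 of 7 by default).  CHD is drawn
from a logistic (not liability-threshold) model,
`logit P = baseline + θ·eGFR + confounder effects`, matching the logistic
analyses used throughout the pipeline; the default causal effect is
θ = −0.016 per ml/min/1.73 m².  Traits follow declared roles: confounders
load on both eGFR and the CHD log-odds, exposure-/outcome-only traits on
one side, pathway markers load on realised eGFR (downstream biomarkers),
null traits are independent; the default panel holds 94 traits.  Trait
covariances beyond these role loadings are not calibrated to any real
cohort.

The outcome sample is ascertained case/control: subjects are drawn from
the same generative population (disjoint random substream) and cases
oversampled until the configured quotas fill — reproducing consortium
case:control ratios without simulating millions of subjects; ascertainment
leaves the logistic slope unbiased (only the intercept shifts).  Cases and
controls are split across three pseudo-meta-analyses treated as
independent (a simplification: real combined-chip analyses overlap their
constituent GWAS), each SNP is fitted by per-SNP logistic regression
(vectorised Newton-Raphson, verified against statsmodels) in the analyses
whose availability mask contains it, and the most precise row is
released, so total N varies across SNPs.  Reported effect alleles are
randomised per SNP so harmonisation is always exercised.  A single master
seed spawns named substreams (genotypes, demographics, traits, disease,
outcome), giving component-level reproducibility: regenerating one sample
never perturbs the other.

What the generator does *not* emulate — and hence what passing tests do
not certify on real data: linkage disequilibrium and correlated
instruments, population stratification, imputation dosages/uncertainty,
realistic trait–trait correlation structure, age/sex effects on eGFR
beyond the MDRD identity, and overlap between outcome sub-analyses.

## Numerical and design choices

* Small OLS fits (weight regressions, linear trait scans) use a dense
  QR/normal-equation path with classical covariance; logistic fits for
  observational models and binary traits use statsmodels, with separation
  caught and reported as missing p-values.
* Monte-Carlo calibration (tests) runs the full pipeline at 17 SNPs,
  score R² = 1.5%, exposure n = 10,000, outcome n = 20,000 with the
  consortium case fraction 63,746/194,427 ≈ 0.328 — 400 replicates for
  bias/coverage, 1,000 for type-I error; screening calibration uses 94
  null traits and 500 within-study permutations.  These sizes are the
  package's chosen compromise between Monte-Carlo resolution and suite
  runtime.
* The weighted estimator treats estimated first-stage weights as fixed.
  With per-SNP first-stage `n·R²_j ≈ 9` (the calibration conditions) this
  yields a known ~10% attenuation toward the null
  (factor `1/(1 + J/(n·R²))`) plus a ~2% non-collapsibility attenuation of
  the marginal logistic slope; both are properties of the estimator and
  the logistic model, are visible in the calibration suite, and stay
  within its acceptance bands.  Coverage is mildly conservative-correct
  (≈0.95) because the attenuation is small relative to the SE.
* Power uses the asymptotic normal approximation with
  `NCP = N·R²·K(1−K)·(ln OR)²`; at consortium scale (N = 194,427,
  K ≈ 0.328, R² = 1.5%) this gives 25.5% power at OR 0.95 and 76.1% at
  OR 0.9, and the formula is cross-checked against empirical rejection
  rates of the full pipeline at reduced scale.  The two-sided form
  includes the (usually negligible) far-tail term, so power at OR = 1
  equals α exactly.
* A known reporting pitfall in this literature: a pooled OR of 0.991 with
  95% CI 0.981–1.001 cannot have p = 0.003 under the normal reference —
  CI and p must be mutually consistent.  This package always derives OR,
  CI and p from the same (beta_hat, se) pair.

## Limitations

No MR-Egger, weighted-median or stratified-exposure estimators are
provided — the pipeline tests for the *presence* of a causal effect with
an allelic-score estimator and documents, rather than corrects,
pleiotropy found by screening.  The permutation scheme and the
pseudo-meta-analysis independence are this package's own design choices.
The generator's defaults are plausibility-calibrated, not fitted to any
real cohort.
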