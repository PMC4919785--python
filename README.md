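# egfr-mr

Two-sample Mendelian randomisation (MR) pipeline for studying whether
kidney function — measured as estimated glomerular filtration rate (eGFR)
— causally affects coronary heart disease (CHD) risk, built for
epidemiologists and statistical geneticists who want every stage of an
allelic-score MR analysis as tested, reusable code: gene-score
construction, instrument-validity screening, summary-statistic causal
estimation, sensitivity analyses, reverse MR and power analysis.  A
synthetic-data module emulates both required samples (a richly phenotyped
multi-study cohort and consortium-style per-SNP case/control summary
statistics) with known ground truth, so the whole chain is verifiable
without access-controlled data.

## The model

Each subject's exposure proxy is a gene score over J instrument SNPs,

- unweighted: `S_i = Σ_j g_ij`, where `g_ij` counts eGFR-increasing
  alleles (orientation from study-adjusted regressions of eGFR on allele
  count, optionally overridden by an external direction catalog);
- weighted: `S_i = Σ_j w_j g_ij`, with `w_j` the per-allele eGFR slope.

With only per-SNP outcome summary statistics available (log odds ratio
`b_Yj` with standard error `s_Yj`), the causal effect of the score on CHD
is the precision-weighted pool

```
beta_hat = Σ_j w_j b_Yj / s_Yj²  ⁄  Σ_j w_j² / s_Yj² ,
se(beta_hat) = ( Σ_j w_j² / s_Yj² )^(-1/2)
```

— exactly weighted least squares of `b_Yj` on `w_j` through the origin
with weights `1/s_Yj²` (the allelic-score form of the inverse-variance
weighted two-sample MR estimator; `w_j = 1` gives the unweighted-score
variant).  eGFR is derived from serum creatinine with the 4-variable MDRD
equation `175 · creat^-1.154 · age^-0.203 · 0.742^female · 1.212^black`.
Instrument validity is screened phenome-wide: traits associated with both
eGFR and CHD (Benjamini-Hochberg FDR 0.05 in each scan family) are
candidate confounders, and the gene scores themselves are scanned across
the trait panel for pleiotropy.  Analytic power for a binary outcome uses
the non-centrality `sqrt(NCP) = |ln OR| · sqrt(N · R² · K(1-K))`.

## Worked example

```python
from egfr_mr.pipeline import calibration_config, run_two_sample_mr

cfg = calibration_config(seed=1)          # 17 SNPs, score R²=1.5%,
run = run_two_sample_mr(cfg)              # n=10,000 cohort + 20,000 outcome
est = run.weighted
print(f"OR = {est.or_:.3f} per eGFR unit, "
      f"95% CI {est.ci95[0]:.3f}-{est.ci95[1]:.3f}, p = {est.p:.3f}")
```

prints

```
OR = 0.989 per eGFR unit, 95% CI 0.974-1.004, p = 0.149
```

i.e. on this replicate the weighted-score estimate of the causal odds
ratio per ml/min/1.73 m² of eGFR is 0.989 — close to the generative truth
`exp(-0.016) = 0.984` but, at this instrument strength and outcome sample
size, not individually significant; the Monte-Carlo tests show the
estimator is unbiased up to a small known attenuation and has correct CI
coverage.

The numbered scripts under `analysis/` run the full study narrative on a
full-scale synthetic cohort (7 studies, 13,145 subjects, eGFR in 4
studies) against a 194k-subject synthetic consortium, writing tables to
`results/`:

```
python analysis/01_simulate_study.py        # design + descriptives
python analysis/02_observational_association.py
python analysis/03_build_gene_scores.py     # weights, scores, F statistics
python analysis/04_screen_assumptions.py    # confounder/pleiotropy scans
python analysis/05_mr_estimates.py          # causal estimates + sensitivity
python analysis/06_reverse_mr.py
python analysis/07_power_analysis.py
```

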