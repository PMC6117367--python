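# predscan

Linking biomarkers measured in one genotyped cohort to clinical diagnoses
in another, without ever measuring the biomarker in the second cohort.

Many quantitative biomarkers (blood pressure, lipids, coagulation factors,
anthropometrics) are measured in epidemiological cohorts but absent from
electronic health records at scale. `predscan` implements the *genetically
predicted biomarker* paradigm for this situation:

1. **Fit** a Bayesian sparse linear mixed model (BSLMM) to genotype dosages
   and a residualized biomarker in the measurement cohort. The model

   *y* = *X*β̃ + *u* + ε,  β̃ᵢ ~ π·N(0, σ²ₐ/τ) + (1−π)·δ₀,
   *u* ~ N(0, σ²_b K/τ),  K = X X′/p

   hybridizes a sparse large-effect component with a dense polygenic one and
   yields, per SNP, a polygenic posterior mean α, a sparse effect β, and a
   posterior inclusion probability γ. The posterior also summarizes the
   architecture: PVE (trait variance explained by all SNPs), PGE (share of
   genetic variance from large-effect SNPs) and the number of large-effect
   SNPs.
2. **Project**: each SNP gets weight **w = α + βγ**; after reconciling
   alleles and strand flips with the target cohort, the genetically
   predicted biomarker of subject *j* is Σᵢ wᵢ·[dosage]ᵢⱼ, standardized to
   SD 1, so effect sizes read as odds ratios per SD of predicted biomarker.
3. **Scan**: a phenome-wide association study (PheWAS) over phecode-defined
   case/control phenotypes (controls exclude carriers of closely related
   codes and are matched on birth-decade range), with logistic regression
   adjusted for sex, birth decade, site, platform and principal components.
   Selection uses an experiment-wide Bonferroni threshold and
   Benjamini–Hochberg FDR q < 0.1; prespecified positive-control pairs,
   a coefficient-skewness diagnostic
   (Σβ³/n)/(Σβ²/n)^{3/2}, stratified fits and cross-cohort direction
   concordance establish validity.

Because real cohorts of this kind are access-controlled, the package ships a
first-class synthetic-cohort module: linkage-equilibrium dosages, biomarkers
with exact requested PVE/PGE, and diagnoses drawn from a logistic liability
model sharing the biomarker's true genetic values — every stage of the
paradigm is testable with known ground truth.

## Worked example

```bash
predscan run --config examples/demo.yaml --out demo_out
```

simulates a measurement cohort (n = 1000, 300 SNPs, biomarker with PVE 0.5
and PGE 0.7 over 5 large-effect SNPs), a target cohort (n = 2000) with one
diagnosis ("401") coupled to the biomarker's genetic value at log-OR 0.6
per SD, fits a 4000-step chain, projects the weights and scans 19
phenotypes. From `demo_out`:

- `fit.json` — posterior PVE median 0.512, 95% credible interval
  [0.455, 0.559]: the chain recovers the simulated heritable fraction.
- `results.tsv` — the planted phenotype is rank 1:

  ```
  biomarker  phecode  beta        or      p           rank
  sbp        401      0.597       1.818   3.8e-20     1
  sbp        101      0.033       1.033   0.66        16
  ```

  OR 1.82 per SD of predicted biomarker against the planted exp(0.6) = 1.82.
- `positive_controls.json` — the prespecified pair lands in every category:
  `{"sbp": ["bonferroni", "fdr", "top_rank"]}`.
- `skewness.json` — 0.05 for this scan: one strong positive association
  among otherwise symmetric null coefficients barely skews the
  coefficient distribution.

The same stages are available piecewise (`predscan simulate / fit /
project / phewas / controls / skewness / concordance`) over documented
text formats: dosage TSV with a SNP metadata sidecar, VCF 4.2 with DS,
occurrence and phecode-definition CSVs, weight and score TSVs.

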