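# Methods

## Model

The measurement-cohort biomarker is first residualized by ordinary least
squares on an intercept plus covariates (by default age, sex and the two
leading principal components); residuals are exactly orthogonal to every
adjustment column. The residual vector *y* (length n, centered) and the
column-standardized dosage matrix X (n × p) enter the Bayesian sparse
linear mixed model

y = Xβ̃ + u + ε,  β̃ᵢ ~ π N(0, σ²ₐ/τ) + (1−π) δ₀,
u ~ N(0, σ²_b K/τ),  ε ~ N(0, I/τ),  K = XX′/p.

Hyperparameters are re-expressed as (h, ρ, log₁₀π) with uniform priors —
h on [0, 1] (total genetic variance proportion), ρ on [0, 1] (share of
genetic variance from the sparse component), log₁₀π on [log₁₀(1/p), 0] —
through σ²ₐ = hρ/((1−h)πp) and σ²_b = h(1−ρ)/(1−h) on the standardized
scale. The residual precision τ carries a Jeffreys prior and is integrated
out analytically.

Dosage columns are mean-imputed (2 × allele frequency) when missing,
centered at 2f and scaled to unit variance inside the fitter; constant
columns are dropped with a warning and recorded on the fit. Exported
effects are back-transformed to the per-allele (raw 0/1/2) scale by
dividing by the column SD, so weight files apply directly to raw dosages.

## Sampler

A Metropolis-within-Gibbs chain alternates (i) a random-walk move on
(h, ρ, log₁₀π) with boundary reflection and (ii) an add/remove/swap move
on the sparse inclusion set, capped at 300 SNPs. Both moves use the
marginal likelihood with effect sizes and τ integrated out, computed in
the eigenbasis of K (one n × n eigendecomposition per fit) with a Woodbury
identity over the |S| included SNPs, so a step costs O(n·|S|²). The
Hastings ratio of set moves includes the move-type selection probability,
which is asymmetric at the empty-set boundary; omitting it measurably
biases posterior inclusion probabilities at small p (the test suite pins
the chain against an exact set-enumeration oracle at p = 3).

At a thinning interval after burn-in the chain draws τ, the included
effects and the polygenic eigencomponents from their conditional
posteriors to record per-draw PVE = V(g)/(V(g)+σ²ₑ), PGE =
V(sparse)/V(g) and |S| (reported as medians with central 95% credible
intervals over recorded draws), and accumulates Rao-Blackwellized per-SNP
summaries: α (conditional mean polygenic effect), β (conditional posterior
mean of the sparse effect given inclusion) and γ (inclusion frequency).
The projection weight is w = α + βγ.

Defaults: 100 000 steps with the first half discarded and thinning 10 is
the production schedule; the test suite and bundled demo run 1 500–20 000
step chains, which recover simulated architectures at the problem sizes
they use (n ≤ 1000, p ≤ 1000). Trace diagnostics record acceptance rates
and an autocorrelation-based effective sample size without asserting a
threshold. Identical seeds give bit-identical posteriors.

The holdout %PVE removes `holdout_n` subjects (default 500), fits on the
rest, projects weights onto the holdout and reports
100 · R²(y, score) / median PVE, where R² is the squared correlation —
the standard reading of "variance explained by the predictor". A PVE
median below 10⁻⁶ flags the ratio undefined instead of dividing.

## Projection

Weights align to a target panel by snp_id with allele verification: same
pair swapped negates w (and α, β); strand complements resolve by
complementing; A/T and C/G pairs are strand-ambiguous and are dropped when
the target minor-allele frequency lies in a configurable window (default
0.4–0.6) where frequency cannot resolve orientation — a conservative
default, configurable off. Incompatible pairs and SNPs absent from the
target are dropped and counted, never fatal. The raw score is the weighted
dosage sum with mean imputation of missing dosages; standardization both
centers and scales (the centering is what makes standardized scores
exactly invariant to allele recoding, and logistic intercepts absorb it).

## Phenome scan

Cases carry ≥ 1 occurrence of the phecode. Samples whose only relevant
occurrences are closely-related exclusion codes sit out entirely. Sites
contributing fewer than 10 cases are excluded wholesale for that
phenotype, single-gender phenotypes are rejected, controls outside the
case birth-decade range are excluded, and a phenotype needs ≥ 300 cases
(configurable; the synthetic suites use 100–300 to match their cohort
sizes). Logistic fits are plain maximum likelihood; separation is detected
(non-finite or exploding estimates, perfect-separation errors) and flagged
with estimates withheld rather than penalized. Birth decade, site and
platform enter as categorical factors; covariates constant within an
analysis cohort are dropped with a log line. Ranks order converged results
by ascending p, ties broken by |β| descending then phecode; non-converged
results are retained but excluded from ranking.

The Bonferroni threshold is α/(biomarkers × phenotypes). B–H q-values are
computed within a configurable family — per biomarker across its
phenotypes (default) or globally. Positive-control pairs are categorized
non-exclusively as bonferroni / top-5 rank / FDR q < 0.1 / none;
unresolvable control phecodes leave the denominator. The skewness
statistic (Σβ³/n)/(Σβ²/n)^{3/2} runs over converged coefficients with at
least `min_cases` cases (inclusive threshold, default 150), excluding
FDR-significant results so strong hits do not dominate the asymmetry
measure. Direction concordance joins two result sets on phecode and counts
sign agreement among pairs nominally significant (p < 0.1) in the second
cohort.

## Synthetic cohorts

Dosages are Binomial(2, MAF) in linkage equilibrium — no LD, population
structure, or relatedness — which keeps variance-decomposition oracles
exact and is the deliberate limit of what passing tests demonstrate:
calibration and recovery under the model's own assumptions, not robustness
to real-data confounding. In "exact" mode the biomarker's large-effect,
polygenic and noise components are orthogonalized in-sample (the
polygenic-on-large projection stays in the span of the large-effect SNPs,
so per-SNP effects remain exact) and rescaled so realized PVE and PGE hit
their targets to machine precision; "sampled" mode draws effects at the
implied scale instead, where the genetic variance is unbiased for the
target but the variance *fraction* carries a small Jensen bias. Diagnoses
follow a logistic liability on the standardized true genetic value — a
logistic rather than probit link so planted log-odds ratios are
recoverable on the scale the downstream scan estimates; the intercept is
solved by root-finding so expected prevalence matches the specification.
Exclusion codes are co-assigned to a fraction of cases (default 0.3) and
to non-cases at a lower carrier rate (default 0.05) to exercise control
exclusion. Sex-restricted codes arise only in the eligible sex, with
prevalence defined within that sex. The liability choice is a test-harness
convention, not a claim about any real phenotype's generative model.

## Pipeline and numerics

One global seed fans out to stage seeds by CRC32 of the stage name, so
stages are individually reproducible and full reruns are byte-identical.
The YAML configuration validates against `docs/pipeline.schema.json`
before any compute. Degenerate inputs fail loudly and early: constant
traits, rank-deficient covariate designs (with the collinear columns
named), zero-variance scores, single-class phenotypes, empty alignments.
Quantities with undefined values (skewness of all-zero coefficients,
concordance over an empty join, %PVE at zero posterior PVE) are flagged
rather than returned as numbers.

## Known limitations

- At very small p the polygenic term spans the causal SNPs, so posterior
  inclusion probabilities are bounded away from 1 even for an overwhelming
  single causal SNP (exact enumeration at p = 2, n = 2000, PVE 0.5 gives
  γ ≈ 0.85); this is a property of the model, not the sampler.
- No LD means per-SNP weights are not directly comparable to weights
  fitted on real, correlated panels.
- The probit/binary-trait variant of the mixed model, genotype QC and
  imputation, and principal-component computation are out of scope; PCs
  are consumed as covariate columns.
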