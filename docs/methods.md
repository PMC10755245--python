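# Methods

## The model chain

The package analyzes a cohort with genotypes, smoking phenotypes and
regional gray-matter volumes (rGMV) under the working causal model

    genetic liability → smoking exposure → gray-matter atrophy → brain-age gap

Each stage is an independent, testable operation; the pipeline wires them
in dependency order and records every parameter and seed in a run
manifest.

### Genotype QC

Samples with more than 5 % missing calls are removed first, then SNPs are
filtered on statistics recomputed over the retained samples: MAF < 1 %,
call rate < 95 %, or Hardy–Weinberg equilibrium p < 10⁻⁵ (all strict
inequalities). The HWE test is the Pearson chi-square goodness-of-fit with
1 df against expected proportions at the sample allele frequency, no
continuity correction — the standard array-QC choice; monomorphic SNPs
return p = 1 by convention so they are caught by the MAF filter, not the
HWE filter. MAF is computed on non-missing calls only. A SNP failing
several filters is attributed to the first of (MAF, call rate, HWE) for
reporting, with an any-failure total alongside. Sex-mismatch checks are
out of scope (they require X-chromosome intensities this data model does
not carry).

### P+T polygenic score

Clumping is the classical greedy pass: visit SNPs by ascending discovery
p-value (ties broken by chromosome, position, SNP id — determinism
matters more than the arbitrary choice); each index SNP removes remaining
SNPs on the same chromosome within ±250 kb whose dosage r² with it exceeds
0.1, with r² computed on pairwise-complete samples in the target panel.
Scoring at threshold P_T averages β_j·G_ij over the m SNPs entering the
sum (the convention of the most widely used scoring tool; the raw sum is
available via `average=False`). Missing dosages are imputed as twice the
target-sample effect-allele frequency, which keeps the score defined for
every subject and is unbiased under missingness at random. Alleles are
matched exactly; a summary-stats row whose alleles match the panel in
neither orientation is skipped with a warning rather than strand-flipped,
because strand heuristics silently corrupt A/T and C/G SNPs. Threshold
selection ranks the 100-point grid by |partial r| with the smoking
phenotype (binary ever-smoker by default; configurable), keeps the top 10,
and z-scores the winner. Absolute ranking is the default reading of
"strongest association"; signed ranking is a flag.

### Brain age and bias correction

Features are the 166 rGMVs residualized on sex, handedness, BMI, alcohol,
TIV, site and education (ethnicity is constant in the synthetic cohort and
therefore omitted from the default list). The learner is gradient-boosted
trees; outer five-fold CV (seeded shuffle, stratified by age decile so
fold age distributions match) yields exactly one out-of-fold prediction
per subject, and inner five-fold CV on the training subjects selects
hyperparameters by minimum mean MAE. The documented default search space
is depth {2, 4, 6} × learning rate {0.05, 0.1} × trees {100, 300}; the
pipeline's default run uses the single combination (3, 0.1, 150), a
desk-scale choice that the config can override. When the grid has one
combination the inner loop is skipped (selection is trivial).

Raw BAG anti-correlates with age (regression to the mean: the model
over-predicts young and under-predicts old subjects), so group contrasts
on raw BAG are confounded by any group age difference. The correction
regresses training out-of-fold BAG on age and subtracts the fitted trend —
the "subtract the age trend estimated in the training set" variant, chosen
because it transfers verbatim to cohorts the model never saw (the
training-set coefficients are applied unchanged to the smoking group); a
rescaling variant that divides by the prediction slope is equivalent up to
scale on the fitting cohort but does not decompose as cleanly across
cohorts. On the fitting cohort orthogonality is exact by least-squares
algebra; on a held-out cohort the residual correlation is
O(1/√n_train + 1/√n_holdout) and is verified empirically. The Fisher-z
interval (SE = 1/√(n−3)) is used for Pearson r because no better-motivated
interval is available without distributional assumptions on the errors.

### Association statistics

Continuous outcomes (BAG, tGMV, pack-years, quit duration) use Gaussian
OLS with an intercept; binary smoking status uses logistic regression.
Covariate sets mirror the two-model layout: Model 1 (sex, age) and
Model 2 (sex, age, TIV, handedness, BMI, alcohol, site, education). Group
contrasts use the Welch t-test (no equal-variance assumption costs almost
nothing and protects against heteroscedasticity) with classical pooled-SD
Cohen's d. The GWAS scan mean-imputes missing dosages, residualizes
phenotype and dosages on the covariates once (Frisch–Waugh–Lovell), and
reproduces full per-SNP OLS estimates exactly with df = n − k − 2 — this
is verified against a per-SNP OLS loop in the tests. Thresholds are
0.05/m (genome-wide) and 1/m (suggestive) with m the number of SNPs
actually tested; monomorphic SNPs are reported NA and excluded from m.

### Mediation

Product-of-coefficients on linear models, covariates included in every
sub-model. Two mediators are parallel (no mediator→mediator path): the
reported per-mediator indirect effects a_j·b_j then sum to τ − τ′ exactly,
which is the decomposition the combined-proportion-mediated statistic
assumes. Inference is nonparametric case resampling (rows resampled
jointly, preserving the covariance of all variables) with bias-corrected
percentile intervals; the acceleration constant is omitted (BC, not BCa).
PM = 100·(τ − τ′)/τ is computed from point estimates, not bootstrap means,
and flagged unstable when |τ| is below tolerance or τ and τ′ disagree in
sign (suppression), in which case the percentage is arithmetically valid
but not interpretable as a proportion.

### Enrichment

BED intervals are 0-based half-open; SNP positions are 1-based; the
conversion lives in one function (`snp_to_bed_coord`) so the off-by-one
cannot drift. A SNP maps to every overlapping (optionally flanked) gene —
overlapping loci are common and a deterministic rule beats a nearest-gene
heuristic that needs tie-breaking. ORA uses the hypergeometric upper tail
P(X ≥ k) with BH adjustment across tested terms; the universe defaults to
all genes in the interval file (configurable), terms with no universe
genes are skipped.

## The synthetic cohort generator

The generator emulates the statistical structure of a middle-aged biobank
imaging-genetics sample, not any real population:

- **Genotypes.** Allele frequencies uniform on (0.05, 0.5]; LD induced by
  a Gaussian copula with an equicorrelated latent factor per block of 10
  SNPs (latent r = 0.6), discretized at Hardy–Weinberg proportions. Blocks
  span < 250 kb internally and are ≥ 1 Mb apart, so the clumping window
  never bridges blocks. Missing calls are injected completely at random at
  1 % per call. This gives controllable within-block dosage r² with exact
  marginal frequencies and no external haplotype panel.
- **Discovery GWAS.** 60 causal SNPs of 2,000 with effects N(0, 0.05);
  observed β̂_j = β_j + N(0, se_j), se_j = 1/√(2p_j(1−p_j)·100,000) — the
  sampling noise of a 100k-sample discovery study of a standardized trait.
- **Smoking.** Liability = √0.3·(standardized true score) + small sex term
  + noise (genetics explains 30 % of liability variance); smokers are the
  top 56 % of liability (the prevalence of the motivating study
  population). Pack-years = max(0, 18 + 8·liability + N(0, 8)) for
  smokers, exactly 0 for never-smokers; half of smokers are "former" with
  a quit duration decreasing in liability.
- **Volumes.** Ages uniform on 44–81. Region k baseline U(2500, 9000) mm³
  loses 3·w_k mm³ per year of age (w_k ~ U(0.5, 1.5), so regions carry
  different amounts of age signal), plus a whole-brain smoking loss of
  60 mm³ per pack-year spread evenly over regions (~0.01 % of tGMV per
  pack-year, within the range volumetric smoking studies report), TIV
  loading 0.0004 mm³/mm³ per region (tGMV–TIV r ≈ 0.8), small sex and BMI
  effects, and N(0, 60) mm³ region noise. tGMV is the exact sum of the 166
  regions. Ancestry PCs are standard normals independent of genotype —
  they exist to exercise the covariate plumbing only.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, population stratification actually correlated
with genotype, relatedness, sex chromosomes, site/scanner batch effects on
volumes, non-linear ageing trajectories, and measurement error structure
of real segmentation. Passing tests therefore demonstrate that the
*methods* are implemented correctly and recover known generative
parameters — not that the pipeline would reproduce any specific real-data
effect size.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; a fixed seed
  gives byte-identical outputs (the boosted-tree learner is run
  single-threaded with the histogram method for this reason).
- Problem sizes in the tests and the acceptance script (cohorts of
  600–3,000, 200–2,000 SNPs, single-combination boosting grids) are chosen
  for desk-scale turnaround; every check is a structural or calibration
  property that does not sharpen with more data.
- Thresholds on the P_T grid are rounded to 10 decimals when constructed
  so that 0.005·i accumulation noise never reorders the grid.
- Partial correlation clips |r| at 1 − 10⁻¹⁰ before the t-transform.
- Zero-variance vectors, empty scores, collinear designs, constant ages,
  all-zero genotype-count triples, malformed BED lines, and empty
  universes raise informative errors rather than propagating NaN; the
  collinearity error names the offending columns via a QR sweep.
- Bootstrap resamples that produce a singular design are recorded as NaN
  and dropped from the percentile computation.

## Known limitations

- The HWE test is asymptotic; at very small counts an exact test would be
  preferable (the QC defaults are meant for thousands of samples).
- The two-mediator model is parallel only; sequential (m1 → m2) mediation
  is not implemented.
- GWAS logistic regression loops per SNP and is slow beyond ~10⁴ SNPs;
  the linear family is vectorized.
- Allele harmonization is exact-match only (no strand flipping).
- The enrichment stage tests over-representation only, not rank-based
  set enrichment.
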