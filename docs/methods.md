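# Methods

## Data model and QC

A cohort is subjects × loci minor-allele counts (0/1/2, −1 missing), a
binary (0 = control, 1 = case) or continuous phenotype, and a numeric
covariate table. The minor allele is defined empirically per dataset
(frequency ties at 0.5 broken lexicographically by allele character);
insertion/deletion polymorphisms are coded as ordinary biallelic loci with
'I'/'D' allele characters. Missing genotypes are handled complete-case per
analysis: a subject is dropped only from analyses that use the missing
locus.

Hardy-Weinberg QC is the plain Pearson goodness-of-fit test on the three
genotype counts against (p̂²N, 2p̂(1−p̂)N, (1−p̂)²N), 1 df, no continuity
correction, computed in controls. Monomorphic loci return chi² = 0, p = 1,
flagged.

## MDR search

For a locus tuple of size k, training subjects are tabulated into the 3^k
genotype cells. With training totals R cases / S controls, a cell with
counts (c, d) is **high-risk iff c/d ≥ T = R/S**, the boundary inclusive
(internally: iff Σ_cell w ≥ 0 with w_i = S for cases and −R for controls,
which is the same rule in exact integer arithmetic). Cells with cases and no
controls are high-risk; cells unseen in training are EMPTY and predict
low-risk at test time. T is recomputed on every training split.

Model quality is balanced accuracy of the high/low prediction. Folds are
stratified by outcome and dealt in a canonical data order, so results are
invariant to subject order and, because tuples are sorted, to locus order;
a fixed seed reproduces every report. Within each fold the tuple with the
highest training BA wins (ties: lexicographically first). Per k the modal
winner across folds is reported (CVC = its count; CVC ties broken by mean
*training* BA — using testing BA here would leak test information into the
reported accuracies and the sign test). The overall best model across k
takes the highest testing BA, ties broken by higher CVC, then smaller k.

The sign test counts folds where the chosen model's testing BA is strictly
greater than 0.5 (exact ties fail) and reports the exact binomial tail
P(X ≥ s), X ~ Binomial(n_folds, ½).

**Calibration caveat (computed by this package's own null simulations):**
the sign test treats the 10 fold outcomes as independent; they are not. A
chance whole-sample association inflates a tuple's training BA (driving its
selection) and its testing BA in *every* fold at once, so under a global
null the selected 2-locus model reaches sign counts ≥ 9 in roughly 15–20% of
study-sized replicates (nominal 1.07%), and even a fixed pair reaches them
in ~4% from fold correlation alone. The sign test is therefore a ranking
heuristic, not a calibrated test; inference should rest on the permutation
test below.

The permutation test permutes the phenotype (detaching it from genotypes
and covariates), re-runs the full search, and reports
p = (r + 1)/(n_perm + 1). Two statistics are reported: the cross-validation
consistency of the best model (ties broken by testing BA) and testing BA
alone. Note the CVC statistic degenerates when the k range approaches the
number of loci (with few tuples per k, CVC is trivially near 10), so the
testing-BA permutation p is the informative one over wide k ranges.

## GMDR

The score residual is s_i = y_i − μ̂_i from the maximum-likelihood null fit
of phenotype on intercept + covariates (logit link for binary, identity for
continuous); a cell is high-risk iff its mean training score ≥ 0 (inclusive,
with a 1e-9-scaled tolerance so GLM round-off cannot flip an exact
ratio-threshold tie). A standardized score (divided by the variance
function) is available behind a flag; the raw residual is the default
because the MDR special case then holds exactly.

Inside the cross-validation the null model is **re-fit on each training
fold** and held-out subjects are scored from that fit. This keeps score
centering free of test-set information and makes binary/no-covariate GMDR
coincide with MDR cell-for-cell and fold-for-fold (MDR's threshold is
likewise the training-fold ratio). The standalone `score_residuals`
operation fits the whole cohort, which is its documented contract.

For continuous traits, accuracy is the balanced accuracy of the high/low
prediction against the dichotomized score (s > 0), computed on the
training/testing sets respectively; fold stratification uses the
whole-sample score sign. This dichotomization is this package's choice of
accuracy metric for continuous traits.

## Association models

"Allelic model" means the log-additive per-allele dose term (0/1/2) in a
logistic regression — the only reading under which covariate-adjusted
allelic ORs exist. Dominant = 0/1/1, recessive = 0/0/1. Fits are
maximum-likelihood logistic regressions (statsmodels Logit; convergence
tolerance 1e-8, max 50 iterations; separation and constant predictors raise
named errors — e.g. a recessive fit with no minor-allele homozygotes).
Wald 95% CIs use z = 1.96 with no small-sample correction.

Risk alleles are declared empirically from the adjusted single-locus allelic
fit (OR > 1 ⇒ the minor allele is the risk allele); the trend model
regresses case status on the 0–4 risk-allele count across a locus pair.

The high/low-risk combination OR is the 2×2 of case status by high-risk cell
membership (EMPTY ⇒ low), with ad/bc, Woolf log-method CI
(Haldane-Anscombe +0.5 on zero cells, flagged) and Pearson chi-squared p.
Because whole-sample ("re-substituted") labels reuse the data that defined
them, the pipeline also reports a fold-wise OR in which each subject is
classified by a partition fit without them; the re-substituted OR is marked
optimistic.

The multiplicative-deviation test adds the product of the two encoded loci
to the main-effects logistic model and reports the product-term Wald p and
the 1-df likelihood-ratio p. Under pure (zero-marginal) epistasis this test
has little power at study sample sizes while GMDR detects the pair — the
dissonance the cell-based search exists to resolve.

## Synthetic cohorts

Genotypes are drawn independently per locus from HWE proportions
(p², 2pq, q²); no LD is simulated (the default six loci sit on different
genes). Covariates: age ~ Normal(56, 10) years, sex ~ Bernoulli(0.55),
smoking ~ Bernoulli(0.20), fasting plasma glucose ~ Normal(6.7, 2.4) mmol/l
truncated at 2.5 — magnitudes typical of a middle-aged community cohort.

Binary phenotypes follow logit P(case) = baseline + Σ per-locus effects +
covariate effects. Pure two-locus epistasis is parameterized on the
penetrance scale: the 3×3 table is target + contrast · u₁ ⊗ u₂ where each
u has zero mean under its locus's HWE weights and unit max-absolute entry
("xor" = heterozygote-vs-homozygote contrast; "checkerboard" = centered
additive dose). Population prevalence then equals the target *exactly* and
each locus's marginal penetrance is analytically constant — ground truth for
the search is exact. Penetrances outside (0,1) raise an error. Continuous
traits use the table as additive mean offsets plus Gaussian noise.

Default study conditions: 324 cases / 373 controls drawn retrospectively
(source population simulated in batches until the quotas fill; a bounded
batch count guards against infeasible specs), six loci at MAFs
(0.30, 0.39, 0.06, 0.30, 0.10, 0.40), prevalence 0.20, xor epistasis at
loci (3, 5) with penetrance contrast 0.085. The contrast was calibrated once
by pilot simulation to give a clearly detectable but not trivial signal at
this sample size (2-locus testing BA ≈ 0.57, comparable to what such panels
report in practice) and is fixed. One master seed spawns child streams for
genotypes, covariates and phenotypes, so each stage is reproducible in
isolation.

What the generator does *not* emulate: linkage disequilibrium, population
stratification, genotyping error/missingness patterns, gene-environment
interaction, and covariates correlated with genotype. Passing tests
demonstrate correctness of the machinery under the assumed sampling model,
not robustness to those real-data features.

## Trend-test power

Per Slager and Schaid's formulation: penetrances f_j = expit(a + j·log OR)
with a calibrated (Brent root-finding, tol 1e-12) so the HWE-weighted
prevalence hits the target (default 0.20, explicit config); case/control
genotype frequencies follow by Bayes inversion; the Cochran-Armitage
statistic U = Σ x_j (S r_j − R s_j)/N with weights (0,1,2) has closed-form
mean and variances under null and alternative, giving two-sided power
Φ((|μ| − z√V₀)/√V_A) + Φ((−|μ| − z√V₀)/√V_A). At OR = 1 this equals α
exactly. A vectorized Monte Carlo oracle (multinomial genotype counts, the
same trend statistic) verifies the analytic value to within ±0.02 at 20,000
simulations across a MAF × OR grid.

## Numerical and design notes

- Problem sizes in tests and the acceptance script (100-replicate recovery,
  500-replicate null/coverage runs, 1000-replicate LRT calibration,
  20,000-simulation power oracles) were chosen so each check's Monte Carlo
  error is small relative to its acceptance band.
- Degenerate inputs raise early, named errors: monomorphic loci (warned,
  retained), folds lacking a class, all-missing loci, empty 2×2 margins,
  infeasible penetrance contrasts, unreachable retrospective quotas.
- Pipeline reports are JSON/TSV with sorted keys, no timestamps and no
  absolute paths; re-running a config reproduces each report byte-for-byte
  (wall-times go to `run.log`).
- Known limitations: no VCF/imputation/LD handling, no multi-allelic or
  X-linked loci, no family data, no multiple-testing correction beyond raw
  p-values, and the sign-test calibration caveat above.
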