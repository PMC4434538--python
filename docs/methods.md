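# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `airwaydx`, in the spirit of a statistical methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The classifier and its derivation

The classifier is a logistic regression over ten features: patient age in
years (unscaled), three clinical-factor gene-expression correlates (CFGCs),
and six cancer-cluster means.  The locked parameterization ships in
`src/airwaydx/resources/locked_model.json`; scores are the logistic of the
linear form and calls use a boundary-inclusive threshold of 0.65.  Feature
accumulation during scoring follows a canonical (sorted) order so a model
serialized and reloaded reproduces scores bit-identically.

The derivation pipeline (`airwaydx.pipeline.derive`) re-creates such models
from a training cohort in five stages.

**1. CFGCs.** For each clinical factor (sex; current/former smoking;
pack-years dichotomized at >10) genes are ranked by empirical-Bayes
moderated-t p-value against the factor and those with p < 0.001 become
LASSO candidates.  An L1-penalized logistic model over the candidates is
fit along a 40-point logarithmic penalty grid (with bisection refinement
when a specific support size is requested; the per-run defaults are 1 gene
for sex, 3 for smoking, 2 for pack-years, mirroring the published
sub-models), the penalty is chosen by 10-fold cross-validated deviance, and
the surviving genes are refit *unpenalized* so the final sub-model has the
plain logistic form of the published formulas.  When the top-ranked
candidate separates the factor perfectly — the Y-linked RPS4Y1 case for sex
— a single-gene threshold rule is returned with the cutpoint at the
midpoint of the gap between classes.  On cohorts where no gene clears
p < 0.001 (null cohorts in calibration runs) the pipeline falls back to the
top-ranked genes at the configured count so it remains runnable end to end.

**2. Clinical baseline and residuals.** Cancer status is regressed on GG,
GS, GPY and age by maximum likelihood.  *Response* residuals (observed
status minus fitted probability) are exposed: they are bounded in (−1, 1),
exactly orthogonal to the fitted covariates by the score equations, and the
paper-family literature does not specify a residual type, so the simplest
interpretable choice is used.  Perfect separation raises an explicit error
recommending a penalized fit rather than silently returning divergent
coefficients.

**3. Cancer-gene selection.** For each gene, the residual vector is
regressed on the gene's expression and the moderated |T| compared with 2.7.
The moderated-t machinery fits the variance prior (d0, s0²) by the method
of moments on log sample variances, solving the trigamma equation by Newton
iteration; posterior variances are the standard degrees-of-freedom-weighted
blend, and prior df of 0/∞ reproduce the ordinary t-test and complete
pooling exactly (both are tested limiting cases).

**4. Clustering and reduction.** Selected genes are clustered by
average-linkage agglomeration on the distance 1 − r (signed Pearson
correlation, so up- and down-regulated modules separate), with the tree cut
to the configured cluster count (default 11).  Genes are sorted before
linkage and clusters relabeled by decreasing size (ties by alphabetically
first member), making the partition invariant to input order.  Each cluster
is reduced greedily: start from the gene most correlated with the cluster
mean and add the gene maximizing the correlation of the running subset mean
with the full cluster mean, stopping at correlation ≥ 0.95 or 4 genes
(never fewer than 2).

**5. Cluster-subset search and the final fit.** Candidate cluster means are
added to the covariates by forward selection scored by repeated stratified
10% holdout CV AUC (default 100 repetitions; fold assignments are shared
across candidates so comparisons are paired).  A cluster is admitted only
when its paired per-fold AUC improvement is significant (one-sided paired
t, p < 0.01).  This is deliberately stricter than "any improvement":
with re-used folds and ridge-shrunken candidates, a plain argmax rule
demonstrably admits noise clusters, while the significance rule implements
the intended criterion that a cluster be *independently* informative in the
context of those already included.  Sequential selection still carries an
irreducible family-wise false-inclusion rate, so validation on planted
cohorts asserts that every signal cluster is admitted with at most one
extra.  The final model is a penalized logistic fit minimizing the summed
negative log-likelihood plus Σ λ_j β_j², with λ = 0 on the clinical
correlates and age and λ = 10 on each cluster mean.  A squared (ridge)
penalty is the default because all six published cluster coefficients are
nonzero, which an L1 penalty of that magnitude would typically preclude; an
L1 mode (proximal gradient/FISTA) is available.  Penalties apply to
coefficients on standardized features and the fit is transformed back to
original units; with all penalties zero the optimizer reproduces the plain
ML solution to ~1e-7 (oracle-tested against statsmodels).  The decision
threshold is the largest cutoff achieving ~90% sensitivity among cancers
with a non-diagnostic bronchoscopy in the training cohort.

## Statistical machinery

* **Fisher exact tests.** 2×2 via scipy; r×c via a hand-written
  Freeman–Halton enumeration over all tables with the observed margins
  (probability-mass ordering, relative tolerance 1e-7, matching common
  implementations), with a table-count guard and a seeded Monte-Carlo
  fallback by permutation of category labels.
* **Binomial intervals.** Wilson score intervals throughout.  The method
  reproduces the printed 51% (40–62%) interval for 40/78 where
  Clopper–Pearson does not; displayed percentages round half-up to integers.
* **AUC.** Mann–Whitney formulation with midranks; variance and paired
  model comparisons by DeLong's method (hand-written; the point estimate is
  oracle-tested against brute-force concordant-pair counting and the
  comparison against sklearn).
* **CV harness.** Repeated stratified 10% holdout re-running the *entire*
  derivation inside each training fold; held-out ids never reach any
  selection step (asserted structurally in tests).  Pooled AUC concatenates
  held-out scores across repetitions.  On a single null cohort the pooled
  estimate carries ~0.05 of correlated wobble because every repetition
  reuses the same 299 samples; calibration checks therefore average over
  independent cohorts.

## Synthetic cohorts

`simulate_cohort` generates the structure the derivation assumes, with
ground truth: log2-scale Gaussian expression (noise sd 1.0, baselines
uniform on 4–10); 11 planted cancer clusters of 20 genes, each a shared
per-sample latent factor scaled so the within-cluster correlation is 0.6,
shifted by a signed per-cluster effect (default ±1.0 log2 units in six
clusters — two up, four down — and zero in five) in cancer samples; five
sex-marker genes with a 5-log2-unit male/female gap (far exceeding the
noise, emulating a Y-linked transcript); 50 smoking- and 30
pack-year-associated genes (±2.0 and ±1.5 log2 units); everything else pure
noise.  Cohort composition defaults to 223 cancer / 76 benign with older,
heavier-smoking cancer patients (ages ~N(65,10) vs ~N(56,12), pack-years
~N(43,25) vs ~N(30,22), floors applied), and a bronchoscopy that detects
~50% of cancers with no false positives.  `null_config` zeroes every effect
and equalizes the class distributions for calibration runs.  All randomness
is PCG64 (`numpy.random.default_rng`); identical configs and seeds are
bit-reproducible.

`simulate_from_locked` draws cohorts *from* the locked model: model genes
are generated at log2 scale (bimodal RPS4Y1 by sex; smoking/pack-year genes
coupled to the drawn clinical attributes; each cluster feature a latent
N(m, 1) per sample with per-gene noise sd 0.4), features are computed
exactly as the scorer computes them, and cancer status is Bernoulli in the
score.  Feature means were chosen once so the cohort has ~0.75 cancer
prevalence and AUC ≈ 0.8, mirroring the derivation cohort, and are not
tuning knobs.  `simulate_platform_shift` adds a gene-wise N(0, sd) constant
and removes listed genes — the condition the mean-shift adjustment and
imputation must undo.

What the generators deliberately do **not** emulate: probe-level effects,
batch structure beyond gene-wise shifts, non-Gaussian heavy tails,
gene–gene correlation outside planted clusters, missing data, or QC
failures.  Passing tests therefore demonstrate that the pipeline's linear
statistics behave correctly under their own assumptions, not that the
classifier's published performance transfers to any real cohort.

## Validation experiment design

* **Coefficient recovery** refits the differential-penalty model on cohorts
  of n = 2000 drawn from the locked model and compares the *mean* estimate
  over five replicate cohorts with the generating coefficients (all ten
  signs; magnitudes within 25% where |β| > 0.3).  A single cohort leaves
  several coefficients with ~17–20% relative standard error, making a 25%
  check a coin flip; averaging five replicates brings every relative SE
  under ~9%.
* **Derivation recovery** measures planted-gene recall of the full pipeline
  and the adjusted Rand index of the clustering on the planted 11-module
  gene set.  Gene misses are cluster-correlated (a weak latent draw lowers
  a whole module), so the acceptance script averages recall over three
  cohorts.
* **Null calibration** checks Kolmogorov–Smirnov uniformity of moderated-t
  p-values at 10,000 genes, the |T| > 2.7 false-selection count against its
  ~70-gene normal-tail expectation, and chance-level leak-free CV AUC
  averaged over three null cohorts.
* **Cross-platform round trip** shifts a locked-model cohort, drops LYPD2
  and RNF150, adjusts and imputes, then verifies per-gene means match the
  training reference to 1e-10 and the locked classifier's AUC moves by less
  than 0.01.  The AUC comparison uses a 5,000-sample cohort: imputing two
  genes as constants removes real signal (a population-level AUC gap of
  about 0.005), and a large cohort isolates that method effect from
  sampling noise.  Problem sizes throughout (cohorts of 299–5,000, 1,500–
  10,000 genes, 4–30 CV repetitions) were chosen as the smallest giving
  stable Monte-Carlo estimates for each check.

## Known limitations

* The published model's training-set gene means were never printed; the
  packaged locked model therefore carries no reference means, and scoring a
  real cohort from another platform requires a user-supplied reference
  (`adjust` accepts either a reference JSON or a model embedding one).
* Reported cohort tables contain one internal inconsistency: the
  non-diagnostic classifier sensitivity appears both as 92% and as 34/38 =
  89% in different tables of the source report.  `reproduce-tables` emits
  the footnote arithmetic (89%) and this note records the discrepancy
  rather than resolving it.
* The r×c exact test enumerates tables and is practical only for small
  margins; the Monte-Carlo mode trades exactness for scale.
* CD177.1 and CD177.2 are treated as two distinct expression features (two
  transcript-cluster measurements of one gene); input matrices must carry
  both identifiers, and the symbol spellings CLND10/CLND22 follow the model
  definition with CLDN10/CLDN22 accepted as read-time aliases.
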