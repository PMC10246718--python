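# Methods

`tepdx` implements a complete tumor-educated-platelet (TEP) diagnostic
analysis for ovarian cancer: a synthetic multi-cohort platelet RNA-seq
generator with known ground truth, count-level QC and confounder correction,
a minimum-redundant-gene-filtering (MRGF) panel-selection cascade, an
RBF-SVM classifier with an optional CA125 combination, and a
diagnostic-statistics battery. This note records the models, the defaults
and why they were chosen, and what the synthetic data can and cannot show.

## The synthetic study

Real platelet RNA-seq cohorts of this kind are gated behind material-transfer
agreements, so every stage is exercised on simulated data whose generative
truth is recorded.

**Counts.** Gene *i* in sample *j* is negative-binomial with mean

    mu_ij = L_j * exp( b_i + log(2)*lfc_i*1[OC_j] + batch_ij + s_i*(age_j - age_ref) )

and variance `mu + alpha_i * mu^2`. The relative-abundance weights
`exp(b_i)` are log-normal (log-mean 3.0, log-sd 1.5) and normalized to sum
to one, so column sums track the drawn library sizes `L_j ~ logNormal(log 8e6, 0.35)`.
The dispersion follows the standard RNA-seq trend `alpha_i = a0/mu_i + a1`
with `a0 = 1`, `a1 = 0.4`. The asymptote 0.4 (≈63% biological CV for
well-expressed genes) is deliberately in the inter-patient clinical-cohort
regime: with it, a single differentially expressed gene at log2FC ≈ 1.5 has
an individual AUC of ~0.85–0.9 rather than ~1.0, which is the regime in
which multi-gene panels — rather than single markers — are actually needed.
Smaller asymptotes make every signal gene individually near-perfect and the
whole selection problem trivial.

**Structure.** Signal genes (default 60 of 5000) receive OC-vs-control
log2 fold changes drawn from N(1.5, 0.3); a disjoint set of 100 age genes
drifts with patient age (log-slope N(0.01, 0.003)/year, random sign); each
batch shifts a random 30% gene subset by gene-wise log-normal factors
(sd 0.3). Age/signal disjointness makes confounder-correction tests
unambiguous; the sparse batch footprint makes surrogate-variable recovery
testable.

**Cohorts.** Defaults reproduce a four-cohort design — training
(289 OC / 182 benign adnexal mass (BAM) / 49 healthy), two validation
cohorts (40/25/8 and 87/68/7) and a third validation cohort
(29/14/86) with an age distribution shifted +7 years, OC prevalence 22.5%
and 73% missing CA125, emulating an older, lower-prevalence European arm of
an otherwise Chinese hospital study. Histology, FIGO stage and grade are
drawn from realistic gynecologic-oncology referral proportions so the
subgroup harness (endometriosis, borderline, early-stage, non-epithelial,
high-grade serous) has members.

**CA125.** log10 CA125 (mU/L) is normal per class — OC (2.0, 0.8),
BAM (1.25, 0.45), healthy (1.1, 0.35) — giving a raw-marker AUC near 0.8
with realistic overlap around the clinical 35 mU/L cut-off. CA125 is
simulated independently of the transcriptome given the class, so any gain of
the combined model is attributable to genuinely independent information.

**Ground truth.** Besides signal-gene identities, the generator records each
sample's exact Bayes posterior P(OC | signal-gene counts) under the
generative model with the cohort prevalence as prior. Its AUC is the
generative optimum against which trained classifiers are compared.

**What the simulation does not emulate.** Gene-gene co-expression modules
(genes are conditionally independent given class/batch/age), platelet-specific
abundance profiles (weights are generic RNA-seq-like), isoform/splicing
structure, and any transcriptome–CA125 dependence. Passing tests therefore
demonstrate correctness of the pipeline's statistics and selection logic on
NB data with known truth, not clinical performance on real platelets.

## Preprocessing

Order is fixed: sample filter, then gene filters, then normalization.
Samples with fewer than 5e6 total reads are dropped. Genes with <10 reads
in more than 10% of samples, or with raw-count coefficient of variation
(population sd / mean) above 3, are excluded; the CV is computed on raw
counts because the filter precedes normalization. Size factors are
DESeq2-style median-of-ratios (geometric mean 1, total-count fallback when
no gene is everywhere positive). The variance-flattening transform is
`log2(count/sf + 1)` — a monotone shifted-log stand-in whose tested property
is flattening of the NB mean-variance trend; downstream stages
(correlation, LASSO, SVM) depend only on that property, not on a particular
closed-form transform. Differential expression for the discovery-style
clustering uses Welch t on the transformed scale with Benjamini–Hochberg
correction and the base-mean > 10 rule; hierarchical clustering uses Ward
linkage on 1 − Pearson distances (zero-variance samples sit at distance 1).

**Surrogate variables.** Gene-wise residuals from a regression on
(intercept + class) are decomposed by SVD; the number of surrogates is set
by permutation parallel analysis on the *proportion of variance* of each
component: each gene's residuals are permuted independently, re-residualized
against the design (so permuted rows live in the same design-orthogonal
subspace), and a component is kept while its observed variance proportion
exceeds the permutation 95th percentile. The proportion statistic makes the
null scale-invariant; raw singular values are biased by the variance lost to
re-residualization. On pure noise the procedure returns k = 0 in ~95% of
runs, and a planted two-batch effect (sd 1.0, 30% of genes) is captured by
SV1 with |correlation| > 0.9.

**Nuisance regression.** Each gene is fitted on [class | age, log10 total
reads, batch indicators, SVs]; only the *centered* nuisance component is
subtracted. Centering preserves each gene's overall level so that training
standardization constants transfer across cohorts; because class is in the
design, class-associated variation — including the part collinear with
nuisance terms — is preserved. The operation is a projection (idempotent to
1e-8). Total read count is computed before sample filtering; missing ages
are imputed with the cohort median (with a warning).

## MRGF panel selection

Five stages, sizes recorded: (1) re-application of the abundance/CV gene
filters; (2) greedy correlation pruning at |r| > 0.90 (caret-style: of the
most correlated pair, drop the member with the larger mean absolute
correlation); (3) L1-penalized logistic regression on standardized features
over a 100-point log-spaced lambda grid spanning four decades below the
smallest all-zeroing lambda, with the lambda minimizing 10-fold CV binomial
deviance (lambda.min, not 1-SE) defining the support; (4) greedy mRMR
ranking (MID scheme: relevance minus mean redundancy, both plug-in mutual
information after 10-bin equal-frequency discretization; optional bootstrap
ensemble aggregated by mean rank, ties to higher relevance); (5) incremental
selection: 10-fold CV accuracy of a default RBF SVM (cost 1, kernel width
from the median squared pairwise distance) on the top-k ranked genes,
k* = argmax with ties to the smallest k.

The L1 solver is liblinear with intercept scaling 1000 (the intercept
penalty is then negligible); path coefficients agree with an independent
proximal-gradient reference to better than 1e-4.

**A known degeneracy.** When effect sizes are strong enough that CV accuracy
saturates at 1.0 for small k, the argmax/smallest-k rule truncates the panel
well below the full set of informative genes (the information is genuinely
redundant for classification at that sample size). In such regimes the
LASSO-stage support is the better measure of signal recovery: in the
packaged synthetic benchmark (200 training samples, 5000 genes, 60 signal
genes at log2FC ~ N(1.5, 0.3)) the LASSO support contains ~⅔ of the signal
genes with zero noise contamination, while the final incremental panel stops
at ~5 genes — with held-out AUC within 0.001 of the generative optimum.
Both panel-level and LASSO-stage recovery are reported.

## Classifier

(cost, sigma) are drawn log-uniformly from the conventional libsvm ranges
(cost 2^-5..2^15, sigma 2^-15..2^3; sigma is the `exp(-sigma*||x-y||^2)`
width) and chosen by stratified 10-fold CV accuracy; ties keep the first
draw; 5000 draws is the full-scale search and 200 the desk-scale default.
The SVM is fitted on per-gene standardized panel expression; probabilities
come from Platt scaling fitted on out-of-fold decision values (5 stratified
refits) to avoid resubstitution optimism. The operating cut-off is 0.5, with
probability exactly 0.5 called positive. Models are frozen, self-contained
objects (panel, standardization constants, support vectors, kernel and
Platt parameters) serialized to versioned JSON; prediction aligns genes by
identifier and fails loudly on missing panel genes.

**CA125 combination.** A logistic stack over [logit(p_TEP), log10(CA125+1)],
fitted on training-cohort outputs with complete cases only; samples with
missing CA125 fall back to the TEP probability at prediction. The stacking
form is this package's choice — how the original combination was computed is
not specified anywhere we could follow — and is flagged as such.

## Evaluation battery

AUC is the Mann–Whitney estimator with ties counted 1/2; its variance uses
DeLong structural components, the CI is normal-approximation truncated to
[0, 1], and correlated markers are compared with the two-sided DeLong test
(zero-variance differences report p = 1 with a warning). Rates carry exact
Clopper–Pearson CIs; kappa uses row/column marginal chance agreement; rates
with zero denominators are reported missing, never zero.
`metrics_from_rates` reconstructs TP/FP/TN/FN from printed SN/SP percentages
and cohort sizes (nearest-integer rounding, warning if irreconcilable
beyond 0.05 points), enabling exact cross-checks against published
diagnostic tables. The permutation test uses the add-one estimator
(1 + #{AUC_perm >= AUC_obs})/(B + 1). Fixed-specificity operating points
scan thresholds at midpoints between distinct scores plus infinite
sentinels, taking the smallest threshold whose specificity reaches the
target. Decision curves report net benefit TP/N − FP/N · p_t/(1−p_t)
against treat-all and treat-none references. The subgroup harness evaluates
TEP, CA125 and the combination on the endometriosis-vs-OC,
borderline-vs-BAM, early-stage(FIGO I–IIA)-vs-BAM, non-epithelial-vs-BAM
and high-grade-serous-vs-BAM contrasts, with DeLong comparisons against
CA125 on CA125-complete cases.

## Reproducibility and problem sizes

A single global seed fans out to per-stage child seeds by stable hashing, so
stages rerun in isolation reproduce exactly; two runs with identical
config/seed produce byte-identical reports (timestamps live only in the run
manifest). Run directories are scoped by a configuration digest and stages
never overwrite each other's artifacts.

Default problem sizes are chosen for single-workstation runs: 5000 genes,
the four cohort sizes above, 200 random-search draws (the full 5000 is one
config key away), B = 999 permutations. The full pipeline — simulation
through the diagnostic report — completes in minutes on one CPU.

## Known limitations

- The shifted-log transform is not the closed-form dispersion-based
  variance-stabilizing transform; only the flattening property is claimed.
- DEG testing is Welch-t based, not an NB Wald test with shrinkage; effect
  sizes on low-count genes are therefore unshrunken.
- The incremental-selection degeneracy above: panel size is not a reliable
  readout of the number of informative genes when classes are easily
  separated.
- CA125 independence from the transcriptome is an assumption of the
  generator, not a biological claim; it makes combination gains predictable
  rather than realistic.
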