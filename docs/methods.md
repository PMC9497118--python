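# Methods

## Overview

`comboscreen` prioritizes single therapies and doublet drug combinations for
melanoma-like cohorts by integrating three lines of per-patient evidence —
somatic mutation status of a drug's target genes, a one-dimensional summary
of their expression, and the mutation–expression association — through Cox
proportional-hazards survival models and Fisher's product method (FPM),
replicated across two independent patient cohorts (labeled `t`, a large
discovery cohort, and `m`, a smaller validation cohort).

## Gene-set coding

For a drug with target-gene set G:

* **Mutation indicator** `x`: 1 for a patient iff at least one gene of G
  present in the cohort's mutation matrix carries a protein-altering somatic
  mutation. Target genes absent from the matrix are ignored and recorded;
  a set with no present gene yields *unavailable* evidence, and a constant
  indicator (nobody, or everybody, mutated) is *degenerate* — not estimable.
* **PC1 score**: the first principal component of the per-gene mean-centered
  (not variance-scaled) expression of G, computed per cohort by SVD.
  Unscaled centering is the common default for expression principal-component
  summaries; scaling would up-weight low-variance genes. The loading vector
  has unit norm, and its sign — statistically arbitrary, since all downstream
  tests are two-sided — is fixed by requiring the loading sum to be positive
  (exact zero broken by the alphabetically first gene), making outputs
  reproducible run to run. A single-gene set returns the centered gene with
  loading +1 and variance fraction 1.

## Batch adjustment

Expression is adjusted across the two cohorts by a per-gene location-scale
correction to the pooled reference: each cohort's gene values are
standardized by the cohort mean/sd and rescaled to the grand mean and the
within-cohort pooled variance. Using the *within-cohort pooled* variance
(not the variance of the concatenated data) matters: the concatenated
variance would absorb the very batch shift being removed, and it makes the
transform an exact no-op on identical cohorts. This is the defining
mean/variance-equalizing core of the classic two-batch empirical-Bayes
correction, deliberately without the shrinkage step: with two large batches
and no model covariates, shrinkage of the batch parameters is a second-order
refinement. Genes with zero variance in either cohort are recentered only.

## Survival models

All models adjust for age and the two treatment flags (BRAF-inhibitor,
checkpoint-inhibitor). Single-therapy models use one primary covariate
(the indicator `x`, or the PC1 score); doublet models use both drugs'
primaries plus their product as an interaction term:

    h(t | ·) = h0(t) · exp(β1·x1 + β2·x2 + β3·x1x2 + βa·age + βB·BRAF + βI·IPI/NIVO)

fit separately for the mutation coding and the expression (PC1) coding.
Fits use the partial likelihood with Efron tie handling (lifelines); every
reported p-value is the per-term two-sided Wald p.

Robustness policies, chosen to be conservative (a failed fit must never
promote a candidate):

* fewer than 2 events → non-estimable, flagged, p = 1 for retained terms;
* constant covariates, and *quasi-constant* binary covariates with fewer
  than 3 subjects in the minority class, are dropped before fitting and
  reported as missing evidence (not p = 1). The quasi-constant rule matters
  in practice: a cohort with 2 treated patients of 459 produces a monotone
  partial likelihood that halts Newton iteration outright;
* if the fit still fails (separation), the sparsest *unprotected* binary
  adjustment covariate is dropped and the fit retried; primary terms are
  never auto-dropped — if the model cannot be fit with them, the fit is
  reported failed with p = 1.

## eQTL test

Per drug and cohort, a two-sided Wilcoxon rank-sum test of the PC1 score
split by the drug's own mutation indicator: does mutation in the set shift
its expression summary? Exact enumeration is used when both groups have at
most 10 observations and no ties; otherwise the tie-corrected normal
approximation with continuity correction.

## Evidence combination

Fisher's product method: for k available p-values,
χ² = −2·Σ ln p ~ χ²(2k) under the null. p-values are clamped to
[1e-300, 1] before the log, and summation uses exactly-rounded `fsum`, so
results are bitwise permutation-invariant. Unavailable terms are dropped
and the degrees of freedom shrink by 2 each — the standard meta-analytic
treatment of an unavailable study; imputing p = 1 instead (config
`fpm_missing: impute_one`) would penalize drugs whose target genes simply
lack mutations in a cohort.

* **Single screen**: per cohort, FPM over {p_mut, p_expr, p_eqtl} (df ≤ 6);
  then FPM over the two cohort-level combined p (df ≤ 4); BH-FDR across
  drugs with available evidence. Seeds = {q < 0.05} ∪ forced clinical
  inclusions, deduplicated, alphabetical.
* **Doublets** (all unordered pairs containing ≥ 1 seed; lexicographic
  canonical order): eight terms per cohort — pM1, pM2, pM3 (mutation mains
  and interaction), pE1, pE2, pE3 (expression), pQ1, pQ2 (per-drug eQTL).
  - *Method 1*: FPM over all ≤ 16 terms.
  - *Method 2*: FPM over the four expression main effects, plus a filter
    flag requiring all four to be available and < 0.05.
  - *Method 3*: per cohort take the single smallest available term
    (tie-break by the fixed family order mutation < expression < eqtl,
    then term name); if both cohorts' minima come from the same Cox model
    family, substitute that family's interaction-term p where available;
    FPM over the two values (df ≤ 4). Whether eQTL terms compete in the
    minimum is configurable (`method3_families: all | cox_only`; default
    all, since the rule speaks of the evidence from all three analyses).

### Calibration caveat

FPM's χ² reference assumes independent inputs. Measured on fully null
simulations (disjoint-drug pairs across independent replicates): each of
the 16 term p-values is individually uniform, and **Method 2 is well
calibrated** (its four inputs come from two independent cohorts and two
nearly orthogonal covariates per fit). **Method 1 is mildly miscalibrated**
(KS D ≈ 0.11): main-effect and interaction terms from the same fit are
correlated, and the eQTL terms share the PC1 scores with the expression
model. **Method 3 is strongly anti-conservative** (KS D ≈ 0.64): the
minimum of ~8 p-values is Beta(1, 8)-distributed, not uniform, and the rule
applies no order-statistic correction. These are properties of the
combination rules themselves, reported as measured; Methods 1 and 3 should
be read as ranking scores, not as calibrated p-values. The per-cohort
p < 0.05 filter on Method 2, and the optional BH q-values over each
method's combined p, are the multiplicity controls.

## Subgroup analyses

The full doublet scoring can be repeated within the BRAF, NRAS and
TripleWT genotype subgroups. Covariates that become constant within a
subgroup (e.g. BRAF-inhibitor treatment among TripleWT patients) are
dropped by the standard rule. A subgroup with fewer than 10 patients in a
cohort contributes no terms from that cohort (flagged).

## TME profiling

From a labeled cell × gene scRNA-seq matrix: per cell type, the mean
expression and expressing fraction of each target gene, summarized as a
per-type set score (mean over the drug's present genes). Counts are
optionally normalized per cell to the median depth and log1p-transformed —
the conventional default, switchable off for pre-normalized input. Doublet
divergence = 1 − cosine similarity of the two set-score vectors. No
perturbation modeling is implied: "targeting" means target-gene expression
by compartment.

## Synthetic cohorts

The generator emulates the two-cohort design: default sizes 459 and 135;
genotype fractions (BRAF/NRAS/TripleWT) 0.514/0.272/0.192 and
0.437/0.252/0.207; checkpoint-treatment rates 0.033 and 0.378,
BRAF-inhibitor rates 0.011 and 0.215 (assigned only to BRAF-genotype
patients, with the conditional rate inflated to match the marginal); age
N(61.5, 15²) truncated to [18, 95]; 62% male.

Genes live in co-expression modules of 5; expression is
`base + 0.7·factor + √(1−0.7²)·noise` with gene base levels N(6, 1) on the
log scale, so a drug's target set (drawn within one module, size
1 + Poisson(2)) is correlated and PC1 recovers the latent factor. Gene-level
mutation prevalences are Uniform(0.02, 0.25), shared between cohorts.
Survival follows a Cox–Weibull model (shape 1.2, scale 1500 days — so
proportional hazards holds exactly) with a mild age effect (log-HR 0.1 per
sd) plus any configured effects: mutation-indicator hazards, latent-factor
"expression" hazards (injected on the factor so the expression model is
well-specified — the generative assumption under which the PC1 survival
model is the right analysis), pairwise mutation-interaction hazards, and
eQTL shifts (expression-only). Cohort `m` receives per-gene N(0, 1)
additive batch offsets. Censoring is an independent uniform–exponential
mixture whose scale is calibrated by bisection to the configured rate
(default 0.45, typical of long-follow-up melanoma cohorts). The seed fully
determines every draw; a truth record retains all injected effects.

What the generator does *not* emulate: count-level noise (expression is
Gaussian on the log scale), gene-gene correlation beyond block modules,
mutual exclusivity or co-occurrence of driver mutations, non-proportional
hazards, informative censoring, and any coupling between genotype labels
and the simulated mutation matrix. Passing tests therefore demonstrate
correctness and calibration of the *procedure* under its own assumptions,
not performance on real cohorts.

## Problem sizes in the test and acceptance runs

Simulation-based checks use deliberately chosen sizes: type-I error at
n = 200 (1000 replicates), log-HR recovery at n = 300 (200 replicates),
doublet interaction power at n = 400 (100 replicates), null calibration
over 1000 doublet scores drawn as disjoint-drug pairs across 50 replicate
simulations (disjointness keeps the uniformity test's independence premise
honest). Module-level tests use smaller replicate counts of the same
designs. `scripts/acceptance.py` re-runs the same designs at moderately
reduced replicate counts, with every RNG derived from the `--seed` flag.

## Known limitations

* A binary indicator at n = 300 information-bounds the Cox coefficient's
  sampling sd at ≈ 0.16–0.18 (even with light censoring), so coefficient
  recovery within ±0.25 plateaus near 85–90% for indicator covariates; the
  recovery check therefore uses the continuous latent factor, which the
  generator stores in its truth record.
* Methods 1 and 3 are not calibrated p-values (see above).
* The location-scale batch adjustment omits empirical-Bayes shrinkage;
  with many small batches it would over-correct — it is intended for the
  two-large-batch design only.
* No proportional-hazards diagnostics, Firth penalization, or time-varying
  covariates; separation is handled by the conservative p = 1 policy.
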