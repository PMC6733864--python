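# Methods

`dysbiome` implements a meta-analysis procedure for characterising dysbiosis
across chronic-disease cohorts from 16S OTU count tables.  This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data does and does not establish.

## The analysis in one paragraph

Disease and healthy sample pools are subdivided into independent
populations by assigned random numbers; every healthy population is
compared to every disease population with a negative-binomial Wald
differential-abundance test; each comparison is summarised by the *fold
difference* — the number of OTUs enriched in the healthy group divided by
the number enriched in the disease group — and the per-disease fold
differences are tested against 1 (one-sample t, Holm-corrected).  The same
machinery run on "stochastic" groups, labelled purely by fresh random
numbers, provides the null.  Significant OTUs are reduced to genera to form
disease-by-genus presence matrices (fraction of comparisons in which a
genus had at least one significant OTU per enrichment side), clustered with
multiscale-bootstrap support.  Finally, per-genus dysbiotic-OTU counts are
regressed on genus OTU richness and genera more than three residual
standard deviations above the line are flagged as dysbiotic beyond what
their diversity predicts.  Antibiotic exposure is related to disease by
relative risk + Fisher's exact test (Holm-corrected) and to community
composition by weighted UniFrac + PERMANOVA.

## Synthetic cohorts

Counts for OTU *i* in sample *j* are negative binomial with mean

    mu_ij = a_i * N_j * 2^(disease_j * beta_i + abx_j * gamma_i)

and a shared dispersion `nb_dispersion` (variance mu + alpha mu^2).
Components:

- **Baseline relative abundances** `a` (sum to 1): a Dirichlet realised as
  per-OTU Gamma draws whose concentrations are lognormal (sigma 1.5),
  giving the heavy-tailed rank-abundance curve typical of gut communities.
- **Library sizes** `N_j`: lognormal, default log-mean log(20 000) and
  log-sd 0.4, matching typical 16S library depth and spread.
- **Disease effect** `beta_i`: −`effect_log2fc` on a depleted subset and
  +`effect_log2fc` on an enriched subset.  Defaults: 15% of OTUs depleted,
  5% enriched, effect 2 log2 units (four-fold).  The 3:1 ratio of depletion
  to enrichment is the loss-of-function dysbiosis structure the analysis is
  designed to detect; four-fold is a moderate, realistically detectable
  effect at 100-sample populations.
- **Antibiotic effect** `gamma_i`: −`antibiotic_effect_log2fc` (default 1,
  i.e. two-fold depletion) on a random 20% of OTUs, applied to samples with
  a positive antibiotic flag.  Flags are Bernoulli at prevalence 0.25
  (healthy) vs 0.45 (disease), so antibiotic use is both a composition
  shift and a disease-associated exposure.
- **Taxonomy**: OTUs are assigned to genera with power-law sizes (exponent
  1.5, every genus non-empty); 5% of OTUs are left unclassified at genus
  level to exercise the genus-reduction filter.  `planted_excess_genus`
  concentrates half of the depleted set into one designated genus, creating
  a known three-sigma positive for recovery tests.
- **Phylogeny**: a random bifurcating tree over the OTUs built by
  successive random joins with exponential branch lengths (scale 0.1).
- **Defaults of scale**: 300 samples per health status (three subsets of
  100) and 500 OTUs over 40 genera — one pooled-source health-status pool
  at desk scale.  `simulate_study` shares one community (abundances,
  taxonomy, tree, antibiotic-affected set) across a healthy pool and
  several disease groups, each with independently drawn effect sets.

What the generator does **not** emulate: compositionality (effects are
planted on absolute means, not as a closed composition), inter-individual
variability beyond NB noise, batch/study effects, read-level error, and
taxonomic realism.  One visible consequence: samples are exchangeable
within a status, so stochastic-label comparisons typically yield *zero*
significant OTUs, whereas on real data they yield many (balanced between
the two arbitrary groups).  A stochastic grouping with fewer than two
defined fold differences is therefore reported as "no evidence of bias"
rather than tested; passing the stochastic-null check here shows the
pipeline does not manufacture a signal from noise, not that it reproduces
the variance structure of real inter-individual data.

## Differential abundance

A deliberate simplification of the DESeq2 family of NB Wald tests, keeping
exactly the quantities the downstream analysis uses (log2 fold change, its
standard error, Wald p, BH-adjusted p):

- **Size factors**: median-of-ratios against the per-OTU geometric mean over
  OTUs present in every sample, then rescaled to geometric mean 1.  When no
  OTU is present everywhere, the reference uses positive counts only
  (poscounts-style fallback).  A fully zero sample is an explicit error.
- **Dispersion**: per-OTU method of moments on normalized counts,
  `alpha = max(1e-8, (s^2 - m)/m^2)`, no shrinkage toward a trend by
  default (an optional log-log trend blend is provided via
  `shrink_dispersion`).  No Cook's-distance outlier handling, no
  independent filtering, no LFC shrinkage; validity rests on the
  calibration and recovery tests rather than on replicating those
  internals.
- **GLM fit**: per-OTU NB regression with log link, group indicator and
  log-size-factor offset, dispersion fixed; IRLS with closed-form 2x2
  normal equations vectorised across OTUs; convergence 1e-8 on the working
  weighted RSS, max 100 iterations; linear predictors clipped at ±50.
  OTUs absent from one entire group have an infinite MLE; they receive a
  0.5 pseudocount across all samples, which keeps the estimate finite and
  exactly antisymmetric under label flipping.
- **Significance**: two-sided normal p on the Wald statistic,
  Benjamini-Hochberg adjusted; "differentially abundant" means adjusted
  p < 0.05 (configurable — no alpha is canonical for this analysis).
- A caution established by the tests: median-of-ratios compresses fold
  changes when a large, one-sided fraction of OTUs is differential (25%
  depleted in a 40-OTU toy biases −2 to about −1.6).  At the study
  conditions (≤20% affected among hundreds of OTUs) the bias is negligible.
- The claim that rescaling one library leaves Wald statistics exactly
  unchanged holds only where NB working weights saturate (alpha·mu >> 1);
  it is tested in that regime with tolerance 0.15.

## Population design

Random numbers are uniform on [0, 1), redrawn on collision so ranks are
strict.  Subsets are consecutive rank blocks (lowest/middle/highest 100 by
default).  A status with fewer than `subset_size x n_subsets` samples but
at least one full block yields the blocks that fit (the small-cohort,
single-subset case); fewer than one block is an error.  Stochastic groups
reassign fresh random numbers ignoring all metadata and split the pool
into 2 pseudo-statuses x 3 subsets, mirroring the disease design (the
subset size for the null is not dictated by anything; mirroring the real
design makes the null comparisons exchangeable with the real ones).
Cross designs pair every healthy subset with every disease subset (3x3=9,
3x1=3); study-wise designs pair positionally, one comparison per study.

## Fold difference and its t-test

`fold = n_healthy / n_disease` per comparison.  A zero denominator is
substituted by 1 and flagged (configurable to exclude); both counts zero is
undefined and excluded.  The t-test runs on the raw ratio values against a
mean of 1 — ratios are already positive, so "absolute values" is read as
the untransformed ratios, with the plotting transform (ratios below 1
inverted and negated) applied only for display.  Holm correction spans the
disease groups tested in one run.  Zero-variance edge cases: all ratios
exactly 1 gives p = 1; zero variance off 1 is degenerate and flagged with
p = 0.

## Genus matrices and cluster support

Cell value = fraction of a disease's comparisons in which the genus had at
least one significant OTU on the given side; unclassified-at-genus OTUs are
dropped; genera never significant on either side are pruned.  The two sides
(depleted in disease = "potentially beneficial"; enriched in disease =
"potentially pathogenic") are clustered separately.

Clustering is Euclidean distance + complete linkage by default
(correlation/average available).  Support follows the multiscale bootstrap:
for scales r in {0.5, 0.6, ..., 1.4}, resample ceil(r·m) genus columns with
replacement `n_boot` times (default 1000), re-cluster, and record
bp(node, r) = fraction of replicates containing the node's leaf set.  AU is
obtained from the weighted least-squares fit

    probit(1 - bp(r)) = v*sqrt(r) + c/sqrt(r),   AU = 1 - Phi(v - c)

with binomial-variance weights; bp is clamped to
[1/(B+1), B/(B+1)] before the probit.  Unanimous profiles (bp = 1 or 0 at
every scale) map to AU = 1 or 0 directly; a matrix of identical rows has a
forced topology and support 1.  Reported bp is the fraction at scale 1.
AU > 0.95 is stored as a significance flag, never as a filter.

## Diversity adjustment

Per genus: total OTUs in the (filtered) table vs dysbiotic OTUs — by
default the *unique* OTUs significant in at least one of the disease's
comparisons, pooling both enrichment sides (comparison-weighted "events"
counting and per-side restriction are configurable).  The expectation is an
ordinary least-squares line through the scatter (free intercept; zero
intercept and Theil-Sen variants available) — the minimal model of
"expected given diversity".  Residual SD uses n−2 degrees of freedom; a
genus is flagged only when its residual exceeds +3 SD (one-sided: excess
dysbiosis only).

## Antibiotic association and beta diversity

Relative risk a/(a+b) / (c/(c+d)) with the log-normal 95% CI; two-sided
Fisher's exact p by the probability-mass rule (the R convention); Holm
across the diseases analysed together; missing exposure metadata dropped
listwise.  Weighted UniFrac (scikit-bio) runs on per-sample relative
abundances, normalized variant by default so distances lie in [0, 1]
(size-factor-normalized input is a flag).  PCoA keeps strictly positive
eigenvalues.  PERMANOVA uses the standard pseudo-F from squared distances
with free label permutation under an explicit seed; designs whose complete
two-group arrangement set is no larger than the permutation budget are
enumerated exactly (p = fraction of arrangements with F at least the
observed, observed included), which makes tiny-design p-values
deterministic and oracle-checkable.

## Problem sizes in tests and acceptance

Chosen as the package's own desk-scale conditions: DA calibration uses 200
null simulations (100 OTUs, 30 samples/group) and sensitivity 10
simulations at 50/group after the <10-count filter; the loss-of-function
check runs 50 full trials at the generator defaults (300/group, 500 OTUs,
9 + 9 comparisons each); three-sigma checks use 100 seeds; cluster support
1000 bootstraps; PERMANOVA power 50 seeds at 50 samples/group with 999
permutations.  `scripts/acceptance.py` recomputes the same quantities with
20 loss-of-function and 20 power seeds.

## Known limitations

- The DA engine is not DESeq2: no dispersion shrinkage, outlier handling or
  LFC shrinkage; small-sample dispersion estimates are noisy (that noise is
  what the calibration tests bound).
- Only two-group designs; no covariates, no strata in PERMANOVA.
- The stochastic-label null on synthetic data is weaker than on real data
  (see the generator section); conclusions about real inter-individual
  variability require real cohorts.
- Multiscale-bootstrap AU is asymptotic; for 4–6 row matrices it is a
  heuristic ordering of support, as in the originating R tooling.
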