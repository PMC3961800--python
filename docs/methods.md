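# Methods

## The model

`rfrs` scores the ten-year relapse risk of node-negative, ER-positive,
HER2-negative, chemotherapy-naive breast tumors.  The core model is a
bagged ensemble of `T` classification trees (default `T` = 100,001; odd so
every majority vote is decided) trained on samples binarized into
*relapse* (event in (0, 10] years) versus *no relapse* (event-free with at
least 10 years of follow-up).  Each tree is grown on a bootstrap sample
with replacement, unlimited depth, minimum node size 1, and a random
subset of ⌊√p⌋ features per split.  The RFRS of a sample is the fraction
of trees voting *relapse*; training samples are scored only by trees whose
bootstrap excluded them (out-of-bag votes), so the training-set score
distribution is an internally cross-validated estimate.  Tree counts in
the tests default to 2,001: the very large production default buys
stability of the *vote fraction* (third-decimal reproducibility), not
discrimination, and rank-based metrics are already stable at a few
thousand trees.

Discrimination is summarized by ROC AUC in its Mann-Whitney form (ties
count one half).  Model persistence uses a versioned joblib archive.

## Cohort assembly

* **Duplicates.** Samples sharing a patient identifier, or with pairwise
  Pearson r > 0.99 across all features, are grouped by transitive closure
  and reduced to one representative.  Correlation is computed on log2
  intensities: the threshold is a near-identity test and the log scale
  stops single bright probes from dominating.  Which member is retained is
  not scientifically determined; the representative comes from the study
  listed earliest in a configurable precedence (default: first appearance
  in the clinical table).
* **Eligibility.** LN-negative, chemo-naive, HER2-negative by array, and
  ER-positive, where ER requires agreement of the clinical and array
  determinations when a clinical status exists and falls back to the array
  call alone when it does not.
* **Marker calls.** ER status uses a single designated probe set; HER2
  status uses the sum over four co-amplified HER2-region probe sets of the
  sample's ascending rank (average ranks on ties), making the score
  invariant to any monotone per-probe transform.  Cutoffs come from a
  univariate Gaussian mixture fitted by EM (k-means++ initialization, 50
  restarts, tolerance 1e-6, unequal variances — the variance structure is
  unstated upstream, so it is configurable).  The cutoff is the maximum
  observed value assigned to the lower-mean component, and positivity is
  strictly greater-than: the top of the negative mode is itself negative.
  A component collapsing below weight 0.01 raises an error advising a
  manual cutoff.
* **Outcome binarization** yields four disjoint classes: relapse,
  no-relapse, excluded-time-zero (immediately postoperative events), and
  excluded-short-follow-up (event-free, censored before 10 years; retained
  for survival analysis only).  Events after year 10 count as no-relapse.
* **Split.** Two-thirds training / one-third test within each
  (study × outcome class) stratum, largest-remainder allocation so the
  global train count hits ⌊2n/3⌉ whenever possible; single-member strata
  go to train; membership is randomized within stratum from one seed and
  is invariant to input row order.

## Feature filtering and reference genes

Filters operate on linear-scale intensities, where the background
threshold (raw value > 100) and the coefficient-of-variation window
(sd/mean between 0.7 and 10) are meaningful.  The global reference-gene
scheme applies, in order: expressed above background in ≥ 99% of samples;
top 5th percentile by mean; top 10th percentile of the remainder by
standard deviation; rank by COV ascending, return 25.  The top-SD step is
atypical for reference genes (one would expect *bottom*); it is
implemented as specified with a `sd_top=False` escape hatch.  The banded
scheme selects the five lowest-COV expressed genes per closed
mean-intensity band (0-400, 500-900, 1,200-1,600); features with means in
the gaps belong to no band.

## Signature compaction

The top 100 genes by Gini importance (features first collapsed to genes by
keeping each gene's most important feature, ties broken alphabetically)
are clustered by k-means (k = 20) on their per-gene z-scored expression
profiles across training samples (k-means++, 100 restarts, fixed seed;
whether to standardize is an open choice upstream — z-scoring makes the
clustering about co-expression shape rather than intensity).  Within each
cluster, genes on the exclusion list (probe-alignment failures,
hypothetical proteins — supplied as an input file, never hard-coded) are
removed; the highest-importance survivor is the cluster's primary and the
rest are its ranked alternates.  Exclusions can empty a cluster, which is
how a k = 20 clustering yields a 17-gene signature with 73 alternates
under a 10-gene exclusion emptying three clusters.  The eight-gene variant
removes the exclusions first, then clusters the top 90 survivors with
k = 8.

## Risk calibration

* **Thresholds.** A 3-component Gaussian mixture on the OOB score
  distribution — three components because there are three risk groups; the
  upstream component count is unstated — with each boundary the maximum
  score assigned to the lower component.  A tertile fallback sits behind a
  flag for degenerate fits.  Group assignment is low < t_low ≤
  intermediate < t_high ≤ high (lower bound inclusive for the upper
  group).  External cohorts on other platforms are grouped by matching the
  training group *proportions* (rank by score, largest-remainder
  apportionment) because mixture thresholds do not transfer across
  platforms.
* **Prevalence down-sampling.** Event samples are removed one at a time,
  uniformly at random, until the event count no longer exceeds the target
  fraction of the remaining cohort rounded up to a whole sample
  (`n_events ≤ ceil(target × n_remaining)`).  Stopping at the integer
  rounding of the target — rather than strictly below it — is what the
  printed worked example implies: a 572-sample cohort with 143 events and
  a 15% target retains 505 samples with 76 events (76/505 = 15.05%,
  reported as 15%); one more removal would undershoot.  Per-group relapse
  rates and proportions are averaged over 1,000 such down-samplings by
  default.
* **Likelihood curve.** Scores are binned into 50 equal intervals on
  [0, 1]; empty bins are skipped; the per-bin relapse fraction is smoothed
  by lowess (span 0.75).  The 95% CI is fit ± 1.96 × SE with the per-bin
  binomial standard error (continuity-floored) smoothed the same way —
  a pragmatic stand-in for a full local-regression covariance that is
  honest about bin occupancy.  The curve is fitted on one seeded
  down-sampled draw at the target prevalence (mirroring the n = 505
  curve-fitting cohort of the study design), exposes a clamped
  interpolation lookup flagged outside the fitted support, and answers
  quantile queries (fraction of the cohort at or below a predicted
  likelihood).

## Survival analysis

Kaplan-Meier curves per risk group (lifelines product-limit estimator;
censored samples stay in risk sets until their follow-up time; events
precede censorings at ties).  Group separation uses a log-rank test for
linear trend: at each distinct event time the per-group observed-minus-
expected events under the hypergeometric model are weighted by equally
spaced group scores 0/1/2; the squared weighted sum over its variance is
chi-square with 1 df.  The statistic is invariant to affine transforms of
the group scores and reduces exactly to the two-sample log-rank test with
two groups — the test suite verifies both, plus nominal type-I error
(5% ± 3% over 200 null permutations) and ≥ 95% power at p < 0.01 under a
hazard ratio of 2 per group step at n = 300.

## Cross-platform application

External cohorts are quantile-mapped onto the pooled training intensity
distribution: each sample's values are replaced by reference quantiles at
the same within-sample rank fractions, so scoring is invariant to any
per-sample monotone (in particular affine) distortion.  When several
external probes map to one signature gene, one is chosen per gene; the
default criterion is highest variance (needs no outcome labels — "best
performance" is ambiguous upstream), with mean and univariate-AUC criteria
selectable, and the choice recorded in the platform map.

## The synthetic cohort generator

`SimulationConfig` defaults describe the assembled study cohort: 858
unique samples from nine studies, a 25% baseline ten-year relapse
probability, 35.2% hormone-treated (multiplicative hazard 0.75), and
exponential censoring at 0.055/year (≈ 40% of samples lack ten-year
follow-up), with follow-up administratively capped at 20 years.  Per
sample a latent prognostic factor M ~ N(0, 1) drives an exponential
proportional-hazards relapse time with log-hazard ratio 0.8 per SD.
Expression is generated on the log2 scale and exponentiated: background
features sit near 50 and expressed features between 200 and 2,000, so the
background-threshold and COV filters bite on synthetic data exactly as on
real intensities.  Fifty signal features load 0.8 on M and are organized
into ten co-expressed blocks (shared block factor, SD 0.5), emulating the
transcriptional modules — above all the proliferation cluster — that give
real signatures their redundancy; the loading is calibrated so the
trained forest's OOB AUC lands near the 0.70 the real training cohort
supports.  The ER feature and the four HER2-region features are drawn
from two-component log-scale mixtures (positive fractions 0.8 and 0.1);
clinical ER/HER2 status mirrors the true component except in one study
left entirely missing, exercising the array-only fallback.  Study batch
shifts are additive on the log2 scale (SD 0.1); 5% of samples are
appended as near-duplicates (log2 noise SD 0.01, guaranteeing r > 0.99).
All randomness flows from one integer seed through a single generator;
identical configs produce byte-identical cohorts.

What the generator does **not** emulate: probe-level effects (it has no
probe sequences, cross-hybridization, or GCRMA artifacts), non-proportional
hazards, correlated censoring, informative treatment assignment, or
inter-study differences beyond an additive shift.  Tests passing on these
cohorts therefore demonstrate that the *pipeline machinery* recovers
planted structure under its own assumptions — not that the signature
generalizes to any real population.

## Problem sizes in the test suite

Pipeline-level checks run on cohorts of 600 samples × 300 features with
2,001 trees across ten seeds, a size at which the planted effect is
comfortably detectable while a full run stays under half a minute; the
statistical calibration checks use 100-200 simulations.  Mean OOB AUC and
mean test AUC are compared across seeds because a single test split of
~90 classifiable samples carries binomial noise of ≈ 0.06 AUC.

## Known limitations

* The mixture-based risk thresholds are sensitive to the shape of the OOB
  score distribution; on weakly separated cohorts the 3-component fit can
  place both boundaries close together, making the intermediate group
  small and its down-sampled rate noisy.  The tertile fallback exists for
  exactly this case.
* The loess CI is a smoothed binomial band, not a full regression
  variance; it is honest about bin occupancy but ignores smoothing
  covariance.
* Bit-level equality with other random-forest implementations is a
  non-goal; determinism is guaranteed only within this package under a
  fixed seed.
* Reference-gene selection implements the specified top-SD percentile
  step verbatim even though bottom-SD is the conventional choice; flip
  `sd_top` if the conventional behavior is wanted.
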