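# Methods

`consensig` implements an in-silico biomarker-discovery pipeline for binary
phenotypes measured by bulk RNA-seq across several cohorts.  The scientific
problem it addresses is instability: on omics data with few samples, many
correlated features and strong technical batch structure, single-shot
feature selection returns different gene lists for every data slice.  The
package's answer is consensus — a gene is reported only if it is selected
by multiple algorithms, in a large fraction of resampled models, across
most cross-validation folds.

## Data model and class convention

Counts are genes x samples with opaque string identifiers.  Each sample
carries a binary class, a batch (cohort) identifier and a role.  The class
encoding is fixed: **0 = metastasis, 1 = non-metastasis**.  Unusually,
class 0 is the *majority* class in the motivating PDAC (pancreatic ductal
adenocarcinoma) case study (~65% of train samples), which is why the
evaluation suite leans on imbalance-robust metrics and why class 0 is the
"positive" class for the ROC and precision-recall curves.  Roles are
`train` (used for every selection and tuning decision) and `validation`
(touched only by the final evaluation protocols).

## Preprocessing

**TMM normalisation.**  Library scale factors are the classic trimmed mean
of M-values: pick the reference sample whose 75th-percentile count
fraction is closest to the across-sample mean (ties: lowest index); for
each sample compute per-gene log ratios M and average abundances A against
the reference over genes positive in both; discard the top/bottom 30% of M
and 5% of A; the factor is the precision-weighted mean of the surviving M
values; factors are rescaled to geometric mean 1.  If fewer than 10 genes
survive the double trim, the factor falls back to 1 with a warning (note a
~20-gene matrix always triggers this; use it only for smoke tests).
Expression is then log2 counts-per-million with a pseudo-count of 0.5
(conventional, configurable).

**Gene filters** (thresholds derived from train-role samples only, masks
applied to all samples):

* *low expression*: train mean log2-CPM strictly below the 5% quantile of
  all gene means;
* *low effect*: |class-0 mean − class-1 mean| strictly below 0.1 log2
  units.  The cutoff is read on the log2 scale; it deliberately removes
  only near-zero effects, since subtle per-gene effects are expected for
  within-disease phenotypes.  The comparison carries a 1e-9 guard so a
  difference that is mathematically exactly 0.1 is kept;
* *batch inconsistency*: the sign of the class difference, computed within
  each train batch, must agree across all train batches.  No formula for
  this filter is canonical; same-sign agreement is one defensible rule and
  it is the package's, kept behind a named strategy (`same_sign`).  Under
  a three-batch null this filter alone removes ~75% of genes (sign
  agreement of three coins), which is also what makes the downstream
  component analysis tractable.

**Batch correction** is ASCA-style ("removal of systematic noise", batch
factor only): centre each gene; replace every sample by its batch mean
(the batch submodel); SVD; call a component systematic when its variance
share is at least `beta / K` with `beta = 2` and `K` the number of PCA
components of the submodel matrix (`min(samples, genes)`); subtract the
reconstruction of the systematic part from each batch; restore centres.
With a handful of batches every non-trace component passes the threshold,
so in practice the full batch-mean structure is removed; the rule exists
to drop numerical-noise components.  (Reading `K` as the batch count
instead makes the rule inert for three or more batches — no component can
reach a 2/3 share of a centred two-component submodel — so that reading
was rejected.)  Because per-batch class proportions are comparable, class
signal cancels out of the centred batch means and survives correction;
this is asserted by tests (class log-FC correlation > 0.9 before/after).

Correction is fitted **jointly on train + validation by default**.  This
mirrors how integrated multi-cohort studies are actually preprocessed and
is the one deliberate, documented train/validation contamination in the
pipeline; the leakage audit reports it as a flag, not a violation.  A
`strict` mode fits on train only and aligns each validation batch's gene
means to the train grand means, for zero-flag runs.

## Class balancing: ADASYN

Adaptive synthetic oversampling of the minority class: with `G = beta *
(majority − minority)` synthetic points to build (`beta = 1`, full
balance), each minority point receives a share proportional to the
majority fraction among its `k = 5` nearest neighbours (Euclidean), so
boundary points get more synthetic mass; each synthetic point interpolates
the point with one of its `k` nearest minority neighbours at a uniform
random fraction.  Integer allocation uses the largest-remainder rule so
the shares sum to exactly `G` (independent rounding can miss `G` by up to
half the minority size and leave the classes visibly unbalanced).  ADASYN
is applied only inside training partitions — per resampled model in the
consensus engine, per split in the evaluation protocols — never to data a
model is evaluated on.

## The selectors

* **LASSO** — L1-penalised logistic regression on internally standardised
  features over a 20–30 point descending lambda path (`lambda_max` zeroes
  all coefficients; floor at 1% of it), lambda chosen by 5-fold CV
  binomial deviance at the minimum (`min`, the permissive default,
  matching the intent of a broad pre-selection pool) or by the
  one-standard-error rule.  liblinear fits carry an explicit random state;
  without one, liblinear consumes the global RNG and reruns stop being
  bit-identical.
* **Boruta** — all-relevant selection.  Every iteration fits a random
  forest on all features plus one shuffled shadow per feature; an
  undecided feature scores a hit when its importance exceeds the maximum
  shadow importance; cumulative hits are tested against Binomial(n, 1/2),
  two-sided at alpha = 0.01 with Bonferroni over the p features; the upper
  tail confirms, the lower rejects; undecided features at `max_runs` are
  rejected (conservative) unless the median-importance resolution is
  requested.  Two design points matter and were found empirically: the
  shadow pool must *not* shrink with the undecided set (a weakening bar
  lets winner's-curse noise survivors accumulate hits late in the run),
  and the Bonferroni level must stay constant rather than track the
  shrinking undecided count (same failure mode).  Residual false confirms
  on small-n null data are features genuinely correlated with the labels
  in-sample (max chance |r| over 20 features at n = 100 is ~0.3) and are
  not removable by any shadow comparison.
* **varSelRF-style backward elimination** — rank features once by the
  initial forest's importance (re-ranking during elimination overfits the
  path), repeatedly drop the least-important 20%, record out-of-bag error,
  and return the smallest set within `c = 1` standard error
  (`sqrt(err(1-err)/n)`) of the minimum.  `c = 0` degenerates to the
  smallest error-minimising set.

Standalone defaults follow the cited algorithms' conventions (permutation
importance, 2000/500-tree forests, Boruta `max_runs = 100`, elimination
`c = 1`).  Inside the consensus loop the per-model settings differ in two
ways, both exposed on `ConsensusParams`: they are scaled for single-CPU
tractability of the fold x model grid (Gini importance, 70–300-tree
forests, `max_runs = 25`), and backward elimination runs at `c = 0`.  The
latter is a statistical choice, not a shortcut: the 1-SE rule's per-model
parsimony deliberately discards redundant *relevant* genes (measured on a
14-signal-gene pool it returns 6–12 genes per model, capping every
redundant gene's model frequency below the 80% consensus bar), which
directly opposes the all-relevant consensus objective; inside the engine,
false-positive control is the job of the cross-selector and cross-fold
thresholds, so each model contributes its error-minimising set instead.

## The consensus engine

The training cohort is split into `n_folds = 10` stratified folds.  Within
each fold's *training portion* (the other nine folds):

1. `n_models = 100` resampled LASSO models run on all genes.  Each model
   draws a stratified 90% subsample without replacement, balances it with
   ADASYN, and fits the LASSO path.  The fold's *pool* is the genes
   selected in at least `model_freq = 80%` of these models.  Subsampling
   rather than bootstrap is deliberate: bootstrap-duplicated rows let any
   noise feature memorise labels (its shuffled shadow loses the
   alignment), which was measured to make Boruta confirm ~90% of null
   features, and they bias OOB error; the duplicate-free scheme has
   neither artifact.
2. `n_models` Boruta and `n_models` backward-elimination models run on the
   pool, **paired on the same resamples** per model index so selector
   agreement is not confounded by resampling noise.  A gene is
   fold-selected by a selector when it appears in ≥ 80% of that selector's
   models in the fold.

The **robust set** is the genes fold-selected in at least `min_folds = 5`
of 10 folds by *both* tree-based selectors ("at least" everywhere — all
thresholds inclusive).  Every (fold, model, selector, gene) record lands
in a ledger, and the robust set is recomputed from raw records on
aggregation, which doubles as an internal consistency oracle.  Seeds
derive from a BLAKE2s hash of (base seed, fold, model, stage), giving
stable, collision-free, platform-independent streams.

At benchmark scale (5 folds x 25 models) the fold-agreement threshold is
scaled to `min_folds = 3`, preserving the half-the-folds strictness of the
full-scale 5-of-10 rule.

## Modelling and evaluation

Random forests use ranger-style hyperparameters: `n_trees`, `mtry`
(features per split), `split_rule` (`gini` = CART forests, `extratrees` =
random-split trees with bootstrap), `min_node_size` (mapped to minimum
leaf size).  The documented default profile — 500 trees, mtry 3,
extratrees, node size 1 — is the tuned optimum reported in the motivating
study.  `tune_rf` grid-searches 10 combinations by stratified 5-fold CV
accuracy with ADASYN on training folds; ties break to smallest mtry, then
gini, then smallest node size.

Twelve metrics: per-class precision/recall/F1 (PC0, RC0, F10, PC1, RC1,
F11), their unweighted macro averages (MPC, MRC, MF1 — macro-F1 is the
mean of class F1s, *not* the F1 of macro precision/recall), ROC-AUC (the
Mann–Whitney statistic of the class-0 score, ties at 1/2), PR-AUC (average
precision, class 0 positive, no interpolation) and MCC.  Degenerate
conventions: a precision with no predicted positives is 0 (flagged in the
report); an MCC with a zero denominator factor is 0 — so an all-majority
guess scores MCC 0 regardless of its accuracy.

Protocols: repeated stratified 90/10 splits within a cohort (`n_rep =
100`; per split: ADASYN on the 90%, train, evaluate on the 10%); a single
cross-dataset run (train cohort → validation cohort); recalibration
(repeated splits of the held-out cohort, testing the signature rather than
the model); and a random-gene baseline (the cross-dataset protocol on 100
random same-size gene draws).  Across repetitions the 95% CI is `mean ±
1.96 × sd` of the repetition values — a population interval, not a
standard-error interval; it is wide by construction and documented here
because both conventions exist.

## Synthetic data: the stated world

The generator emulates pooled multi-cohort bulk RNA-seq: negative-binomial
counts (variance μ + φμ²) with a log-normal baseline (log2 mean 5, sd 2);
gene-specific per-batch log2 shifts (sd 0.5 by default, 1.0 in the batch
benchmarks); log-uniform library-size factors in [0.5, 2]; 65% class-0
prevalence per batch; and a small planted signature up-regulated in class
0 by a modest log2 fold change (1.0 by default).  Dispersion is φ = 0.16,
i.e. a biological coefficient of variation of 0.4 — the canonical value
for human bulk cohorts — constant across genes.  Batches can be assigned
the validation role to emulate an independent cohort, and a planted truth
can be re-used to simulate a second cohort carrying the same signature.

What the generator does *not* model: paired samples, age/sex covariates,
tumour-cellularity heterogeneity, gene–gene correlation beyond the shared
class/batch structure, or heterogeneous per-gene effect sizes.  A green
recovery test therefore establishes that the machinery finds clean planted
signal under realistic noise, imbalance and batch structure — not that it
would find real biology in real cohorts.

## Numerical choices and degenerate inputs

* Thresholds on model fractions compare counts with `ceil(freq · n −
  1e-9)` so "at least 80%" is inclusive at the boundary.
* Empty LASSO pool: the fold contributes no stage-2 records (warning).
* Empty robust set: evaluation protocols are skipped with a warning.
* Zero-variance genes get batch R² = 0; constant features are dropped
  before LASSO with a warning; single-batch inputs make batch correction
  the identity.
* Repeated-split test draws are redrawn (≤ 10 times) if a class is absent.
* `mtry` is clamped to the number of available features inside the
  protocols (relevant when a robust set is smaller than the default 3).

## Known limitations

* Joint-fit batch correction leaks validation structure into training by
  design; the audit flags it and strict mode avoids it at the cost of a
  cruder validation alignment.
* The consensus engine's inner-loop selector settings trade statistical
  polish for runtime; at publication scale (10 folds × 100 models) a user
  should restore the standalone defaults and expect hours, not minutes.
* Boruta's residual small-n false-confirm behaviour is inherent to shadow
  testing (see above); the consensus thresholds, not the single run, are
  the package's false-positive control.
* Only a single batch factor is supported; no multi-factor ASCA designs.
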