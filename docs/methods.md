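# Methods

## The problem and the model

`hfselect` implements a five-step hybrid feature-selection procedure
for binary clinical outcomes on tabular cohorts, developed around the
prediction of per-cycle IVF/ICSI treatment success. The classifier
throughout is a random forest (bagged decision trees, majority vote
for labels, mean leaf probability for scores); feature selection, not
model choice, is the object of study.

The five steps: (1) a stratified 80/20 train/test split; (2) four
filter/embedded pre-selectors reduce the feature set on the training
partition; (3) a hesitant-fuzzy-set (HFS) scoring system picks the
best pre-selector; (4) wrapper searches (SFS, SBS, SFFS, SFBS, random
search) refine the winner's pool to a target of k features using
cross-validated accuracy; (5) the final subsets are refit on the full
training partition and profiled on the held-out test rows.

## Hesitant-fuzzy method scoring

Each pre-selection method *x* is summarized by the multiset
`h(x) = {ACC, AUC, F-score, (MCC+1)/2, PPV, recall}` of its six test
criteria. MCC (Matthews correlation) lives on [−1, 1] and is mapped
affinely to [0, 1] so all six values share a scale. The deviation
degree

σ̄′(h) = (1/l) √( Σ_{i,j} (γᵢ − γⱼ)² )   over all *ordered* pairs,

is algebraically √2 times the population standard deviation of the
values; the score function SF(h) = 1/σ̄′(h) ranks methods by the
*consistency* of their criteria. This ordered-pair reading is adopted
because it is the one under which the scoring system's published
reference scores are reproduced within 0.35% from their published
six-criterion inputs; alternative readings (mean absolute pairwise
difference, per-pair radicals) miss by large margins. An all-equal
element has σ̄′ = 0 and scores +∞ (with a warning) rather than
erroring: a perfectly consistent profile is a legitimate, if
degenerate, best case. Ties in the ranking break lexicographically by
method id.

By default the scoring consumes full-precision criterion values; a
`table_fidelity_rounding` switch rounds them to display precision
first, for comparability with workflows that scored rounded report
tables.

## Evaluation metrics

All scalar metrics derive from confusion counts. Zero-denominator
conventions keep profiles total on degenerate splits: PPV, recall and
F-score are 0 (with a warning) when undefined; MCC is 0 when any
radicand factor vanishes. Two aggregation modes are provided for
PPV/recall/F: `positive_class` (the plain formulas) and
`support_weighted` (per-class values weighted by class support) — the
default is support-weighted, under which weighted recall is
identically equal to accuracy; this is the mode consistent with
evaluation tables in which ACC and recall agree while the F-score
falls below both. ROC AUC is trapezoidal (equivalently the
Mann-Whitney probability with ties counted ½), computed from
predicted class-1 probabilities by default; an `auc_mode="label"`
option computes the single-threshold ROC from hard predictions, since
some published workflows evidently did so.

## Wrapper search

Candidate subsets are scored by stratified k-fold cross-validated
accuracy (folds shuffled once by `cv_seed`; the forest seeded by
`model_seed`). Default folds: 10. All ties break toward the lowest
feature index, making every search deterministic.

SFS adds the best candidate per step until k features; SBS removes
the least harmful candidate from the full pool down to k. The
floating variants additionally reverse earlier decisions whenever the
reversal *strictly* improves the best score recorded at the resulting
subset size; strict improvement against the best-at-size table bounds
the number of reversals and guarantees termination. The floating
sweeps continue through the whole pool (sizes float up and down along
the way) and return the best subset of size k encountered anywhere —
this is what allows SFFS to recover feature pairs that are
informative only jointly, which a greedy pass stopped at k can miss.
Random search samples subsets of uniformly random size and keeps the
best; it reports its best subset at whatever size that subset has.

Per-step cross-validation statistics follow the conventions of the
classic sequential-selector trace tables: `std_dev` is the population
SD of the m fold scores, `std_err = std_dev/√(m−1)` (the sample-SD
standard error of the mean), and `ci_bound = std_err · t₀.₉₇₅` with
m degrees of freedom. These exact conventions — including the
unusual df = m — are fixed by matching the arithmetic of the
reference trace (std_dev 0.0702348 → std_err 0.0405501, ci_bound
0.112585 at m = 4).

The default `target_k = 7` reflects the clinical setting (a
practitioner-sized predictor panel from 38 candidates). The wrapper
stage needs a candidate pool of at least k features, so step 4 hands
its pool to the highest-HFS-scoring method whose pool is large
enough; the reported HFS ranking itself is never altered. If no pool
qualifies, k shrinks to the largest pool.

## Pre-selectors

* **VT** keeps features with training population variance above a
  threshold (default 0.35), applied to *raw* (imputed,
  unstandardized) columns — on standardized columns every variance is
  1 and the threshold would be vacuous.
* **k-best** keeps the k features (default 19) with the largest
  two-group ANOVA F against the outcome; undefined F (constant
  feature) ranks last with a warning.
* **L1** keeps features with nonzero coefficients of an L1-penalized
  logistic-loss linear classifier (inverse regularization C = 1.0) on
  standardized inputs.
* **Tree** keeps features whose forest impurity importance exceeds
  the mean importance (median and quantile rules available).

A failure of one selector (e.g. an empty survivor set) becomes an
error row; the stage never aborts.

## Synthetic cohorts

The generator emulates the summary shape of the study cohort the
method was developed on (which is not publicly deposited): n = 1000
cycles, p = 38 predictors, positive prevalence 0.317, and 7
informative predictors — FSH (day-3 dose, Gaussian, mean 10.5 mIU/ml),
FAge (female age, Gaussian, mean 30.9 yr), and Poisson counts for
oocytes (rate 9), 16Cells (4), compact (3), GIII (1.5) and previous
unsuccessful cycles (0.9). The outcome is drawn first
(Bernoulli(0.317)) and features conditional on class, so planted
standardized mean differences are exact by construction. All seven
default effects are adverse (success cycles have lower values), with
magnitudes 0.4–0.8: FSH −0.8, FAge −0.7, oocytes −0.5, 16Cells −0.5,
compact −0.4, GIII −0.4, unsuccessful −0.6 — directions chosen to
match the reported clinical associations (success falls with rising
female age, FSH dose and prior failures), magnitudes chosen once as
moderate, detectable-but-not-trivial clinical effect sizes. The
remaining 31 columns are standard normal noise, optionally
exchangeably correlated. Informative columns are placed at indices
1, 3, 6, 8, 11, 14, 17 (the positions the clinical variables occupy
in the source cohort's column ordering) when p permits.

What the generator does **not** emulate: the real cohort's
inter-feature correlation structure, center effects, repeated cycles
per couple, missing-data mechanisms, or the many weakly informative
clinical variables a real record carries. Consequently, passing
recovery tests show the pipeline finds planted independent signal at
realistic effect sizes and prevalence; they do not certify
performance on correlated clinical predictors.

## Numerical and design choices

* Stratified splitting and stratified CV folds throughout: at ~32%
  prevalence, unstratified 20% splits are unstable.
* Median imputation and standardization are fitted on the training
  partition only; test rows never contribute statistics.
* Standardization uses population (ddof = 0) SD; zero-SD columns map
  to 0. Variance for VT likewise uses the population form.
* The evaluation forest has 100 trees by default and a fixed seed;
  no hyperparameter search is performed anywhere.
* Categorical predictors are expected pre-encoded as integers; no
  one-hot expansion.
* Heavier statistical experiments in the test suite (20-seed planted
  recovery, 20-permutation null control) run the pipeline with the
  SFS arm, 3 CV folds, 15-tree CV forests and a 50-tree evaluation
  forest; these sizes are the package's chosen experiment scale and
  are exercised end-to-end on the full default cohort (n = 1000,
  p = 38).

## Known limitations

* The wrapper stage's greedy searches have no optimality guarantee;
  their exhaustive-enumeration equivalence is verified only at small
  p in the test suite.
* Runtime columns in reports are wall-clock and non-deterministic;
  report files are byte-reproducible only with runtimes excluded.
* A label-permuted cohort yields a held-out MCC whose null
  distribution has SD ≈ 1/√n_test (≈ 0.071 at n_test = 200), so
  individual permutations occasionally land outside a ±0.1 band; the
  null-control test asserts the 90%-coverage behaviour of the band,
  which is itself a statistically tight criterion at 20 permutations.
* The HFS score ranks methods by criterion consistency, not by any
  accuracy-weighted combination; a uniformly mediocre method can in
  principle outscore a better but less consistent one. This is a
  property of the scoring system, faithfully implemented.
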