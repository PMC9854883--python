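# Methods

## Setting and assumptions

`fusemble` operates on the *prediction set* abstraction: m base classifiers,
one shared test set of N items, C mutually exclusive classes, ground truth
known for every item.  Each classifier contributes an N×C row-stochastic
probability matrix; hard-label-only classifiers are stored one-hot and
flagged so probability-dependent operations (soft voting, stacking, ROC)
refuse them explicitly rather than treating a vote as a calibrated
probability.  Nothing upstream of this container — image handling, network
training, feature extraction — is in scope.

Probability rows whose sum deviates from 1 by at most 1e-3 are renormalized
(tolerating float round-trips through text); larger deviations are rejected
with the offending row named, because silently renormalizing a corrupt file
masks real errors.  Items are aligned across input files by explicit item
id, never by file order.

## Fusion methods

**Soft voting / weighted average voting.**  Fused score vector
`Σ_j w_j p_ij`, label = argmax.  The two methods are one operation with
different weight vectors; weights are stored normalized to sum 1 since argmax
decisions are invariant to positive scaling.

**Weighted hard voting.**  Per item, each class scores the summed weight of
members voting for it.  Exact ties are possible (that is the method's known
weakness with even member counts and uniform weights); the resolution rule is
deterministic and auditable: the tie goes to the class supported by the
highest-ranked tied-supporting member (member order is the ranking order in
sweeps), falling back to the lowest class index; every tie event is counted
and its item index logged in the result.

**Weight optimization.**  Sequential model-based search over [0,1]^m: a
Gaussian-process surrogate (Matérn 5/2, expected-improvement acquisition over
a 256-point random candidate pool) maximizes the overall accuracy of the
corresponding fusion on an objective item set.  The uniform vector is always
evaluated first, which gives a hard guarantee: the returned weights never
score below uniform on the objective set.  Roughly the first quarter of the
evaluation budget (at least 2m points) is random exploration.  Default budget
is 200 evaluations; everything is deterministic under the seed.  All-zero
weight proposals are re-sampled as degenerate.

The objective set matters.  By default `FusionModel.fit` optimizes weights on
a stratified half split of the provided items, keeping the reported accuracy
honest about optimization leakage.  `paper_mode=True` optimizes on the full
evaluation set itself — the protocol under which published weighted-voting
results are typically produced when no second labeled set exists — and is
provided so that such results can be mirrored deliberately, never silently.

**Stacking.**  Meta-features are the concatenated member probability vectors
(m·C columns).  A stratified k-fold scheme (default k = 5) trains the
meta-learner on k−1 folds and predicts the held-out fold, so every fused
probability is out-of-fold.  The default meta-learner is LightGBM
(multiclass log-loss, up to 1000 boosting rounds, early-stopping patience 50
on an inner stratified 80/20 split of each training fold) with a seeded
random hyperparameter search (default 50 trials over leaf count, learning
rate, minimum child samples, feature fraction, L2) confined to the training
split.  A multinomial-logistic meta-learner is provided as a fast,
fully deterministic alternative; it is what the test suite and the
acceptance sweep use, since the stacking contract being verified is the
out-of-fold scheme, not LightGBM's capacity.  If any class is rarer than the
fold count the stack refuses with a suggestion to lower k, rather than
producing folds that miss a class.

## Pruning

Members are ranked by standalone overall accuracy (ties broken by macro F1,
then identifier, and logged).  The sweep fuses the top-k prefix for every
method and every k in 2..m, re-optimizing weights and re-fitting the stack at
each k — per-k ensembles are independent fits, not warm starts, because the
quantity of interest is "the best ensemble of size k", not a continuation
path.  The single top-ranked classifier is carried as the k = 1 baseline.
Reported best-k accuracies are reproducible by re-running that single fusion
standalone with the same seed.

## Evaluation conventions

One-vs-rest counts per class come from the C×C confusion matrix: tp is the
diagonal cell, fn the rest of the row, fp the rest of the column, tn the
remainder.  Per-class metrics: precision tp/(tp+fp), sensitivity tp/(tp+fn),
specificity tn/(tn+fp), F1 the harmonic mean, one-vs-rest accuracy
(tp+tn)/N.  Macro values are unweighted means over classes.

Two conventions deserve explicit flags:

- **"Accuracy" means overall accuracy Σtp/N** (the trace of the confusion
  matrix over N).  Summary tables in this literature sometimes label that
  number "macro-averaged accuracy", but the mean of per-class one-vs-rest
  accuracies is a different (larger) quantity; both are exposed
  (`overall_accuracy` and `macro.class_accuracy`), and `accuracy` always
  refers to the former.  On balanced truth supports, macro sensitivity
  equals overall accuracy — a useful cross-check the tests exercise.
- **Specificity is tn/(tn+fp).**  A formula occasionally printed as
  tp/(fp+tn) in this literature is inconsistent with the tabulated values it
  accompanies (e.g. 691/750 = 0.921); the package computes the standard
  definition, which reproduces those values.

Undefined ratios (0/0, e.g. precision of a class never predicted) are
carried as NaN — an explicit undefined marker, never silently zero — and
propagate into macro averages unless the `omit` policy is chosen.  Pruning
sweeps can create such degenerate members, so the distinction is live.

**Confidence intervals.**  Wilson score intervals are the default for a
single proportion (the standard single-proportion reading of the Newcombe
method); Wald intervals p ± z√(p(1−p)/n) are offered because macro-level
intervals in the reference tables this package reproduces are averages of
per-class Wald bounds.  Macro CIs are the arithmetic means of unrounded
per-class bounds.  Both intervals are clipped to [0,1], and boundary counts
(0 or n successes) pin the corresponding bound exactly.

**ROC/AUC.**  One-vs-rest, using the class's probability column as the score
without renormalization; the implementation (scikit-learn's trapezoidal
construction) equals the Mann–Whitney pair statistic with ties counted one
half, and the tests verify that equivalence against a brute-force
pair-counting oracle.  Single-class truth yields the undefined marker.

**McNemar.**  χ² = (n01−n10)²/(n01+n10) on 1 df, uncorrected by default to
match the plain form of the statistic; the continuity-corrected variant
(|n01−n10|−1)² is available but off.  Zero discordance is flagged degenerate
with χ² = 0, p = 1.  Significance defaults to two-sided α = 0.05.

**Diversity.**  Pearson correlation of predicted-label vectors under the
registry's 0-based integer encoding, with pairs ≥ 0.95 flagged as redundant
for ensembling.  This diagnostic is encoding-sensitive — permuting class
indices changes it — which is why Cramér's V is offered alongside as a
sounder association measure; the Pearson form is kept because it is what
practitioners in this area report.

## The synthetic generator

The generator emulates a bank of classifiers evaluated on one balanced test
set.  Per item, a shared evidence vector S_i ~ N(0, I_C) represents what
every classifier sees; classifier j's logits are
√ρ·S_i + √(1−ρ)·E_ij + b_j·1[class = truth] with idiosyncratic noise
E_ij ~ N(0, I_C).  Square-root mixing keeps each logit's variance at 1, so
the bias b_j maps to accuracy independently of ρ: accuracy and
inter-classifier correlation are separate dials.  Probabilities are a
softmax at the configured temperature (labels are temperature-invariant).

Defaults are the study conditions the packaged fixtures describe: N = 1000
items, C = 4 balanced classes, m = 16 classifiers with target accuracies
spanning 0.617–0.719 (the published per-classifier spread), and ρ = 0.45,
chosen so the off-diagonal predicted-label correlations fall in the
0.33–0.75 band observed for independently fine-tuned CNNs on one dataset
(measured mean ≈ 0.48 at the default seed).

b_j is calibrated by bisection on the realized margins of the generation
draw itself: an item is correct iff b_j exceeds its margin (best wrong-class
logit minus true-class logit), so realized accuracy is a monotone step
function of b_j and bisection lands within ±0.005 of the target.
Calibrating against a held draw instead would leave √(p(1−p)/N) ≈ 0.015
binomial wobble on the realized accuracy — with 16 classifiers, some member
would miss a ±0.02 target at most seeds — so the package trades a small
conditioning of the noise (the bias is data-dependent through one order
statistic) for exact, seed-reproducible skill targets.

What the generator does *not* emulate: class-conditional error structure
(real CNNs confuse specific class pairs, e.g. the two cancer classes, far
more than others), per-architecture idiosyncrasies, calibration error in the
probability outputs, and item-difficulty heavy tails.  Because its errors
are closer to exchangeable than real CNN errors, fusion gains on synthetic
banks are systematically larger than on real ones (uniform soft voting of
the default bank reaches ≈ 0.84 where a comparable real bank reached
≈ 0.78).  Passing tests on synthetic data therefore demonstrate the
machinery and its invariances, not effect sizes on real data; effect-size
fidelity rests on the packaged count-table fixtures, which the metric suite
reproduces cell for cell.

## Packaged fixtures

Two count tables ship with the package (`counts16`, `counts_ensembles`):
per-classifier, per-class one-vs-rest TP/FP/FN/TN for a published bank of 16
CNNs and for the four best pruned ensembles (SV16, ST9, WAV7, WHV13) on a
1000-image, 4-class balanced liver-ultrasound test set.  Every row satisfies
tp+fp+fn+tn = 1000 and tp+fn = 250, and the tests assert those identities.
One reproduction caveat: the exact count-derived macro precision of the
top classifier is 0.7318, which rounds to 0.732 while the published summary
prints 0.731 — one rounding step apart; the acceptance test pins the exact
value and checks the published one at ±0.001.

## Problem sizes and runtime choices

The default test run fuses banks of up to 16 members × 1000 items; the
end-to-end sweep test (4 methods × k = 2..16, budget-50 weight optimization,
logistic stacking) completes in well under a minute, and the full suite in a
few minutes, on one CPU.  Property suites use 20–200 seeded replicates at
small N (e.g. AUC oracle checks at N ≤ 12, McNemar formula checks over all
discordant tables with n01+n10 ≤ 50).  These sizes were chosen as the
smallest that exercise every code path at full default dimensionality.

## Known limitations

- Weight optimization treats accuracy, a step function of w, with a smooth
  GP surrogate; for large m the budget needed to beat uniform meaningfully
  grows, and the guarantee degrades gracefully to "no worse than uniform".
- The stacking hyperparameter search is random, not adaptive; with the
  default 50 trials × 5 folds the LightGBM path is the slowest operation in
  the package.
- Pearson label-correlation diversity depends on class encoding (documented
  above); cross-study comparisons of its absolute values are fragile.
- McNemar p-values are reported per pair without multiple-testing
  correction; sweeping many ensemble sizes and testing each against a
  baseline inflates family-wise error, and callers comparing many pairs
  should correct accordingly.
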