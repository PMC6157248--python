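# Methods

## Selection model

Single-view MRMR is the standard greedy approximation to the
minimum-redundancy maximum-relevance subset problem: seed with the
feature of maximal relevance f(x, y), then repeatedly add

    argmax_{j in candidates}  f(x_j, y) - (1/|S|^e) * sum_{l in S} g(x_j, x_l)

with g = |Pearson correlation|. The package's default redundancy divisor
exponent is e = 2. Note the consequence: the penalty term is at most
|S|·1/|S|^e = |S|^(1-e), so with e = 2 redundancy fades as selection
grows and the criterion progressively reduces to pure relevance ranking.
The classical e = 1 (mean redundancy, which does not fade) is available
as `exponent=1` everywhere. Both are exercised by the tests and the
brute-force oracles.

The multi-view variant allocates selection steps to views by sampling a
schedule of k-1 view indices i.i.d. from a categorical importance
distribution P before any selection happens. Step 1 takes the globally
most relevant feature across all views and deliberately ignores P — even
P = (1, 0) can open with a view-2 feature. Every later step restricts
candidates to the scheduled view but penalizes redundancy against the
union of selections from all views (divisor |S_all|^e). That cross-view
penalty is the substance of the method: it admits complementary features
from different views and rejects cross-view duplicates, e.g. a
copy-number column and an expression column tracking the same amplified
locus.

Two degrees of freedom are not fixed by the greedy recipe and are
resolved as follows:

* **Ties** at any argmax break toward the lowest view index, then the
  lowest feature index, making every trace deterministic given the
  schedule.
* **Exhausted scheduled views** (possible when k approaches the total
  feature count and P is skewed): the step's view is redrawn from P
  restricted and renormalized to views with remaining candidates (uniform
  over them if P gives all of them zero mass). This preserves the total
  count k and the spirit of P; the realized schedule is available via
  `return_schedule=True`.

There is no stopping rule other than k: selection proceeds even when all
candidate scores are negative.

## Relevance and redundancy scales

Relevance functions: chi-squared statistic, one-way ANOVA F, and a
plug-in mutual information computed after equal-width discretization into
10 bins (a deterministic estimator was chosen over nearest-neighbour
estimators so that selection traces are exactly reproducible; the bin
count suits [0,1]-rescaled features). CFM is the equal-weight average of
the three after min-max normalization over the current candidate pool —
raw averaging would let F statistics (unbounded, often in the hundreds)
drown mutual information (at most ln 2 nats for binary labels). Because
of the pool normalization, CFM is only defined relative to a pool of at
least two features; in the multi-view setting the pool is the union of
all views, so scores stay commensurable across views.

The relevance scale interacts with the bounded redundancy penalty in a
way users should know: with raw F or chi-squared relevance the penalty
(at most 1 per selected feature, divided by |S|^e) only separates
near-ties, so duplicates of a strongly relevant feature can still be
selected; with MI or CFM, relevance and redundancy live on comparable
scales and redundancy genuinely bites. The examples and the redundancy
tests use MI/CFM for exactly this reason.

Conventions at degenerate inputs: |Pearson| of a zero-variance vector is
0 (no signal, no redundancy — not NaN); constant features score 0 under
every relevance function; chi-squared validates non-negativity of its
input rather than silently shifting it (upstream [0,1] rescaling
guarantees this in the standard pipeline).

## Preprocessing

The standard chain for omics tables is: drop every feature with at least
one missing value; min-max rescale to [0,1]; remove features with
population variance (divide by m) strictly below 0.02, keeping the
boundary value. Rescaling defaults to per-feature — the reading required
for chi-squared non-negativity per feature and the standard one — with a
per-sample option for data normalized row-wise. Constant slices rescale
to all-zeros so the variance filter removes them cleanly. Alignment of
views keeps the intersection of sample ids in lexicographically sorted
order, for reproducibility. Survival outcomes binarize at a 3-year
cutoff: time >= cutoff is long-term (1); time < cutoff with vital status
0 is short-term (0); short-follow-up cases with any other status are
excluded as unlabelable rather than guessed.

## Two-stage framework

Stage I holds one filter per view behind an enable gate; a disabled
filter passes *no* data downstream, implemented as view deletion (not
zero-filling), so disabling a view is provably equivalent to deleting it
from the dataset. Shipped Stage-I filters: the pass-through AllFilter and
an embedded sparse filter that ranks features by absolute coefficient of
a lasso fit (default regularization strength 1e-4) and truncates to
top_n — ranked truncation rather than the nonzero set, so the budget is
explicit; with every coefficient zeroed the ranking degrades to stable
index order. Other screeners (forest importances, recursive elimination)
satisfy the same contract and are registerable by name.

Stage II is single-view (applied to the concatenation of surviving views,
feature names prefixed with their view name to guarantee uniqueness — a
copy-number and an expression view may share gene symbols) or multi-view
(MRMR-mv on the surviving views jointly). A `mrmr_per_view` Stage-II kind
implements the per-view-selection baseline, splitting the budget k across
views as evenly as possible so all strategies compare at equal total
budget.

`fit` learns every enabled filter's feature set from training data;
`transform` is a pure projection keyed by feature *name* (column order in
test tables is irrelevant; a missing selected feature is an error, never
silently imputed).

## Synthetic data generator

The generator emulates the structural features of a multi-omics cohort
that the selector is supposed to exploit, at a scale where ground truth
is exact:

* relevant features: class-conditional Gaussians, between-class mean
  shift `effect_size` in units of `noise_sd` (defaults 1.0 and 1.0 — a
  clearly detectable but not separable single-feature signal at m ≈ 300);
* within-view and cross-view redundant features: copies of relevant
  features plus fresh Gaussian noise with sd sigma*sqrt(1/rho^2 - 1),
  which hits the target correlation rho exactly in expectation;
* noise features: label-independent Gaussians;
* labels: exact class counts at the requested balance (default 0.5),
  positions shuffled; both classes always present.

Everything is min-max rescaled to [0,1] per feature afterwards (affine,
so planted correlations are untouched) and is a pure function of the
seed. What the generator does **not** emulate: real omics marginals
(copy-number discreteness, methylation beta bimodality), block/LD-like
correlation structure, batch effects, or view-specific sample noise.
Passing tests therefore certify the algorithmic claims — recovery of
planted signal, redundancy suppression, schedule fidelity, strategy
ordering under complementary signal — not clinical performance on real
cohorts.

## Evaluation harness

Repeated stratified k-fold cross-validation (defaults 10 repeats of 5
folds; fold assignment for repeat r is seeded `seed + r`). The entire
pipeline — Stage-I filters, Stage-II selection, classifier — is fitted on
training folds only; the held-out fold is projected through the fitted
pipeline and scored by AUC. All strategies in a comparison see identical
splits (paired comparison). The Ensemble strategy averages the predicted
scores of the best per-view single-view model (best by mean AUC across
the shared folds) and the multi-view model. Shipped learners: a 500-tree
random forest, 500-round gradient boosting, and L1-regularized logistic
regression; any estimator with fit/predict_proba satisfies the contract.

P-sensitivity: for two views, the MV model is evaluated at
P = (p1, 1-p1) for p1 = 0, 0.1, ..., 1 on shared splits, and each k's
spread is summarized as the percent relative range
100*(max - min)/mean of the eleven mean AUCs (the standard definition of
relative range; the quantity is undefined for zero mean, which cannot
occur for AUCs of non-degenerate folds).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as this
package's own study conditions: m = 200–2000 samples, tens to a few
hundred features per view, 1x3- or 1x5-fold CV for stochastic
comparisons, 20 seeds for averaged claims, 100 random fixtures for
oracle-agreement checks, and 1000 runs for the schedule-frequency law.
The L1-logistic learner is used in loops for speed and determinism.
Oracle comparisons demand exact equality of selection orders; scores are
compared at 1e-12 where an independent formula exists (Mann-Whitney AUC,
plug-in MI, hand arithmetic of the criterion).

## Known limitations

* Greedy MRMR has no optimality guarantee; the exhaustive search is
  exponential and exists here only as a test oracle at tiny sizes.
* With e = 2 the redundancy penalty fades as k grows (see above); users
  wanting sustained redundancy control should pass `exponent=1`.
* |Pearson| only captures linear redundancy.
* The first pick ignoring P is a modelling choice inherited from the
  selection procedure's definition; with a strongly informative feature
  in a low-priority view, realized per-view counts deviate from P by one.
* P is taken as given; the package does not optimize it.
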