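# Methods

This note documents the models, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Dose-response featurization

Expression at the three dose levels is coded on a unitless log-like axis
d = 1, 2, 3 (low/middle/high). Real studies dose each compound on its own
mg/kg scale, so a categorical coding is the only dose axis shared across
compounds; it is configurable. Each (compound, gene) triple is fitted with
the logistic

    r(d) = baseline + (R_max − baseline) / (1 + exp(−slope · (d − ec50)))

**The steepness is a fixed shape constant** (default `slope = 4`,
configurable), and (baseline, R_max, ec50) are fitted — three unknowns
against three points, exactly identifiable. We deliberately do not fit the
steepness: with three points and a pinned or free lower asymptote the
four-quantity problem is degenerate — families of near-exact fits exist in
which the slope runs to a step function and R_max becomes arbitrary (we
observed exact-residual fits with R_max off by far more than 1%). Fixing
the shape removes the degeneracy and makes R_max recovery exact on clean
curves. `slope = 4` places most of the transition within one inter-dose
step, the typical appearance of a three-dose response.

Fitting is batched: for each candidate ec50 on a fine grid (1201 points
over [0, 4]) the baseline and amplitude enter linearly and are solved in
closed form; a parabolic refinement of the grid minimum localises ec50 to
about 1e−5. All compound × gene triples are fitted in one vectorised pass
(seconds for tens of thousands of fits).

A triple is **invalid** — "cannot form a curve" — when (a) its range is
below `flat_tolerance` (default 0.3; no dose signal), (b) the best-fit
residual sum of squares exceeds `rss_tolerance` (default 0.05; e.g.
non-monotone triples unreachable by a monotone logistic), or (c) the
fitted R_max falls below the baseline. Case (c) means down-regulated
responses are filtered rather than modelled; handling them would need a
sign convention for "maximal response" that the upward-response definition
does not provide. A gene is retained when its fit is valid for at least
`min_valid_fraction` of compounds (default: all). Control (vehicle)
samples are not part of the fit input; the alternative — responses
relative to vehicle — would shift the baseline but not the amplitude
structure.

## Improved MLSMOTE

Imbalance is measured by IRLbl(l) = max_l' count(l') / count(l) and
MeanIR (mean over labels with at least one positive; empty labels are
flagged infinite and excluded). A label is minority when IRLbl > MeanIR.

One pass visits each minority label's positive bag; every bag member
seeds one synthetic sample: features are interpolated uniformly toward
one of its k = 5 nearest bag neighbours (Euclidean; k-NN ties broken by
row index for determinism), labels are assigned by strict majority over
the seed plus its k nearest bag members. Passes repeat until
MeanIR ≤ `target_mean_ir` (default 1.5) or `max_rounds` (default 5) is
exhausted. Because synthetic votes can drag in commonly co-occurring
labels, a pass can worsen balance; such a pass is rolled back and
iteration stops, which guarantees MeanIR never increases.

The **zero-label guard** forces the triggering minority label on when the
vote yields an all-zero vector (a no-finding synthetic sample would
dilute the minority class it was meant to strengthen); a reject-and-redraw
variant is available (`guard="redraw"`). Under within-bag voting the
all-zero outcome cannot actually arise — every voter carries the bag's
label — so the guard is a safety net for alternative voter schemes; it is
unit-tested directly on engineered votes.

Originals are always preserved verbatim; synthetic rows carry a
provenance record (seed row, neighbour row, interpolation coefficient)
that the leak-free pipeline audits.

## Att-RethinkNet

The classifier treats multi-label prediction as a T-step sequence task
over a single input: the (attention-weighted) feature vector is replicated
across T recurrent steps; each step's hidden state decodes through a
shared dense sigmoid layer into tentative label scores, and the recurrent
state carries tentative predictions into the next step. All weights are
shared across steps, so the parameter count is independent of T. Default
T = 5 (a kidney-scale T = 3 is a config change); performance typically
converges within a few iterations.

**Attention.** A dense map over the feature axis followed by softmax gives
per-sample, per-gene probabilities a (summing to 1); the block multiplies
the input by the mean-one rescaled weights dim·a so that uniform attention
is exactly the identity and the input scale is preserved. A step-axis
variant (softmax over the T replicated steps, dense map T × T — the
literal permute reading of the block; its parameters do depend on T) is
provided for comparison. Per-sample multiplicative gating is a potent
memorisation channel: unregularised, the model reached perfect training
accuracy with near-chance held-out accuracy on a linearly separable
benchmark. An L2 penalty on the attention map (`attention_l2`, default
1.0, applied inside the gradient so it shapes the optimum) keeps the
learned weighting near uniform unless the data genuinely support feature
importance.

**Cells.** LSTM (default; forget-gate bias initialised to 1) or a simple
recurrent (tanh) cell as the ablation.

**Loss.** Mean over samples, steps and labels of w_l · BCE(score, y_l),
with w_l inverse prevalence normalised to mean 1 (uniform or explicit
vectors available; zero-count labels clamped at `weight_cap`). Weighting
every step's output trains the whole rethinking trajectory, not only the
final step.

**Training.** Everything is numpy with hand-derived backpropagation
(feature- and step-axis attention, LSTM and SRN cells), verified against
central-difference numerical gradients in the test suite. Optimisation is
AdamW: learning rate 5e−3, decoupled weight decay 0.05 on weights (not
biases), step decay ×0.1 at 60% and 85% of 200 epochs, batch 32, hidden
32. These defaults were set by reference runs on the separable benchmark,
where the default configuration reaches held-out subset accuracy ≥ 0.95
across seeds. A fixed seed drives initialisation and minibatch order, so
single-threaded runs reproduce exactly (epoch-1 loss bit-identical).

## Baselines and feature selection

BR trains one injected base learner per label; CC feeds true preceding
labels as extra features at training time and predicted ones at
prediction time (standard CC), default chain order = dataset label order.
Base learners are scikit-learn estimators (logistic regression, random
forest, linear SVM with a sigmoid over the decision function); a
single-class training label degrades to a constant predictor with a
warning. The per-label 5-NN model majority-votes the k nearest training
samples per label, ties predicting positive.

Gene ranking uses the two-group one-way ANOVA F statistic per label,
aggregated across labels by mean (max available); single-class labels are
excluded with a warning, and zero within-group variance with distinct
means is capped at F_MAX = 1e12 to preserve ordering without infinities.
The subset sweep deletes ranked genes along a descending size grid
(geometric by default), scores each subset by an evaluator the caller
provides — conventionally CV-mean subset accuracy of a baseline — and
maximises Fitness = α·ACC + (1 − α)·(D_total − λ·D_selected)/D_total with
α = 0.6, λ = 10; ties break toward the smaller subset. The second term
goes negative when λ·D_selected > D_total, which is intended: at
study-scale D_total (thousands of genes) the amplification λ makes
hundred-gene differences matter; for pools of only a handful of genes a
smaller λ is appropriate (see `examples/03_feature_selection.py`).

## Metrics

Subset accuracy (exact row match), pair accuracy (per-sample Jaccard of
positive sets; both-empty counts as 1, so a correctly predicted
no-finding sample is not penalised), per-label accuracy, per-label
TP/FP/TN/FN, macro average-label-accuracy / sensitivity / specificity /
F1 (zero-denominator labels excluded from that ratio's mean with a
warning; a count-as-zero mode is available), and ROC/AUC (micro-averaged
over all (sample, label) pairs by default, macro available; trapezoidal
integration via scikit-learn's ROC points). The whole suite is verified
against an independent nested-loop oracle to 1e−12, and AUC against the
Mann-Whitney rank-sum statistic.

## Pipeline

`run_crossval` executes dose-response featurization → MLSMOTE →
normalisation → K-fold (default K = 5) train/evaluate → mean ± sd
aggregation. Two augmentation placements: `paper_faithful` augments the
pooled data before splitting (the printed procedure; synthetic samples
can land in test folds, which flatters the estimate), and `leak_free`
splits originals first, augments only training folds, and tests on
untouched originals — the methodologically safer choice and the one the
provenance audit covers (no synthetic sample may reference a test-fold
original). Normalisation (per-gene z-score; constant genes map to 0) is
fitted on the training portion and applied to the test portion.
`run_holdout` is the external-validation variant: augment and normalise
on the training set only, evaluate on a disjoint test set.

## Synthetic data

The generator emulates the *structure* of a three-dose toxicogenomics
study, not the marginal distributions of any platform. Defaults (chosen
once for minutes-scale single-CPU runs): 200 compounds, 120 genes of
which 10% are informative, L = 20 findings (the 12 + 8 liver/kidney
layout), geometrically skewed prevalences 0.4 → 0.05, two pairwise label
dependencies (P(j|i=1) = p_j + boost·(1 − p_j), boosts 0.3 and 0.25),
baseline expression 6.0, response amplitude 1.5, per-active-label R_max
shift 1.0, Gaussian noise sd 0.1, and generating curves drawn from the
same fixed-slope logistic family the fitter assumes. Informative genes
are assigned to findings round-robin, so with the defaults eight of the
twenty findings carry no marker gene — a deliberate feature of the
fixture (some findings lack transcriptomic correlates) that caps
attainable subset accuracy.

The separable benchmark draws Gaussian features and L random unit
normals, labels by halfspace sign, and pushes points within 0.3 of any
boundary outward so every label is linearly separable with margin;
prevalence ≈ 0.5 per label.

What passing on these fixtures shows: the mechanics are correct —
curve-forming genes are recovered, balancing contracts hold, the
classifier learns separable structure and exploits label correlation, the
metrics are exact. What it does not show: performance on real
toxicogenomics data, where noise is heteroskedastic, responses are not
logistic in a shared coded dose, and label dependencies are richer than
pairwise boosts.

## Known limitations

- Down-regulated dose responses are filtered, not modelled.
- The fixed-steepness logistic cannot represent curves whose transition
  spans the whole dose range and a step-like curve simultaneously; the
  residual tolerance decides.
- Feature-axis attention under the default L2 stays close to uniform;
  data with strongly redundant/noisy features may warrant relaxing
  `attention_l2` with external validation.
- MLSMOTE stops at the first non-improving pass, so heavily correlated
  label sets may stay above `target_mean_ir`.
- `paper_faithful` cross-validation evaluates on folds that contain
  synthetic samples; use `leak_free` for honest generalisation estimates.
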