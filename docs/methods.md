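# Methods

## Overview

`swarmtune` selects a feedforward network's training hyperparameters
(learning rate η, dropout rate p, momentum μ, weight decay γ) and its
per-hidden-layer neuron counts by particle swarm optimization, scoring each
candidate with a short gradient-descent training run. This note records the
model, the defaults and why they are what they are, the places where the
design was genuinely open, and what the synthetic benchmarks do and do not
establish.

## The trainer

The network is a plain MLP: hidden layers compute `f(xW + b)` with tanh
(classification default) or logistic sigmoid (regression default) units;
the output head is softmax with mean negative log-likelihood loss for
classification and a linear unit with mean squared error for regression.
The output width equals the number of classes, or 1 for regression. A
half-sum squared-error cost is also exposed as a loss variant for users who
want the cost on that scale; the trainer itself always optimizes the mean
forms, whose gradients are the familiar `(p − y)/n` and `2(pred − y)/n`.

Mini-batch SGD uses the legacy momentum/decay semantics

    lr_k = η / (1 + γ·k)         k = update counter, starting at 0
    v   ← μ·v − lr_k·grad
    w   ← w + v

chosen because the hyperparameter ranges this package targets (η up to 0.9,
γ of order 10⁻⁴) are calibrated to that rule; other decay conventions would
change what the same numbers mean. Dropout is the inverted variant on
hidden activations only, applied during training and absent at prediction,
so no rescaling is needed at test time. Weights initialize uniform(−s, s)
with s = 1/√fan_in (small, zero-centred — large early gradients for
saturating units); biases start at zero. Samples are reshuffled every
epoch; the final partial mini-batch is used as-is so each epoch visits
every sample. A non-finite batch loss stops training immediately and flags
the returned history as diverged — callers translate that into a −∞
candidate score rather than an exception, because divergence is an
informative outcome of an aggressive configuration, not an error. The
per-epoch loss recorded is the sample-weighted mean of the batch losses
(each measured before its update), which is what falls monotonically on the
well-conditioned fixtures.

Probabilities are clamped at 1e−12 before any log. Gradient correctness is
pinned by central finite differences at 1e−5 relative tolerance in the
suite.

## The swarm

Particles live in the box defined by the `SearchSpace`: four continuous
hyperparameter dimensions plus one dimension per hidden layer. The number
of hidden layers is fixed per experiment — only widths are searched — and
all hidden layers share one neuron range. The updates are the canonical

    V' = W·V + C₁R₁(pbest − X) + C₂R₂(gbest − X),   X' = X + V'

with R₁, R₂ drawn independently per dimension. Schedules are linear over
t ∈ [0, t_max]: C₁ 2.5 → 0.5, C₂ 0.5 → 2.5, W 0.9 → 0.4 by default — the
classic TVAC/TVIW settings, which shift the swarm from self-guided
exploration to socially-guided exploitation.

Numerical choices:

- **Velocity** initializes at zero, so generation 0 is a pure uniform
  sample of the box, and is capped per dimension at 0.2 of the box range —
  unbounded velocities destabilize narrow hyperparameter boxes.
- **Positions** are clipped to the box after each move; a clipped
  dimension has its velocity component zeroed so particles do not grind
  against walls.
- **pbest/gbest replacement is strict** (`>`): on ties the earlier
  incumbent is kept, which makes the gbest history non-decreasing and
  runs reproducible.
- **Maximization convention** throughout; regression fitness is the
  negated validation MSE.
- Each generation evaluates, updates the records, computes the schedules
  at t, then moves; a final evaluation happens at t = t_max, so a run
  performs t_max moves and t_max + 1 evaluations.

Some formulations update the position from pbest rather than from the
current position and mix generation indices between the two update
equations; that variant is internally inconsistent with the coefficient
schedules' intent, so this package implements the standard form above.

## Candidate encoding

The particle vector order is fixed: (η, p, μ, γ, n₁, …, n_L). Neuron
dimensions remain continuous inside the swarm and are rounded half-up to
integers only at decode time — rounding inside the dynamics would create
plateaus the velocity updates cannot sense. Decode∘encode is the identity
on valid configurations; encode∘decode is the identity up to that rounding.
The default box is the classification regime: η ∈ [0.01, 0.9], p and μ ∈
[0.1, 0.9], two hidden layers of 90–150 neurons. The decay default is
γ ∈ [1e−5, 1e−4]; a zero-width bound is legal and pins a value exactly.

## Fitness protocol

The training data D is split once per search run into Tr/Te by the fraction
λ (default 0.8, floor(λn) training records, stratified by class). Each
particle decodes to a configuration, trains a **fresh** network (no warm
starts, no caching) for `eval_epochs` (default 5) and is scored on Te:
accuracy, or negated MSE. Scoring on the held-out Te is the default because
it is the only reading under which validation is meaningful; scoring on the
last training loss is available as an option. Re-splitting every generation
would make pbest scores incomparable across generations, so the split is
fixed for the whole search.

Per-candidate seeds are derived by hashing the particle's position bytes
with the master seed, so identical positions always train identically —
batch evaluation equals one-at-a-time evaluation, and results are
order-stable.

## Final models and the ensemble

After the search, each pbest (and gbest, separately) is retrained with
`final_epochs` (default 20) on all training samples and scored for ranking
on the λ-held-out portion of a fresh split of that same pool. The ranking
score is therefore not fully independent of the training data — the
protocol trains finals on everything — but it is measured on samples the
network saw with the lowest weight, and it only orders candidates. The top
h candidates form the ensemble; ties go to the lower candidate index and
no retraining occurs at selection time. Divergent members keep a −∞ score
and can never be selected.

Classification fusion is a majority vote over members' argmax labels. Vote
ties are broken by the larger sum of members' class scores across the
ensemble, then by the lower class index; the tie-break is this package's
own deterministic rule. Regression fusion is the unweighted mean of member
outputs (score-softmax weighting is a non-default option).

A practical note observed throughout the desk-scale experiments: high-η
configurations can score well in a 3-epoch evaluation yet oscillate and
collapse under a longer final budget. The ensemble absorbs this — collapsed
members rank at the bottom and are excluded or outvoted — while the single
gbest model is exposed to it. This mirrors the occasional collapsed
candidate visible in per-candidate result tables of ensemble-of-MLP
studies, and is why the ensemble is the primary deliverable.

## Synthetic data

Two generator regimes, both pure functions of their parameters and seed:

- **Pixel-like classification**: Gaussian clusters with class means at
  distance ≈ `separation` (in within-class standard deviations) along
  random unit directions, features min-max scaled to [0, 1], near-balanced
  labels. `separation ≥ 3` is essentially linearly separable. An IDX
  (MNIST-dialect) reader/writer and a divide-by-255 scaler support real
  pixel data; the reader trusts the file's dimension header.
- **QSAR descriptor regression**: descriptors = latent factors × sparse
  loadings + Gaussian noise, column-scaled into the open interval (0, 1)
  (margin 10⁻³). Every descriptor couples to at least one latent factor;
  otherwise the per-column rescaling would inflate pure-noise columns to
  unit range and destroy the low-rank spectrum. The activity is
  5 + z₀² + z₁z₂ + z₀ plus noise — offset away from zero so MAPE is
  well defined, quadratic-plus-interaction so a linear model cannot fit it
  but a two-hidden-layer network can. Default desk-scale shapes
  (hundreds × tens) keep tests fast; full-scale shapes
  (thousands × thousands) are available by argument.

What the generators do **not** emulate: pixel correlation structure,
descriptor collinearity blocks, heavy-tailed activity distributions, label
noise, and class imbalance. Passing results on these fixtures establish
that the search, trainer and fusion machinery behave as specified — not
that any particular accuracy transfers to MNIST-scale images or real
descriptor sets.

For descriptor matrices, `pca_reduce` projects onto the top-k principal
axes; the default k is the number of components explaining 95% of variance
(`components_for_variance`), overridable, since an appropriate target
dimensionality is data-dependent.

## The comparison harness

`run_comparison` folds whatever dataset it is given (stratified k-fold, the
first n mod k folds taking the extra record, or a single λ holdout) and
runs two arms per fold. The PSO arm searches, retrains its pbest solutions
as candidates, and builds the top-h ensemble plus the gbest individual.
The random arm draws the same number of configurations uniformly from the
same space and pushes them through the identical retraining, ranking,
ensemble and test pipeline — equal candidate count and equal final epochs.
The report also records both arms' candidate scores under the *search*
protocol on the same Tr/Te split, which is the budget-matched comparison of
configuration quality itself. MAPE is mean |actual − predicted|/|actual|
with an optional epsilon floor for near-zero targets. All fold and arm
seeds derive from the master seed; reports embed the seed and a config
hash, and the Avg/Std summary rows are recomputed from the candidate rows
they summarize.

Desk-scale defaults used by the suite's comparison experiments: 600 samples
× 16 features, 3 classes, separation 3; population 8, 10 generations;
3 evaluation epochs, 8 final epochs; h = 4; narrow networks (8–32 neurons
per layer). These sizes exercise every code path of the full-scale protocol
while keeping a 10-seed replication cheap.

## Known limitations

- The trainer is CPU/numpy only: no convolutional or recurrent layers,
  batch normalization, early stopping, or L1/L2 penalties.
- Depth, batch size, epochs and activation are per-experiment constants,
  not searched dimensions.
- The λ-ranking of final models re-uses training data (see above); with
  abundant data a fully held-out ranking split would be cleaner.
- Logistic-sigmoid hidden units learn slowly on low-variance unit-interval
  inputs at desk scale; the regression example uses tanh for that reason
  and says so.
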