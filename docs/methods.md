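# Methods

This note records the models the package implements, the assumptions and
defaults behind them, and the design choices made where the published
description of this prediction stack is ambiguous or internally inconsistent.

## Task and data model

The canonical task is binary classification of the cultivation system
(hydroponic vs. soil) from per-sample phytohormone concentrations and 0/1
growth-condition indicators. All reported metrics are binary-confusion
metrics, which is why the binary label is the tested path; multiclass labels
are accepted by every operation that does not intrinsically require two
classes.

### Synthetic generator

`generate_synthetic_dataset` emulates the structure of a phytohormone panel:

- **Informative compounds** are log-normal. Column j has log-concentration
  `N(base_j ± effect_size·σ/2, σ)` with σ = 0.5 and per-compound baselines
  (2.3, 4.0, 3.2, 2.8, 1.9 on the log ng/g scale, roughly tens of ng/g).
  The shift direction alternates across compounds — hormones respond in
  either direction to soil-free culture — and `effect_size` is the
  standardized class separation on the log scale.
- **Noise columns** come from the same marginal family with no class
  dependence.
- **Condition indicators**: earthworm presence agrees with the label with
  probability 0.7 (configurable); growth medium is an independent fair coin.
- Labels are Bernoulli with `class_balance` = P(hydroponic) = 0.5 by default.

What this does *not* emulate: measurement censoring/detection limits,
correlated hormone co-regulation, batch effects, and non-log-normal tails.
Passing tests on this generator therefore demonstrate that the stack recovers
a known class-conditional mean-shift signal — not that it handles assay
artifacts in real panels.

Default study conditions used by the tests and the acceptance script:
n = 400 samples, 75/25 stratified split, effect size 3 for the separable
condition and 0 for the null condition.

## IEMOA

A population metaheuristic over a bounded box, minimizing by default. Three
phases per iteration, each proposing one candidate per member, clipped to the
box, accepted only on strict improvement:

- education: `u' = u + r1·f(t)·(best − r2·u)`
- guidance: `u' = u + r1·f(t)·(u − r2·peer)`, peer drawn uniformly from the
  strictly worse members (members with none are skipped)
- nurturing: `u'_j = u_j + r·(1 − 2r')·f(t)·(upper_j − lower_j)/m`

with r1, r ~ U(0,1), r2 ~ U(1,2), and the iteration-assisted decay
`f(t) = 1 − t/T` multiplying every step. Printed forms of this algorithm's
update equations are partly uninterpretable (a negative "random variable", an
undefined guide symbol, a bound symbol reused as a multiplier); the
implementation takes the decaying-magnitude reading of the iteration factor,
the best member ("the mother") as the education guide, and a fresh U(0,1)
scalar where the nurturing equation reuses the bound symbol. These choices
match the stated exploration-to-exploitation intent and the source
mother-optimization algorithm's phase semantics.

Numerical conventions: ties keep the incumbent (prevents plateau drift and
makes the best-so-far trace exactly non-increasing); out-of-box proposals are
clipped componentwise; one random stream per run consumed in a fixed order
(phase → member → coordinate; the nurturing r, r′ are per-member scalars), so
equal seeds give bitwise-equal traces. The education guide is the best member
at phase start. Budget: at most `s + 3·s·T` objective evaluations.

Defaults follow the study setup: population 10, 50 iterations, dimension =
number of features when used for weight optimization.

## Feature weighting

The weighted-feature objective is `TL(w) = mean_f[χ²_f/n] + mean_f[Relief_f]`
evaluated on `X·diag(w)`, maximized over `[0.01, 0.99]^d` with IEMOA.

- **Anchoring.** Bin edges (10 equal-width bins over each unweighted training
  column) and Relief normalization ranges are computed once from the
  unweighted training split and reused for every weighted evaluation. With
  quantile re-binning and per-evaluation re-normalization the objective would
  be exactly scale-invariant and optimization meaningless; anchoring is the
  only reading under which the fitness is optimizable.
- **χ² term**: Σ(O−E)²/E over the bins × classes contingency table,
  zero-marginal rows/columns dropped; divided by n to put it on a bounded
  scale commensurate with Relief. Degenerate inputs (single class, one
  non-empty bin) score 0 with a warning.
- **Relief variant**: deterministic, every sample a pivot once, one nearest
  hit and one nearest miss by Euclidean distance over all anchored-normalized
  features jointly, ties to the lowest index. Scores lie in [−1, 1];
  zero-range features score 0; singleton-class pivots are skipped.
- **Aggregation** across features is the mean (the published fitness is
  printed for scalars with no aggregation rule).

Weights, anchors and scalers are functions of the training split only.

## Deep belief network

Binary RBMs with the canonical two-layer energy `E(v,h) = −g·v − y·h − vᵀWh`
and Boltzmann probabilities `exp(−E)/Z` (the printed partition function omits
the exponential; the standard form is implemented). Inputs are min-max scaled
to [0,1] against the training split. Training is CD-1 (configurable k),
mini-batch 16, weights initialized N(0, 0.01²), biases zero. Deep features
are top-layer hidden *probabilities*, keeping the downstream pipeline
deterministic.

**Inter-layer contrast stretching.** On continuous tabular inputs the first
layer's hidden probabilities vary over a range of only a few hundredths, so a
second RBM fed raw probabilities sees nearly constant visible units and
degenerates to a bias-only model (its features collapse to constants). Each
layer's training-time hidden probabilities are therefore affinely stretched
to span [0,1] (anchors stored in the model, reused and clipped at transform
time) before feeding the next layer. With this, the defaults — layers
(32, 16), 60 epochs, learning rate 0.2 — yield deep features on which a
linear probe separates an effect-size-3 two-cluster dataset with ≥ 0.98
held-out accuracy across seeds.

The exhaustive partition-function routine is a testing aid guarded to
D + F ≤ 20 units.

## MS-CAGRU

- **Branches**: one 1-D convolutional encoder per feature view (original,
  weighted, deep), kernel sizes 3/5/7 respectively — the three receptive-field
  scales — stride 1, same-padding, 8 channels, tanh activation (configurable,
  linear/relu available). Each branch has a mirror decoder used only for
  reconstruction-MSE pretraining (15 epochs by default; 0 disables and leaves
  parameters at initialization).
- **Fusion**: the flattened branch encodings concatenate into `EF`; a further
  1-D convolution (8 channels, kernel 3) encodes `EF`.
- **GRU head**: tabular rows are not sequences, so the fusion stage's channel
  axis is presented to the GRU as the step sequence (channel = time step,
  step input = the channel's width). This is the minimal consistent reading
  of "the GRU replaces the fully connected layer" and is isolated in one
  place so sliding-window alternatives can be swapped in. The cell is the
  canonical two-gate GRU — `z = σ(W_z[h,x]+b_z)`, `r = σ(W_r[h,x]+b_r)`,
  `c = tanh(W_c[r⊙h,x]+b_c)`, `h' = (1−z)⊙h + z⊙c` — the published
  equations print the two gates identically and mix symbols, so the standard
  form they describe in words is implemented.
- **Training**: softmax cross-entropy on the final hidden state, Adam at
  1e-3, batch 32, 60 epochs; all initialization and batch order derive from
  the run seed; inference has no stochastic layers. Everything is numpy with
  hand-written backpropagation (the backward passes are verified against the
  identity-kernel architectural oracle and gate-saturation hand cases in the
  test suite).

## Metric suite

Standard textbook definitions throughout (the printed formulas for F1, FDR,
TPR and TNR in the source description are garbled; the published metric
table's rows are mutually consistent under the standard definitions, which is
the validation surface the tests use). Zero-denominator ratios are NaN with a
flag, never exceptions. `implied_metrics_from_rates` inverts
(sensitivity s, specificity c, precision v) to the unique prevalence
`p = v(1−c)/(s(1−v) + v(1−c))` and reconstructs the full suite from the
normalized cells — the mechanism behind the table-consistency checks.

## Pipeline

Stage order: data → stratified 75/25 split → anchors + IEMOA weight
optimization (training split) → DBN fit (training split) → bundle assembly
(original and weighted views min-max scaled against training; deep view from
the DBN) → MS-CAGRU pretrain + train → metric suite on the held-out split.
Ablations: `optimize_weights=False` uses uniform 0.5 weights;
`use_deep_features=False` feeds a zero-width deep view. Reports echo the full
configuration and all seeds; identical configurations reproduce identical
reports bitwise.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the full
stack is exercised in minutes on one CPU: n = 400 for headline learning
checks (n = 80–240 for unit-level checks), 20 optimizer seeds for convergence
statistics, 10 seeds for weight recovery (n = 160, 2 informative + 4 noise
features), 100 Monte-Carlo datasets for the Relief null, and enumerated RBMs
up to 6–8 units for exactness checks.

## Known limitations

- The GRU sees a fixed 8-step pseudo-sequence; no temporal semantics.
- CD-1 is a biased gradient; the DBN is a feature extractor here, not a
  calibrated generative model, and is never fine-tuned by backpropagation.
- The weighting objective's χ²/n and Relief terms are commensurate only
  roughly; their relative influence shifts with bin occupancy.
- Absolute accuracies published for the original external dataset are not
  reproducible here: that data's preprocessing and the network widths behind
  those numbers are unspecified. The package instead validates the published
  tables' *internal* consistency exactly and the stack's learning behavior on
  synthetic data with known signal.
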