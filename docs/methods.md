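# Methods

## The selection model

Given a min–max normalized expression matrix `X` (samples × n features), a
concrete autoencoder (CAE) learns to pick `k` *actual* input features whose
values suffice to reconstruct all `n` features. The encoder is a concrete
selection layer: node `j` holds a logit vector `α_j ∈ R^n` and, during
training, draws a relaxed one-hot weight vector from the concrete
(Gumbel-softmax) distribution

    w_j = softmax((α_j + g) / T),   g_i ~ Gumbel(0, 1) i.i.d.,

encoding the sample as `z_j = w_j · x`. A feedforward decoder (two hidden
layers of 300 units, leaky ReLU with slope 0.1, 10% dropout, linear output)
maps `z ∈ R^k` back to `R^n`; the loss is the mean squared reconstruction
error. The temperature follows an exponential schedule
`T(e) = T₀ (T_E/T₀)^(e/E)` from `T₀ = 10` to `T_E = 0.1`, updated once per
epoch, so selection moves from near-uniform exploration to near-one-hot
commitment. After the final epoch each node's feature is extracted as
`argmax α_j`, and the held-out reconstruction error is recomputed with hard
one-hot selection. Optimization is Adam at learning rate 0.002 for 300
epochs with an 80/20 stratified train/validation split. All of this is
implemented directly in NumPy (hand-written backpropagation), which keeps a
fixed-seed run bit-reproducible on a fixed BLAS.

Noise is drawn *per sample*: each sample in a minibatch explores its own
concrete draw. With a few hundred samples and a few thousand optimizer
steps, per-sample draws are what gives the selector enough parallel
exploration to rank correlated candidate features; a single shared draw per
batch measurably degrades selection at this scale. The validation-loss curve
uses one concrete draw per node (shared across validation samples) at the
current temperature — stochastic enough to mirror the training objective at
a fraction of the cost — while the `val_mse` stored in the run result always
uses hard selection.

Selector logits start at exactly zero: a fully symmetric start in which the
nodes differentiate only through their stochastic draws. Compared with a
small random initialization this measurably reduces the chance that two
nodes lock onto the same feature early.

### Batch size

The minibatch size defaults to 32. This method was originally tuned on
cohorts of several thousand samples, where a 256-sample batch still gives
the selector over a dozen gradient updates per epoch; at the desk scale
used here (hundreds of samples) a 256-sample batch collapses that to 2
updates per epoch and the selection probabilities cannot harden within 300
epochs (the mean–max probability plateaus near 0.2). A batch of 32 restores
a comparable update count per epoch. The value is exposed in `CAEConfig`.

### Convergence diagnostics

The per-epoch trace records the temperature, training loss, validation loss
and the **mean–max probability**: the mean over nodes of
`max_i softmax(α_j / T)_i`, i.e. the largest selection probability each
node's concrete distribution currently assigns. It starts near `1/n` and
approaches 1 as nodes commit; a final value well below 1 flags an
unconverged selector. It is computed at the current temperature because that
is the distribution the layer actually samples from; the raw-logit softmax
would understate commitment under annealing.

## Multi-run aggregation (mrCAE)

A single CAE run is stochastic and different runs select different,
comparably informative subsets. The multi-run system trains `R` CAEs with
seeds `base_seed + i`, counts for every feature the number of runs whose
deduplicated selection contains it, and ranks features by that frequency
(ties broken by feature ID, ascending, so reports are deterministic). The
Top-N prefix of the ranking is the *stable set*. Within one run a feature
picked by several nodes counts once. Runs are persisted as JSON keyed by
seed, so interrupted jobs resume and nested systems (10-run, 20-run, …)
can share one run pool as exact prefixes.

## Evaluation harness

Feature subsets are scored by stratified 5-fold cross-validation with a
linear-kernel SVM (C = 1.0, not tuned; recorded in the result). Precision,
recall and F1 are macro-averaged over classes — with a dozen imbalanced
classes, micro averaging would nearly duplicate accuracy. Scoring different
subsets with the same seed reuses identical folds, so comparisons are
paired. The harness accepts any named feature list, so externally produced
selections (lasso, random-forest importance, …) can be compared without
being reimplemented here. Random-search tuning draws (epochs, learning
rate) uniformly from caller-supplied grids, trains one CAE per trial and
scores its selection with the same harness; failed trials are logged, not
fatal.

## Prognostic screening

For each candidate feature, samples with expression at or below the cohort
median form group A (low), the rest group B (high); features whose
zero-expression fraction exceeds 0.5 (strict majority, configurable) are
excluded, and all-constant features are skipped as degenerate. Group
survival is compared with the two-group log-rank test: at each distinct
event time, expected events split proportionally to the at-risk counts; the
statistic is the Mantel–Haenszel form `(O_A − E_A)² / V` with the
hypergeometric variance `V` accumulated over event times, referred to χ²(1).
This is the statistic the established survival packages report, and the
implementation agrees with them to 1e-8 (the test suite cross-checks
against lifelines on random fixtures). The hazard ratio is estimated from
the same internals as `HR = (O_A/E_A) / (O_B/E_B)`, so `HR > 1` means the
low-expression group dies faster; when group B has no events the ratio is
reported as +infinity. A feature is called *prognostic* when `p ≤ α`
(default 0.05, uncorrected — a Benjamini–Hochberg filter can be applied
downstream by the caller) and the hazard ratio differs from 1 (literal
reading, `|HR − 1| > 1e-9`). Censored subjects tied with an event time
remain at risk at that time. Kaplan–Meier curves use the standard
product-limit estimator.

## Synthetic cohorts

The generator plants a known causal structure so that every stage is
testable without any download:

- **Drivers** (10 of 200 features by default): each driver assigns the
  classes equally spaced means `class_sep` apart (assignment permuted per
  driver) plus unit Gaussian noise, so drivers carry the class signal.
- **Dependent features** (60% of the remaining features): positive,
  sum-to-one mixes of `mix_sparsity = 3` randomly chosen drivers plus
  `N(0, noise_sd²)` noise. With the defaults (`noise_sd = 2`) a dependent
  feature correlates moderately (r ≈ 0.5–0.6) with its driving combination,
  the range typical of downstream co-expression. This moderation is what
  makes the planted truth *identifiable*: with near-noiseless dependents, a
  dependent feature is an interchangeable proxy for its drivers and no
  reconstruction-based selector — including an exhaustive linear oracle —
  can prefer the true drivers.
- **Noise features** (the rest): standard Gaussian, no signal.
- The matrix is min–max normalized per feature; class sizes are balanced
  within one sample; everything is deterministic per seed.

Survival times are exponential with hazard
`λ₀ · exp(β · 1[driver > median])` (defaults `λ₀ = 0.01`, `β = log 2`, time
units opaque); setting `β = 0` yields a prognostically null feature for
type-I-error studies. Censoring times are independent `U(0, c)` with `c`
solved numerically so the expected censored fraction equals `censor_rate`
(default 0.2).

What the generator does *not* emulate: negative-binomial count noise,
zero inflation / dropout, batch effects, correlated censoring, or
class-dependent survival. Tests passing on these cohorts demonstrate the
machinery — recovery of planted structure, calibrated error rates — not
performance on real sequencing data.

## Numerical choices and degenerate inputs

- Min–max normalization maps constant features to all-zero (keeps
  dimensionality; such features carry no signal). Statistics are computed on
  the full matrix before any split, mirroring the upstream pipeline order;
  this leaks no labels but does leak test-set ranges, which is accepted and
  documented.
- Stratified splitting delegates to scikit-learn; a class with one sample is
  an error naming the class.
- Temperature, weights and logits are float32 in training; the public
  concrete-weights helper is float64 and asserts weight rows sum to one
  within 1e-9.
- Frequency ranking ties break by feature ID ascending. `top_n` beyond the
  table size returns the full ranking.
- Degenerate median splits (all values equal) and zero-event cohorts are
  skipped with a flag in the screen, fatal only when called directly.
- The O/E hazard-ratio estimator is reported as +infinity when the
  denominator group has no events.

## Problem sizes

Default study conditions are 500 samples × 200 features, 10 drivers,
4 classes; recovery checks use 10-run systems over 5 base seeds, stability
comparisons 5-run systems at k = 40, and screening calibration 1000
null replicates at n = 300. These sizes were chosen so the full pipeline
(training included) runs end-to-end on a single CPU in minutes while leaving
each statistical check enough replicates to be binding.

## Known limitations

- With k nodes racing independently, two nodes can commit to the same
  feature; a single run therefore typically yields slightly fewer than k
  unique features (if placement over k equally attractive targets were
  uniform, the expected unique count would be `k(1 − (1 − 1/k)^k)` ≈ 0.65k).
  The decoder's diminishing-returns gradient counteracts duplication only
  partially. This is intrinsic to the single-run method and is precisely
  what multi-run aggregation repairs.
- The selector's convergence depends on the update count; very small
  cohorts (tens of samples) would need more epochs than the default 300.
- The log-rank HR estimator is crude relative to a Cox fit; it is used
  because it derives from the same O/E internals as the test itself.
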