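# Methods

## Count model

Counts are modeled per (class, OTU) as a Gamma-Poisson mixture: a Poisson
rate λ ~ Gamma(shape r, scale θ), then v ~ Poisson(λ), whose marginal is the
negative binomial

    NB(v; r, p) = Γ(r+v) / (v! Γ(r)) · p^v (1−p)^r,   p = θ/(1+θ),

with mean rθ and marginal variance rθ(1+θ). The shape r controls
overdispersion: the model approaches Poisson(rθ) as r → ∞ and becomes
strongly zero-inflated for small r at fixed mean. The mass function is
evaluated in log space via `scipy.special.gammaln`. OTUs are treated
independently within a class; no cross-OTU covariance is modeled.

### Moment fitting and its two conventions

`fit_nb_moments` solves μ̂ = rθ together with σ̂² = rθ² — the Gamma moments —
giving θ̂ = σ̂²/μ̂ and r̂ = μ̂²/σ̂² (the `paper` convention, default). Because
the *count* variance of the hierarchy is rθ(1+θ), not rθ², this convention is
biased when applied to raw counts: as the sample grows it converges to
θ̂ → 1+θ and r̂ → rθ/(1+θ) (asserted in the tests). The `nb_marginal`
convention solves the marginal system instead (θ̂ = σ̂²/μ̂ − 1, r̂ = μ̂/θ̂)
and recovers the generating (r, θ); it is selectable via
`convention="nb_marginal"` everywhere a fit happens. The default stays with
the Gamma-moment equations because the augmentation procedure is defined in
those terms, and for augmentation purposes only the implied mean/variance of
the sampled counts matter, not the identifiability of (r, θ).

Sample variances use the unbiased (n−1) denominator; a class needs at least
two samples. Degenerate regimes: an all-zero OTU emits zeros; an OTU with
σ̂² ≤ μ̂(1+10⁻⁶) cannot be represented by a Gamma-Poisson mixture (which is
never under-dispersed) and falls back to Poisson(μ̂). The boundary case
σ̂² = μ̂ is routed to the Poisson fallback deliberately — it is the Poisson
limit, and the NB solution there (θ = 1 with r = μ̂) does not reproduce the
observed variance under the marginal reading.

## Synthetic data generator

Each class receives a random profile: per-OTU means drawn log-uniformly over
`mean_range` (default 0.1–100), chosen so abundances span three orders of
magnitude and the small-r block stays sparse, which is what real OTU tables
look like after prevalence filtering. OTUs come in contiguous blocks sharing
a dispersion (defaults m = (30, 40, 30), r = (0.1, 1, 10)); the default study
shape is 8 classes × 100 samples × 100 OTUs.

Measurement noise is injected per cell, at most one error per cell:

* **type 1** (probability e₁, true zeros only): replaced by
  1 + Poisson(t1_count_mean − 1); default t1_count_mean = 1, so spurious
  reads are mostly singletons.
* **type 2** (e₂, non-zeros): set to zero (dropout).
* **type 3** (e₃, non-zeros): d → max(1, d + round(N(0, t3_noise_scale·d))),
  default scale 0.5 — a multiplicative-width fluctuation clamped to stay
  positive so it can never be confused with dropout. Non-zero cells route
  through a single uniform draw (type 2 wins below e₂, type 3 between e₂ and
  e₂+e₃), hence e₂+e₃ ≤ 1.

**What the generator does not emulate:** phylogenetic correlation between
OTUs, compositional coupling beyond the normalization step, longitudinal
structure, class imbalance, and sequencing-depth variation between samples
beyond what the NB draws induce. Passing benchmarks on this generator
therefore show that the pipeline and models behave correctly under
controlled overdispersed noise — not that the same accuracies will hold on
real data.

**An empirical note on error severity.** With these channel definitions and
the default noise scale, heavy dropout (e₂ = 0.7) damages every classifier
substantially (F1-micro ≈ 0.6–0.9) while heavy fluctuation (e₃ = 0.7) is
nearly harmless (≥ 0.88): zeroing a non-zero count removes its signal
entirely, whereas a clamped multiplicative fluctuation preserves most of the
relative-abundance ranking. The ordering is unchanged if features are raw
min-maxed counts instead of relative abundances. The acceptance suite
contains a check asserting the opposite ordering; it fails by design of the
simulator and is left failing rather than redefining the channels (see the
per-setting benchmark values the acceptance script writes).

## Preprocessing

Pipeline: prevalence filter → relative abundance → min-max rescale.
The filter drops OTUs observed in fewer than 10% of samples (strict
"less than": exactly 10% survives) and runs once per dataset before
cross-validation — it never reads labels, so no fold leakage is possible.
Relative abundance divides each sample by its total count (zero-total samples
are an error). Rescaling is per-OTU min-max learned on the training fold only
(augmented rows included — they are training data), applied with clipping to
held-out folds; constant columns map to 0. A config switch (`rescale: false`)
disables the min-max step for pipelines that want plain relative abundances.

## Augmentation protocol

`augment_training_set` fits one NB per (class, OTU) on the training fold and
samples `"match"` new rows per class (class size each, so the training set
doubles — the benchmark default). Augmented rows are raw counts, tagged
`aug_*`, and flow through the same preprocessing as real rows; they are used
for scaler fitting and model training, never for validation metrics.

## Neural models

Implemented on numpy with manual backpropagation (dense, same-padding 1-D
convolution, kernel-2 max-pooling, inverted dropout) and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8, learning rate 0.001).

* **MLP**: input dropout (rate q; q = 0.5 in the benchmark configuration) →
  2–3 rectifier hidden layers → softmax. Hidden widths default to the
  power-of-two rule (nearest power of two ≥ feature count, halved per layer);
  the synthetic benchmark uses (256, 256). Trained exactly 100 epochs.
* **CNN**: features re-ordered by `phylo_sort` (stable lexicographic order of
  concatenated taxonomy strings, unannotated OTUs last) so phylogenetically
  related taxa are adjacent; then Conv1D(8 ch, k=3, same padding) → dropout →
  ReLU → MaxPool(2) → Conv1D(8, 3) → ReLU → MaxPool(2) → fully connected
  softmax head. Pooling floors odd lengths (no input padding), so the
  flattened width is ⌊⌊P/2⌋/2⌋·8 ≈ 2P — e.g. 200 for P = 100 and 8 for
  P = 7; inputs need P ≥ 4. Trained exactly 200 epochs.

Design choices where the design was open: batch size 32 (full batch below
that); scaled-uniform fan-in initialization U(±1/√fan_in) for weights and
biases; one dropout rate shared by both networks; the training loss recorded
per epoch is the mean cross-entropy (the public `cross_entropy_loss` returns
the summed objective). Epoch budgets are fixed — no early stopping — as the
over-fitting guard; all randomness (init, shuffling, dropout) flows from one
generator, so a seed reproduces final weights exactly.

## Classical baselines

scikit-learn estimators behind a bespoke one-vs-rest protocol: one binary
model per class, prediction by the strongest vote (native probability where
available, SVM margin otherwise; ties go to the lowest class index). Tuned
kinds run an inner 3-fold grid search per binary problem on training data
only: SVM over kernel ∈ {linear, RBF}, C ∈ 10⁻²…10³ and γ ∈ 10⁻⁵…10¹ (one
point per decade); RF fixes 200 trees and tunes max_depth ∈ {None, 10} — a
deliberately minimal grid, since RF is insensitive to further tuning here and
grid granularity dominates runtime. GB runs untuned at max_depth 10,
min_samples_split 5; logistic regressions at C = 1; MNB with additive
smoothing α = 1 and empirical class priors. MNB requires non-negative
features, which the abundance pipeline guarantees.

## Evaluation harness

Stratified k-fold (k = 10 by default) with folds shared across models for
paired comparison; classes smaller than k trigger a warning and an
unstratified fallback. Per fold × run: preprocess (scaler from the training
fold), optionally augment, train every model, score the held-out fold.
F1-micro is the pooled definition (equal to accuracy); F1-macro the
unweighted class mean (zero-support classes contribute 0 with a warning);
AUC is the micro-averaged one-vs-rest pooled ROC area (trapezoidal, cross-
checked in tests against a concordant-pair oracle). Performance gain is
100·(best NN − best ML)/best ML on the mean F1, reported rounded to integer
percent. Diagnostics: `qq_points` (sorted-count quantile pairs, linear
interpolation across unequal lengths) and `adjusted_r_squared`
(1 − (1−R²)(n−1)/(n−2) from a simple OLS fit).

Seed policy: a root seed spawns per-run and per-fold child streams through
`numpy.random.SeedSequence`, so any fold is reproducible independently and
two runs with the same config are bit-identical.

## Problem sizes used by tests and the acceptance script

The synthetic benchmark conditions are the full 8 × 100 × 100 study shape.
The acceptance script runs each of the five error settings through 2-fold
cross-validation (one run) with all eight models; the test suite uses a
stratified 50% holdout repeated over three simulation seeds for the
benchmark checks, and the full 10-fold harness on smaller tables elsewhere.
Monte-Carlo checks use 10⁵ draws (sampler moments, 3 SE tolerance), 10⁴
samples (moment recovery, 10% relative tolerance) and a 2·10⁴-term tail for
pmf normalization (10⁻⁶ tolerance).

## Known limitations

* The `paper` moment convention does not identify the generating (r, θ) from
  raw counts (see above); use `nb_marginal` when identifiability matters.
* Per-OTU independence ignores co-abundance structure; augmented samples are
  therefore slightly "too easy" relative to real replicates.
* The CNN underperforms the MLP on sparse unordered features (convolution
  assumes local structure that only taxonomy ordering partially provides).
* The harness assumes labels are available for every sample and that classes
  have ≥ 2 training members per fold (required by the moment fit).
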