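# Methods

## Problem setting

Expression studies of rare phenotypes routinely produce matrices with
thousands of features and a severely skewed class split (a 9:1
majority:minority ratio is typical of the benchmarks this package
targets). Univariate filter scores computed on pooled statistics are
dominated by the majority class: a feature can rank highly while carrying
no information about the minority samples at all. The selector implemented
here counteracts that in three ways — robust location/scale statistics,
explicit amplification of the minority-class terms, and a multivariate
margin criterion — followed by an L1 step that removes redundant
survivors.

## Score model

Let κ⁺, κ⁻ be the class counts (κ⁺ ≤ κ⁻ by construction: the rarer label
is always the minority; on a tie the declared positive label plays the
minority role and τ = 1). The amplification factor is τ = κ⁺/κ⁻ ∈ (0, 1].

Per feature b the package computes class medians η_b^±, the pooled median
ζ_b over all κ samples, mean absolute deviations θ_b^± about the class
median, and within-class sample variances (denominator n − 1, so each
class needs ≥ 2 samples). Stability weights are inverse variances,
υ_b^± = 1 / max(Var_±, ε). The robust discriminant score is

    Φ_b = [υ_b⁺(1+τ)|η_b⁺ − ζ_b| + υ_b⁻|η_b⁻ − ζ_b|]
          / [υ_b⁺(1+τ)θ_b⁺ + υ_b⁻θ_b⁻]

with the denominator floored at ε. Properties relied on by the tests:
Φ ≥ 0; Φ is invariant under per-feature affine maps x → a·x + c with
a > 0 (both numerator and denominator scale by a/Var·…, and the common
factor cancels — verified numerically to 1e−9); with balanced classes the
minority terms carry weight exactly 2.

Interpretive notes on deliberately resolved ambiguities:

- **υ as within-class feature variance.** The weights are the inverse
  *within-class sample variance of the feature*, not the sampling variance
  of the median estimator. The feature-variance reading keeps the score a
  pure plug-in statistic; a bootstrap variance of the median would add a
  resampling layer with no clear benefit at these class sizes (a minority
  class of 10 gives a very noisy bootstrap variance).
- **θ about the class median.** The mean absolute deviation is centered on
  the class median, consistent with the median-based numerator.
- **ε floors instead of dropping features.** Zero-variance or
  zero-denominator features keep finite scores (ε = 1e−8 in squared
  expression units) so all score vectors stay length p and downstream
  alignment is trivial.

## Margin weights

A linear soft-margin SVM is fitted with the minority class coded +1
(cost C = 1 by default). The weight vector is assembled explicitly from
the dual solution, ω = Σ_a γ_a y_a x_a over the κ* support vectors, and a
test asserts this equals the solver's primal coefficients. By default
features are z-scaled before the fit so ω entries are comparable across
genes of different dynamic ranges; the scaling record is kept on the
model object, and `standardize=False` exposes the raw-space fit. The
combined ranking score is Ψ_b = |Φ_b · ω_b|, invariant to a global sign
flip of ω (label-orientation independence).

## Ranking and L1 refinement

Features are ranked by descending Ψ with ties broken by ascending column
index, deterministically. The top d = max(5·n_final, 50) features (d is
configurable, clamped to p) form the candidate pool — large enough that
the L1 step has genuine room to discard, small enough that the logistic
fit is cheap and well-conditioned at κ ≈ 100.

The refinement minimizes the penalized negative log-likelihood
Σ_a −[y_a log d_a + (1−y_a) log(1−d_a)] + λ‖β‖₁ with
d_a = 1/(1+e^{−x_aᵀβ}), via liblinear (sklearn's `C` = 1/λ). Candidates
are standardized inside the refinement so the penalty is scale-fair.
λ is chosen by stratified K-fold (default 5) cross-validated deviance
over a fixed grid λ ∈ 10^{2 … −3} (11 log-spaced points, descending so a
deviance tie resolves to the sparser model). If the chosen λ zeroes every
coefficient, the grid is stepped down until at least one survivor appears;
a user-fixed λ is respected as given, and an all-zero fit at a fixed λ
raises an explicit empty-refinement signal.

**Exactly collinear candidates.** For byte-identical standardized columns
the L1 optimum is non-unique (any split of the coefficient along the
duplicate set has equal objective), and coordinate-descent and stochastic
solvers land on the symmetric interior solution with *all* duplicates
nonzero. Since duplicates carry zero additional information, the
refinement collapses byte-identical standardized columns to a single
representative (the highest-ranked) before the fit and maps exact zeros
back to the duplicates. This makes the redundancy guarantee — at most one
member of an identical set survives — deterministic rather than
solver-dependent. Merely correlated (non-identical) features are left to
the penalty itself.

The final set 𝒢\* is the intersection of the candidate pool with the
nonzero-β set, in Ψ-rank order, truncated to n_final (default 10). When
the intersection is smaller than n_final and backfill is on (default),
the next-best ranked candidates are appended and flagged as backfilled in
the provenance, so the "top-k genes" contract of downstream classifiers
is always satisfiable; `backfill=False` exposes the bare intersection.

## Simulation generator

`simulate_dataset` emulates the imbalanced benchmark design: κ = 100
samples, p = 5000 features, a 9:1 majority:minority split by default.
Class sizes follow κ⁺ = round(κ·τ/(1+τ)) (half-up, floored at 1) and
κ⁻ = κ − κ⁺, so the counts always sum to κ. Features are multivariate
normal: the majority mean is 0 everywhere, the minority mean is δ
(`effect_size`, default 1.0, in noise-SD units) on the first
`n_informative` features and 0 elsewhere; the covariance is identity or
block-equicorrelated (consecutive blocks of `block_size`, correlation ρ,
drawn through a per-block Cholesky factor). The mean and covariance
defaults are the simplest structure consistent with that design — zero
majority mean, pure mean-shift signal, unit noise — and every piece is
overridable. `enforce_imbalance` reproduces the benchmark preprocessing
step of downsampling the minority class (seeded, without replacement,
never upsampling, minimum 2 minority samples) to a target ratio.

What the generator does *not* emulate: count-distribution features
(negative-binomial mean–variance coupling), heavy tails, batch effects,
and realistic gene–gene correlation graphs. Passing tests on this
generator therefore demonstrate correctness of the statistics and the
selection machinery and recovery of mean-shift signal under imbalance —
not performance on any particular real dataset.

## Evaluation harness

One run = one seeded stratified split (70/30 by default; per-class
rounding, both partitions keep ≥ 1 sample of each class), feature
selection on the training rows only, a classifier (random forest, SVM, or
distance-weighted kNN, each at scikit-learn defaults — they are plumbing,
not a contribution) trained on the selected columns and scored on the
held-out rows. Metrics are accuracy, sensitivity, specificity, F1 and
precision with the **minority class as positive**; any 0/0 denominator
yields 0 with a degeneracy flag rather than NaN. Repeated evaluation runs
seeds base…base+n−1 and reports mean ± sample SD (SD = 0 for a single
run) plus per-feature selection frequencies, the standard stability
summary across resamples. Information hygiene is enforced structurally
(the selector never receives test rows) and asserted by a test that
corrupts the test partition and verifies the selected set is unchanged.

A calibration note: under permuted labels a classifier at a 9:1 ratio can
sit slightly *below* the majority base rate, because it predicts the
minority class for a small fraction of null test samples; that deficit is
a property of the classifier under extreme imbalance, not of the harness.
The RBF-SVM back-end degenerates to near-pure majority prediction under
the null and is therefore the cleanest probe of harness calibration; the
calibration test also asserts that no configuration sits *above* chance,
which is the signature actual leakage would leave.

## Numerical and design choices

- Determinism: every stochastic step (simulation, splits, CV folds,
  minority downsampling) draws from an explicit integer seed;
  re-invocation with the same inputs and seed is byte-identical. libsvm
  and liblinear are deterministic on fixed input.
- Ties in every sort break by ascending feature index.
- The λ grid spans 10² to 10⁻³: above 10², every fit at these scales is
  empty; below 10⁻³, liblinear is effectively unregularized and slow to
  converge.
- Problem sizes in the test suite (p = 500 for recovery, p ≈ 10–100 for
  property and calibration checks, 50–500 replicates, 100 evaluation
  runs) were chosen so the whole suite completes in a few minutes while
  keeping every check's statistical power; they are scaled-down versions
  of the same study design, not different designs.

## Known limitations

- Binary classes only; no multiclass extension, no missing-value
  handling (non-finite input is rejected with cell coordinates).
- The margin layer is linear-kernel only; nonlinear class boundaries are
  outside the score's model.
- The L1 step assumes the candidate pool fits a dense in-memory logistic
  fit; d is meant to be ≪ p.
- With `backfill=False` the final set can be smaller than requested, or
  empty if a fixed λ kills every coefficient.
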