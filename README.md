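# mwrds

Feature selection for **binary, class-imbalanced, high-dimensional
expression data** — bulk or single-cell transcriptomics matrices where one
class (tumour subtype, responder group, rare cell state) holds only a
small fraction of the samples and classical filter scores are dominated by
the majority class.

## The method

Given a samples × features matrix 𝒳 ∈ ℝ^{κ×p} and binary labels with
minority/majority counts κ⁺, κ⁻, the selector works in four layers:

1. **Minority amplification.** τ = κ⁺/κ⁻ quantifies the imbalance; the
   minority-class terms of the score are weighted by (1 + τ) so that rare
   class structure is not swamped.

2. **Robust discriminant score.** With class medians η_b^±, pooled median
   ζ_b, mean absolute deviations θ_b^± about the class medians, and
   stability weights υ_b^± = 1 / Var_±(x_b) (inverse within-class
   variance), each feature b gets

   Φ_b = [ υ_b⁺(1+τ)|η_b⁺ − ζ_b| + υ_b⁻|η_b⁻ − ζ_b| ] /
         [ υ_b⁺(1+τ)θ_b⁺ + υ_b⁻θ_b⁻ ]

   — a median/MAD analogue of a weighted standardized mean difference,
   robust to outliers and heavy tails.

3. **Margin weighting.** A linear soft-margin SVM (minority = +1) gives
   ω = Σ_a γ_a y_a x_a over the support vectors; the combined ranking
   score is Ψ_b = |Φ_b · ω_b|, so a feature must both separate the class
   medians stably *and* carry weight on the maximum-margin boundary.

4. **Redundancy elimination.** The top-d features by Ψ are refined with
   L1-penalized logistic regression (λ by stratified cross-validated
   deviance); the final gene set 𝒢\* is the intersection of the top-ranked
   pool with the nonzero-coefficient set, backfilled by rank to the
   requested size.

The package also ships the matching **simulation generator** (imbalanced
multivariate-normal data with planted informative features) and a
**repeated split-sample evaluation harness** (stratified 70/30 splits,
selection on training rows only, accuracy / sensitivity / specificity /
F1 / precision with the minority class positive, selection-frequency
tables across runs).

## Worked example

```python
from mwrds import SimConfig, SelectorConfig, simulate_dataset, mwrds_select

sim = simulate_dataset(SimConfig(n_features=500, n_informative=10,
                                 effect_size=2.0, seed=1))
res = mwrds_select(sim.X, sim.labels, SelectorConfig(n_final=10, seed=1))
print(res.provenance["tau"])   # 0.1111  (10 minority vs 90 majority samples)
print(res.final_set)
# ('G2', 'G1', 'G8', 'G6', 'G9', 'G10', 'G4', 'G5', 'G7', 'G415')
```

The generator planted a mean shift of 2 (in noise-SD units) on features
G1–G10 in the 10 minority samples; the selector recovers 9 of the 10
among 500 features, with one false positive (G415). Evaluating the
configuration over 20 stratified 70/30 split-sample runs with an SVM on
the selected genes:

```python
from mwrds import repeated_evaluation
summ = repeated_evaluation(sim.X, sim.labels, SelectorConfig(n_final=10),
                           "svm", n_runs=20, base_seed=0)
# accuracy:    0.9933 +/- 0.0137
# sensitivity: 0.9333 +/- 0.1368
# specificity: 1.0000 +/- 0.0000
```

Mean held-out accuracy 0.9933 against a majority base rate of 0.90, and
sensitivity 0.93 on a class with only 3 test samples per run — the
planted minority signal is found and generalizes.

The same selector is a scikit-learn transformer:

```python
from mwrds import MWRDSSelector
sel = MWRDSSelector(n_final=10, random_state=1).fit(sim.X.values, sim.labels.labels)
X_sel = sel.transform(sim.X.values)        # (100, 10)
sel.psi_, sel.ranking_, sel.get_support()  # scores, order, boolean mask
```

## Command line

```bash
mwrds simulate --seed 1 --n-samples 100 --n-features 5000 --out sim.tsv
mwrds select sim.tsv --label-column class --positive-label pos \
      --n-final 10 --seed 1 --out report.tsv
mwrds evaluate sim.tsv --label-column class --positive-label pos \
      --classifier svm --runs 100 --seed 1 --out-prefix eval
mwrds sweep sim.tsv --label-column class --positive-label pos \
      --tau-grid 0.1,0.2,0.3,0.4 --lambda-grid 0.01,0.1,1 --out sweep.tsv
```

`select` writes a per-feature report (rank, Φ, ω, Ψ, β, final-set and
backfill flags) plus a JSON sidecar with the configuration, τ and the λ
used; `evaluate` writes a per-run log and a mean ± SD summary;
`sweep` maps the number of L1 survivors over a τ × λ grid.

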