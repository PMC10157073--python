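# wmpattern

Multivariate pattern analysis of white-matter ROI feature tables for
small two-group neuroimaging cohorts.

`wmpattern` is a reusable implementation of the classification workflow
used in small-sample forensic/clinical neuroimaging studies that ask
whether a diffusion-MRI feature table separates a clinical group from
matched healthy controls even when no single feature does: a linear
maximum-margin classifier inside repeated nested cross-validation with
greedy wrapper feature selection, label-permutation significance,
feature-stability interpretation, prevalence-adjusted diagnostic
indices, classical univariate group statistics, and a post-hoc stepwise
regression linking the model's decision scores to clinical covariates.
It is aimed at biostatisticians and imaging researchers who want the
whole pipeline as tested, scriptable library code rather than a GUI
toolbox.

## The model

Subjects are rows of a feature table `X` (e.g. 72 white-matter features:
17 regions of interest × {FA, MD, RD, AD} plus 4 structural-connectivity
features) with labels `y ∈ {+1, −1}` (+1 = clinical group). The engine
runs a repeated nested cross-validation:

* **outer cycle (CV2)**, k₂ folds × r₂ repeats (study scale 10 × 10):
  estimates out-of-sample performance;
* **inner cycle (CV1)**, k₁ folds × r₁ repeats on each outer training
  partition: greedy forward *wrapper* selection — starting from the
  empty set, repeatedly add the feature (jointly with the best penalty C
  from a grid) that maximizes mean inner-validation balanced accuracy
  BAC = (sensitivity + specificity)/2, stopping when no candidate
  improves it.

All features are min-max rescaled to [0, 1] with training-fold statistics
only; each fold's winning configuration is refit on its full outer
training partition, scores its held-out fold, and joins the model
ensemble used for external cohorts (mean decision score
`f(x) = Σ wᵢxᵢ + b` over members; positive mean ⇒ +1).

Interpretation and inference:

* **CVR** (cross-validation ratio): per feature, mean weight across all
  models that selected it divided by the standard error of that mean — a
  Z-score-like stability index;
* **sign-based consistency**: exact two-sided binomial test of how often
  a feature's weight kept one sign across models, Benjamini–Hochberg
  FDR-controlled;
* **permutation test**: the full pipeline (selection included) rerun on
  permuted labels; p = (1 + #{null BAC ≥ observed}) / (1 + n_perm);
* **prevalence-adjusted metrics**: NND = 1/(sens + spec − 1),
  PPV(π)/NPV(π) by Bayes' rule at assumed prevalence π,
  PSI(π) = PPV + NPV − 1 and NNP(π) = 1/PSI;
* **post-hoc stepwise regression** (forward–backward on partial-F
  p-values, enter 0.05 / remove 0.10) of per-subject out-of-fold
  decision scores on covariates.

A synthetic cohort generator produces block-correlated Gaussian feature
tables with a sparse, mixed-sign planted group shift — individually too
small for any per-feature test at n ≈ 30, but jointly separable — plus
covariates tied to the true latent discriminant, so the whole pipeline
is testable end-to-end without any data download.

## Worked example

```python
from wmpattern import (SyntheticSpec, generate_cohort, NestedCVClassifier,
                       generate_external_cohort)

cohort = generate_cohort(SyntheticSpec(seed=7))      # 14 vs 15, 72 features
clf = NestedCVClassifier(cohort.features, k_outer=5, r_outer=2,
                         k_inner=3, r_inner=2,
                         c_grid=[0.0625, 0.25, 1.0, 4.0], seed=11)
res = clf.fit()
print(res.summary())
```

```
Nested cross-validated linear SVM classification
================================================
Subjects:        29 (14 positive / 15 negative)
Features:        72
Outer CV:        5 folds x 2 repeats
Inner CV:        3 folds x 2 repeats
C grid:          4 values [0.0625 ... 4]
Ensemble:        10 outer models, 60 weight records
------------------------------------------------
TP 11  TN 9  FP 6  FN 3
Sensitivity:     78.6%
Specificity:     60.0%
Balanced acc.:   69.3%
PPV / NPV:       64.7% / 75.0%
AUC:             0.76
NND:             2.59
PSI / NNP:       0.397 / 2.52
------------------------------------------------
Most frequently selected features:
  FA_dACC_right                in 24/60 models
  AD_sgACC_left                in 18/60 models
  SC_PFC_to_amygdala_left      in 18/60 models
  RD_amygdala_left             in 18/60 models
  MD_pgACC_left                in 18/60 models
```

The cross-validated balanced accuracy (69.3% here) is the headline
generalization estimate: each subject's prediction is the sign of its
mean held-out decision score. The selected-feature list shows the
wrapper repeatedly picking planted features (ACC fractional anisotropy,
left-amygdala diffusivity, prefrontal–amygdala connectivity) out of the
72 candidates. Continuing the session:

```python
ext = generate_external_cohort(53, seed=21)          # all-negative cohort
out = res.apply(ext, assume_all_negative=True)
print(f"external specificity: {100 * out.specificity:.1f}%")

perm = res.permutation_test(n_perm=100, seed=1)
print(f"permutation p (100 perms): {perm.p_value:.3f}")
```

```
external specificity: 60.4%
permutation p (100 perms): 0.059
```

`res.feature_stability()` returns the CVR / sign-consistency table,
`res.prevalence_sweep()` the prevalence-adjusted metrics, and
`res.posthoc_regression(cohort.covariates)` the stepwise fit of decision
scores on the covariates. The same stages are scriptable from the shell
(`wmpattern simulate/train/apply/permtest/interpret/metrics/groupstats/
posthoc/run`); `wmpattern run --config cfg.yaml` executes everything and
writes CSV tables plus a manifest with seeds and checksums.

## Layout

| Module | Contents |
| --- | --- |
| `wmpattern.io` | `FeatureTable` / `CovariateTable`, CSV/TSV readers and writers, label mapping, covariate alignment |
| `wmpattern.features` | canonical 72-name feature vocabulary |
| `wmpattern.simulate` | synthetic cohort generator, external cohorts, label permutation |
| `wmpattern.metrics` | confusion summaries, AUC, NND/PSI/NNP, prevalence sweep |
| `wmpattern.cv` | CV plans, fold-wise min-max scaler, linear SVM, greedy wrapper |
| `wmpattern.model` | `NestedCVClassifier` / `NestedCVResults`, ensemble application |
| `wmpattern.stability` | CVR, sign-based consistency, BH-FDR, permutation test |
| `wmpattern.univariate` | Mann–Whitney U, 2×2 chi-square, per-feature screen |
| `wmpattern.stepwise` | forward–backward stepwise OLS, post-hoc assembly |
| `wmpattern.cli` | `wmpattern` command-line interface |

See `docs/methods.md` for the statistical details, default parameters
and known limitations.
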