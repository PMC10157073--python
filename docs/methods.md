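# Methods

This note documents the statistical procedures `wmpattern` implements,
the default parameters and the reasoning behind them, what the synthetic
cohort generator does and does not emulate, and the numerical
conventions that matter for reproducing published tables.

## Data model

A cohort is a subject × feature matrix with labels in {+1, −1}
(+1 = clinical group of interest, −1 = healthy controls). The canonical
vocabulary is the 72-feature white-matter set: 17 regions of interest
(five anterior-cingulate subdivisions per hemisphere — caudal, dorsal,
rostral, subgenual, pregenual; two amygdalae; five corpus-callosum
segments) × four diffusion scalars (FA, MD, RD, AD), plus four
directional prefrontal-cortex↔amygdala structural-connectivity features
(normalized probabilistic fiber counts). Any other numeric feature set
is accepted with a warning; nothing downstream depends on the names
except reporting. Validation is strict for features (no missing values —
the classifier consumes every cell) and lenient for covariates
(missingness is flagged per column and handled by listwise deletion in
the one stage that uses them).

## Nested cross-validation engine

**Plans.** Outer (CV2) and inner (CV1) cycles are repeated stratified
k-fold partitions; defaults mirror the study design of 10 folds × 10
repeats at both levels (10,000 inner-winner configurations). Fold
assignment requires k at most the minority-class count; requesting
k = n yields leave-one-out with stratification waived and a warning. All
assignments derive deterministically from one master seed (inner cycles
are keyed by seed and (repeat, fold) coordinates), so a run is fully
reproducible from its configuration.

**Rescaling.** Features are rescaled to [0, 1] by per-feature training
minima/maxima; held-out values are clipped to [0, 1]; a feature constant
in training maps to 0.5 (the midpoint leaves the decision score
unbiased; the constant's value is irrelevant, which is verified by
test). Scaling is refit inside every training partition — outer test
folds and inner validation folds never touch the scaler that transforms
them.

**Classifier.** A linear C-SVM (hinge loss, penalty C). Fits go through
scikit-learn's libsvm binding via a thin wrapper that returns the primal
weights w and bias b directly; the wrapper's agreement with the public
`sklearn.svm.SVC` estimator is asserted by a property test over random
problems. Decision score = w·x + b on rescaled features; positive score
predicts +1; an exact zero predicts −1 (conservative toward the control
class, relevant only for degenerate constant models).

**Wrapper selection.** Greedy forward selection scored by mean
inner-validation balanced accuracy, jointly over the candidate feature
and a log-spaced penalty grid (default 2⁻⁶ … 2⁴, 11 values). The search
starts at the empty set with a chance-level baseline of 0.5 and stops
when no candidate improves the running best by more than ε = 1e-6 or
all features (or an optional `max_features` cap) are included. Ties
break toward the lower feature index, then the lower C — candidates are
scanned in that order and only strict improvements displace the
incumbent, which makes duplicated columns resolve to the first one. If
no feature ever beats chance the fold gets a constant majority model
whose score is the mean training label, keeping ensemble averages
continuous.

**Refit and aggregation.** Each outer partition's winning
(subset, C) is refit on the full outer training data (using every
available training subject, rather than carrying one inner-fold model)
and scores its held-out fold. A subject therefore has exactly r₂
out-of-fold scores; its cross-validated prediction is the sign of their
mean, and the single pooled confusion matrix over subjects is the
headline performance estimate (a documented alternative would pool
fold-level counts; the per-subject rule is used because it yields one
confusion matrix comparable across configurations and a continuous
per-subject score for the post-hoc stage). The outer refits form the
ensemble applied to external cohorts: each member applies its own scaler
and weights, members' scores are averaged (majority voting is available
as an option), and for a cohort declared all-negative the reported
specificity is the fraction predicted −1.

## Interpretation

**Cross-validation ratio.** For each feature, over the models in which
the wrapper selected it (zero-weight features do not influence the
decision score and are excluded): CVR = mean weight / (SD/√m), the mean
over its standard error — the bootstrap-ratio idea transplanted to CV
ensembles. With the default inner-model retention the records are the
r₂·k₂·r₁·k₁ inner-fold models trained with each partition's winning
configuration. Zero variance yields a signed-infinity sentinel with a
warning; never-selected features report absent statistics. A variant
using the SD alone (not the standard error) is available
(`cvr = mean/sd` follows from the reported m and sd columns) since the
literature is not unanimous about the denominator.

**Sign-based consistency.** Per feature, an exact two-sided binomial
test of the split between positive and negative weight signs against
0.5, over the models that selected it; exact rather than normal-
approximate because selection counts can be small. p-values are
Benjamini–Hochberg FDR-controlled at q = 0.05 across all evaluated
features (not only the most-selected ones).

**Permutation test.** Model-level significance compares the observed
cross-validated BAC against nulls obtained by rerunning the *entire*
pipeline — fold construction, wrapper selection, hyperparameter search —
on labels permuted uniformly at random with class counts preserved:
p = (1 + #{null ≥ observed}) / (1 + n_perm). The add-one correction
makes the test slightly conservative (verified by a type-I calibration
simulation). Default n_perm = 200 for desk-scale work; study-scale
analyses use 5,000.

## Diagnostic metrics

From confusion counts with +1 positive: sens = TP/(TP+FN),
spec = TN/(TN+FP), BAC their mean, PPV = TP/(TP+FP), NPV = TN/(TN+FN),
NND = 1/(sens+spec−1) (∞ when the Youden index is not positive),
PSI = PPV+NPV−1, NNP = 1/PSI (∞ when PSI ≤ 0). Ratios with zero
denominators are reported as absent, never as zero, and infinities are
returned rather than raised so sweeps cannot abort. AUC is the
rank-based Mann–Whitney statistic divided by n₊n₋, ties counting ½.

At an assumed prevalence π, Bayes' rule gives
PPV(π) = sens·π / (sens·π + (1−spec)(1−π)) and
NPV(π) = spec(1−π) / (spec(1−π) + (1−sens)π), from which PSI(π) and
NNP(π) follow. Two arithmetic conventions are provided: full-precision
inputs (the API default), and a *printed-rounding* mode that first
rounds sensitivity and specificity half-up to one decimal when expressed
as percentages. The published sweep tables this package mirrors are
reproduced digit-for-digit only under the printed-rounding convention
(e.g. NNP 23.57 at π = 0.01 from inputs 64.3%/86.7%, versus 23.64 at
full precision 9/14 and 13/15), so that mode is used when comparing
against printed values. Display rounding is half-up: one decimal for
percentages, two for NND/NNP, three for PSI as a fraction. One further
printed-source discrepancy is handled by following the defining formula:
where a published summary row lists a balanced accuracy of 75.0 next to
sensitivity 64.3 and specificity 86.7, the package reports
(64.3+86.7)/2 = 75.5, consistent with the accompanying text.

## Univariate statistics

Group comparisons use the two-sided Mann–Whitney U test, reporting U for
the first group (U₁ = Σranks₁ − n₁(n₁+1)/2); the p-value is exact for
n₁·n₂ ≤ 400 without ties and a tie-corrected normal approximation
otherwise (exact enumeration is cheap at cohort scale, and the 14/15
design sits well inside the exact regime). 2×2 frequency tables use the
Pearson chi-square without continuity correction (df = 1) — the
convention under which the published handedness example
(χ² = 0.0026, p = 0.96 for 13/1 vs 14/1) reproduces. The per-feature
screen runs U tests across the full feature family with BH-FDR at
q = 0.05; the FDR family is always an explicit argument, never implicit.

## Post-hoc stepwise regression

The response is each positive-class subject's repeat-averaged
out-of-fold decision score — the only per-subject score the pipeline
defines that is not contaminated by training (in-sample ensemble scores
would be circular). Candidates are the raw-scale covariates; main
effects only. Forward–backward stepping on partial-F (squared-t)
p-values with enter/remove thresholds 0.05/0.10 — the defaults of the
classical stepwise routine this stage mirrors; terms that make the
design rank-deficient are skipped with a warning. The final term set is
refit by OLS and reported with estimates, SEs, t statistics, two-sided
p-values, 95% CIs (estimate ± t₀.₉₇₅,df·SE), R², adjusted R² and the
model F test, plus the full step trace. Stepping is verified against an
independently coded exhaustive implementation on small candidate sets,
and a generative-recovery test checks that a single true predictor is
found with its coefficient inside its own CI.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not DTI physics: features are block-correlated Gaussians (exchangeable
correlation ρ = 0.3 within each modality block — FA, MD, RD, AD, SC;
ρ must lie in [0, 1) for positive definiteness), the two groups differ
by a sparse standardized mean-shift vector, and values are affinely
mapped into plausible ranges (FA ≈ 0.45 ± 0.05 clipped to [0, 1],
diffusivities in units of 10⁻³ mm²/s, positive; connectivity ≈
0.5 ± 0.12). The default effect map plants 20 of 72 features at
0.3–0.8 SD with mixed signs following the qualitative direction pattern
the pipeline is meant to recover (ACC FA raised in the positive class,
left-amygdala MD/RD lowered, left prefrontal–amygdala connectivity
raised, right lowered). Magnitudes were fixed within that band so that
the default 14 vs 15 cohort reproduces the regime of interest:
individually null per-feature tests after FDR, jointly separable by the
multivariate pipeline. Covariates are linear functions of each subject's
true latent discriminant score plus Gaussian noise — with age, verbal
IQ and education as pure-noise distractors and forensic-style scores
linked at varying strengths — plus one three-level ordinal rating
obtained by thresholding a latent variable, mimicking a professional
risk assessment in {0, 1, 2}.

What the generator does **not** emulate: absolute per-ROI scalar values
(not published), measurement noise structure of a scanner, non-Gaussian
tails, site/batch effects, or label noise. Passing tests on synthetic
cohorts therefore demonstrate the pipeline's correctness and its
behavior under a known ground truth — not that any particular real
cohort is separable.

## Problem sizes, tolerances and degenerate inputs

Desk-scale defaults used by the test suite (the package's own choice of
test conditions): nested-CV property tests run the 14/15 × 72-feature
default cohort at 5 outer folds × 2 repeats, 3 inner folds × 2 repeats
with a 4-point C grid; the permutation type-I calibration uses 50 null
cohorts (n = 16, 4 features) × 200 permutations at a 3×1/2×1 plan with a
single C and a 2-feature cap; the stepwise null simulation uses 200
replicates at n = 14. Under those conditions the measured behavior is:
cross-validated BAC comfortably above chance in the median across seeds
(with wide seed-to-seed spread, as expected at n = 29), zero
FDR-significant univariate features in the median, planted features
selected about five times more often than noise features, and CVR signs
agreeing with the planted directions for at least 80% of selected
planted features. Study-scale plans (10×10 at both levels, 11-point
grid) are the API defaults but are orders of magnitude heavier; the
engine is O(r₂k₂ · steps · d · |C-grid| · r₁k₁) SVM fits.

Numerical conventions: wrapper improvement threshold ε = 1e-6; SVM
stopping tolerance 1e-3 (libsvm default); scaler degeneracies and
undefined metric ratios resolve to documented sentinels (0.5, absent,
±∞) rather than exceptions; tie at zero decision score predicts the
negative class; stepwise stepping is capped at 200 iterations as a
cycle guard.

## Known limitations

* The wrapper is strict greedy-until-no-improvement; percentile-based
  retention or early stopping variants used by some toolboxes are not
  implemented.
* The ensemble applied externally is the full set of outer refits;
  reduced "best members" ensembles are not implemented.
* The sign-consistency operationalization is the exact binomial test on
  weight signs; it is inspired by, but not identical to, published
  sign-consistency formulations for wrapper ensembles.
* No confidence intervals for predictive values, no probability
  calibration, no nonlinear kernels, no imaging I/O (feature tables are
  assumed already extracted).
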