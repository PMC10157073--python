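"""Nested cross-validated linear SVM classification engine.

The modelling surface follows the Model/Results idiom: build a
:class:`NestedCVClassifier` from a labeled :class:`~wmpattern.io.FeatureTable`,
call :meth:`~NestedCVClassifier.fit`, and work with the returned
:class:`NestedCVResults` — cross-validated confusion metrics, per-subject
out-of-fold decision scores, the retained model ensemble for external
application, permutation significance, and feature-stability maps.

Algorithm per outer training partition (repeat x fold):

1. run the inner cycle (repeated stratified k-fold on the outer training
   subjects only) with greedy forward wrapper selection over a penalty
   grid, scored by mean inner-validation balanced accuracy;
2. refit the winning (feature subset, C) on the full outer training data
   after min-max rescaling to [0, 1] with training statistics;
3. score the held-out outer test fold.

A subject therefore receives exactly one out-of-fold decision score per
outer repeat; its cross-validated prediction is the sign of its mean
out-of-fold score (ties predict the negative class). The ensemble kept
for external cohorts is the set of outer refits, aggregated by mean
decision score; the per-inner-fold models trained with each partition's
winning configuration are retained as the weight records behind the
stability maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cv import (CVPlan, DEFAULT_C_GRID, ScalerState, apply_scaler,
                 build_cv_plan, fit_scaler, greedy_forward_select,
                 inner_splits_for, train_linear_svm)
from .io import FeatureTable
from .metrics import ConfusionSummary, confusion_from_predictions

logger = logging.getLogger(__name__)


@dataclass
class LinearModel:
    """One trained fold-level linear model.

    Weights are zero exactly on unselected features; the decision score of
    a subject is w @ x_rescaled + b and a positive score predicts +1.
    """

    weights: np.ndarray
    bias: float
    mask: np.ndarray
    scaler: ScalerState
    C: float | None
    provenance: tuple  # (repeat, fold) or (repeat, fold, inner_index)

    def decision(self, X_raw: np.ndarray) -> np.ndarray:
        return apply_scaler(self.scaler, X_raw) @ self.weights + self.bias


def _fit_fold_model(X: np.ndarray, y: np.ndarray, selected, C,
                    provenance) -> LinearModel:
    d = X.shape[1]
    scaler = fit_scaler(X)
    weights = np.zeros(d)
    mask = np.zeros(d, bool)
    if len(selected) == 0:
        # empty wrapper selection: constant majority model; the score is the
        # mean training label so the ensemble average stays continuous
        bias = float(np.mean(y))
        logger.info("empty feature selection; constant model (bias %.3f)", bias)
    else:
        Xs = apply_scaler(scaler, X)
        cols = list(selected)
        w, bias = train_linear_svm(Xs[:, cols], y, C)
        weights[cols] = w
        mask[cols] = True
    return LinearModel(weights, bias, mask, scaler, C, provenance)


@dataclass
class WeightRecords:
    """Per-model feature weights and selection masks for stability maps."""

    feature_names: list[str]
    weights: np.ndarray  # (n_models, n_features)
    masks: np.ndarray    # (n_models, n_features) bool
    provenance: list[tuple]


@dataclass
class PredictionResult:
    """Per-subject out-of-fold decision scores (one per outer repeat)."""

    subject_ids: list[str]
    per_repeat_scores: np.ndarray  # (n_subjects, r_outer)
    labels: np.ndarray | None

    @property
    def mean_scores(self) -> np.ndarray:
        return self.per_repeat_scores.mean(axis=1)

    @property
    def predictions(self) -> np.ndarray:
        # tie at exactly zero predicts the negative class (conservative)
        return np.where(self.mean_scores > 0, 1, -1)


@dataclass
class ExternalResult:
    """Ensemble decision on an external cohort."""

    subject_ids: list[str]
    scores: np.ndarray
    predictions: np.ndarray
    specificity: float | None = None


@dataclass
class EnsembleModel:
    """The collection of outer-fold refits with mean-score aggregation."""

    feature_names: list[str]
    members: list[LinearModel]
    aggregation: str = "mean"

    def decision_scores(self, ft: FeatureTable) -> np.ndarray:
        """Mean member decision score per subject, matching features by name."""
        missing = set(self.feature_names) - set(ft.feature_names)
        if missing:
            raise ValueError(
                f"external table lacks {len(missing)} training features, "
                f"e.g. {sorted(missing)[:3]}")
        order = [ft.feature_names.index(f) for f in self.feature_names]
        X = ft.values[:, order]
        scores = np.zeros(ft.n_subjects)
        if self.aggregation == "mean":
            for m in self.members:
                scores += m.decision(X)
            scores /= len(self.members)
        elif self.aggregation == "vote":
            for m in self.members:
                scores += np.where(m.decision(X) > 0, 1.0, -1.0)
            scores /= len(self.members)
        else:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        return scores

    def apply(self, ft: FeatureTable,
              assume_all_negative: bool = False) -> ExternalResult:
        """Apply the ensemble to an external cohort.

        When the cohort is declared all-negative (e.g. an external healthy
        control sample), the reported specificity is the fraction of
        subjects predicted -1.
        """
        scores = self.decision_scores(ft)
        pred = np.where(scores > 0, 1, -1)
        spec = float(np.mean(pred == -1)) if assume_all_negative else None
        return ExternalResult(list(ft.subject_ids), scores, pred, spec)


def run_nested_cv(ft: FeatureTable, plan: CVPlan,
                  c_grid=DEFAULT_C_GRID, eps: float = 1e-6,
                  max_features: int | None = None,
                  keep_inner_models: bool = True):
    """Run the full nested cross-validation.

    Returns ``(ensemble, prediction, confusion, records)``. ``records``
    holds the weight vectors of every model trained with a winning
    configuration across the CV structure (the inner-fold models, plus the
    outer refits when ``keep_inner_models`` is off), feeding the stability
    maps.
    """
    if ft.labels is None:
        raise ValueError("nested CV needs a labeled table")
    X, y = ft.values, ft.labels
    n = ft.n_subjects
    per_repeat = np.full((n, plan.r_outer), np.nan)
    members: list[LinearModel] = []
    rec_w, rec_m, rec_p = [], [], []
    for rep, splits in enumerate(plan.outer_splits):
        seen = np.zeros(n, bool)
        for fold, (tr, te) in enumerate(splits):
            if seen[te].any():
                raise ValueError("outer folds overlap within a repeat")
            seen[te] = True
            inner = inner_splits_for(plan, y[tr], rep, fold)
            sel = greedy_forward_select(X[tr], y[tr], inner, c_grid,
                                        eps=eps, max_features=max_features)
            model = _fit_fold_model(X[tr], y[tr], sel.selected, sel.C,
                                    (rep, fold))
            members.append(model)
            per_repeat[te, rep] = model.decision(X[te])
            if keep_inner_models and sel.selected:
                for i, (itr, _) in enumerate(inner):
                    im = _fit_fold_model(X[tr][itr], y[tr][itr],
                                         sel.selected, sel.C, (rep, fold, i))
                    rec_w.append(im.weights)
                    rec_m.append(im.mask)
                    rec_p.append(im.provenance)
            else:
                rec_w.append(model.weights)
                rec_m.append(model.mask)
                rec_p.append(model.provenance)
        if not seen.all():
            raise ValueError("outer folds do not cover the sample")
    prediction = PredictionResult(list(ft.subject_ids), per_repeat, y.copy())
    confusion = confusion_from_predictions(
        y, prediction.predictions, scores=prediction.mean_scores)
    ensemble = EnsembleModel(list(ft.feature_names), members)
    records = WeightRecords(list(ft.feature_names),
                            np.array(rec_w), np.array(rec_m, bool), rec_p)
    return ensemble, prediction, confusion, records


class NestedCVClassifier:
    """Nested cross-validated linear maximum-margin classifier.

    Parameters
    ----------
    ft : FeatureTable
        Labeled cohort (+1 positive class, -1 negative class).
    k_outer, r_outer, k_inner, r_inner : int
        Folds and repeats of the outer and inner cross-validation cycles.
        The study-scale default is 10 folds x 10 repeats at both levels
        (10,000 inner-winner models); desk-scale analyses typically pass
        smaller values.
    c_grid : sequence of float
        Penalty grid searched in the inner cycle.
    seed : int
        Master seed; fixes fold assignments and hence the whole run.
    max_features : int or None
        Optional cap on the wrapper's subset size.
    """

    def __init__(self, ft: FeatureTable, k_outer: int = 10, r_outer: int = 10,
                 k_inner: int = 10, r_inner: int = 10,
                 c_grid=DEFAULT_C_GRID, seed: int = 0,
                 eps: float = 1e-6, max_features: int | None = None):
        if ft.labels is None:
            raise ValueError("classifier needs a labeled table")
        self.ft = ft
        self.c_grid = tuple(float(c) for c in c_grid)
        self.seed = seed
        self.eps = eps
        self.max_features = max_features
        self.plan = build_cv_plan(ft.labels, k_outer, r_outer,
                                  k_inner, r_inner, seed)

    @classmethod
    def from_dataframe(cls, df, label_column: str = "group", **kwargs):
        return cls(FeatureTable.from_dataframe(df, label_column=label_column),
                   **kwargs)

    def fit(self, keep_inner_models: bool = True) -> "NestedCVResults":
        ensemble, prediction, confusion, records = run_nested_cv(
            self.ft, self.plan, self.c_grid, eps=self.eps,
            max_features=self.max_features,
            keep_inner_models=keep_inner_models)
        return NestedCVResults(self, ensemble, prediction, confusion, records)


@dataclass
class NestedCVResults:
    """Results of a nested cross-validated classification run."""

    model: NestedCVClassifier
    ensemble_: EnsembleModel
    prediction_: PredictionResult
    confusion_: ConfusionSummary
    records_: WeightRecords
    _stability: object = field(default=None, repr=False)

    # -- headline metrics --------------------------------------------------

    @property
    def bac(self) -> float:
        return self.confusion_.bac

    @property
    def auc(self) -> float | None:
        return self.confusion_.auc

    def feature_stability(self, q: float = 0.05):
        """Per-feature CVR, sign-consistency p-values and FDR flags."""
        from .stability import feature_stability
        if self._stability is None:
            self._stability = feature_stability(self.records_, q=q)
        return self._stability

    def permutation_test(self, n_perm: int = 200, seed: int = 0,
                         keep_nulls: bool = True):
        """Label-permutation significance of the cross-validated BAC."""
        from .stability import permutation_test
        return permutation_test(
            self.model.ft, n_perm=n_perm, seed=seed,
            k_outer=self.model.plan.k_outer, r_outer=self.model.plan.r_outer,
            k_inner=self.model.plan.k_inner, r_inner=self.model.plan.r_inner,
            c_grid=self.model.c_grid, eps=self.model.eps,
            max_features=self.model.max_features,
            observed=self.bac, keep_nulls=keep_nulls)

    def apply(self, external: FeatureTable,
              assume_all_negative: bool = False) -> ExternalResult:
        """Apply the retained ensemble to an external cohort."""
        return self.ensemble_.apply(external,
                                    assume_all_negative=assume_all_negative)

    def posthoc_regression(self, covariates, subset: int | None = 1,
                           p_enter: float = 0.05, p_remove: float = 0.10):
        """Stepwise regression of decision scores on covariates."""
        from .stepwise import assemble_posthoc_inputs, stepwise_fit
        y, Xc = assemble_posthoc_inputs(self.prediction_, covariates,
                                        subset=subset)
        return stepwise_fit(y, Xc, p_enter=p_enter, p_remove=p_remove)

    def prevalence_sweep(self, prevalences=None, printed_rounding=False):
        from .metrics import DEFAULT_PREVALENCES, prevalence_sweep
        return prevalence_sweep(
            self.confusion_.sens, self.confusion_.spec,
            prevalences if prevalences is not None else DEFAULT_PREVALENCES,
            printed_rounding=printed_rounding)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        c = self.confusion_
        plan = self.model.plan
        counts = self.model.ft.class_counts()
        lines = [
            "Nested cross-validated linear SVM classification",
            "=" * 48,
            f"Subjects:        {self.model.ft.n_subjects} "
            f"({counts[1]} positive / {counts[-1]} negative)",
            f"Features:        {self.model.ft.n_features}",
            f"Outer CV:        {plan.k_outer} folds x {plan.r_outer} repeats",
            f"Inner CV:        {plan.k_inner} folds x {plan.r_inner} repeats",
            f"C grid:          {len(self.model.c_grid)} values "
            f"[{min(self.model.c_grid):g} ... {max(self.model.c_grid):g}]",
            f"Ensemble:        {len(self.ensemble_.members)} outer models, "
            f"{self.records_.weights.shape[0]} weight records",
            "-" * 48,
            f"TP {c.tp}  TN {c.tn}  FP {c.fp}  FN {c.fn}",
            f"Sensitivity:     {100 * c.sens:.1f}%",
            f"Specificity:     {100 * c.spec:.1f}%",
            f"Balanced acc.:   {100 * c.bac:.1f}%",
            f"PPV / NPV:       {_pct(c.ppv)} / {_pct(c.npv)}",
            f"AUC:             {c.auc:.2f}" if c.auc is not None else "AUC: n/a",
            f"NND:             {c.nnd:.2f}",
            f"PSI / NNP:       {c.psi:.3f} / {c.nnp:.2f}",
        ]
        sel_counts = self.records_.masks.sum(axis=0)
        used = np.flatnonzero(sel_counts)
        top = used[np.argsort(sel_counts[used])[::-1][:5]]
        lines.append("-" * 48)
        lines.append("Most frequently selected features:")
        for j in top:
            lines.append(f"  {self.records_.feature_names[j]:<28s} "
                         f"in {sel_counts[j]}/{self.records_.weights.shape[0]} models")
        return "\n".join(lines)

    def plot_stability(self, ax=None, top: int = 25):
        """Horizontal bar chart of the per-feature cross-validation ratios."""
        import matplotlib.pyplot as plt

        stab = self.feature_stability()
        sub = stab.dropna(subset=["cvr"]).copy()
        sub = sub.reindex(sub["cvr"].abs().sort_values(ascending=False).index)
        sub = sub.head(top).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.3 * max(len(sub), 5) + 1))
        colors = ["#c0392b" if v > 0 else "#2980b9" for v in sub["cvr"]]
        ax.barh(sub.index, sub["cvr"], color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("cross-validation ratio (mean weight / SE)")
        ax.set_title("Feature stability (red: positive class, blue: negative)")
        return ax


def _pct(x: float | None) -> str:
    return "n/a" if x is None else f"{100 * x:.1f}%"
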