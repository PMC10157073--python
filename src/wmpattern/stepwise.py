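"""Stepwise linear regression of model decision scores on covariates.

Forward-backward stepping on partial-F (equivalently squared-t) p-values,
in the style of the classical stepwise-regression routines: starting from
the intercept-only model, the candidate with the smallest entry p-value
below ``p_enter`` (default 0.05) is added, then any included term whose
p-value rose above ``p_remove`` (default 0.10) is dropped, until the
model is stable. The final term set is refit by ordinary least squares
(statsmodels) and reported with estimates, standard errors, t statistics,
two-sided p-values and 95% confidence intervals.

This is the post-hoc stage of the pipeline: the response is the
per-subject repeat-averaged out-of-fold decision score, the candidates
are the sociodemographic/forensic covariates of the positive-class
subjects, on their raw scales (no standardization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class StepwiseFit:
    """Final stepwise model: coefficient table, fit statistics, step trace."""

    params: pd.DataFrame            # rows: Intercept + included terms
    included: list[str]
    rsquared: float
    rsquared_adj: float
    fvalue: float | None
    f_pvalue: float | None
    df_resid: float
    nobs: int
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    results: object = field(default=None, repr=False)  # statsmodels results

    def summary(self) -> str:
        lines = [
            "Stepwise linear regression",
            "=" * 70,
            f"n = {self.nobs}   R^2 = {self.rsquared:.3f}   "
            f"adj. R^2 = {self.rsquared_adj:.3f}   df_resid = {self.df_resid:g}",
        ]
        if self.fvalue is not None:
            lines.append(f"F = {self.fvalue:.2f}   P = {self.f_pvalue:.3g}")
        lines.append("-" * 70)
        lines.append(self.params.to_string(float_format=lambda v: f"{v: .4g}"))
        if self.trace:
            lines.append("-" * 70)
            lines.append("Steps: " + "; ".join(
                f"{action} {term} (p={p:.3g})" for term, action, p in self.trace))
        return "\n".join(lines)


def _ols(y: np.ndarray, X: pd.DataFrame, terms: list[str]):
    design = sm.add_constant(X[terms], has_constant="add") if terms \
        else pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
    return sm.OLS(y, design).fit()


def _entry_pvalue(y, X, terms, candidate) -> float | None:
    """p-value of the candidate term when added to the current model.

    Returns None when the augmented design is rank deficient (the term is
    collinear with the current model and is skipped with a warning).
    """
    trial = terms + [candidate]
    res = _ols(y, X, trial)
    if res.df_resid <= 0 or np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        logger.warning("term %r skipped: rank-deficient design", candidate)
        return None
    return float(res.pvalues[candidate])


def stepwise_fit(y, candidates: pd.DataFrame, p_enter: float = 0.05,
                 p_remove: float = 0.10, max_iter: int = 200) -> StepwiseFit:
    """Forward-backward stepwise OLS on F-test p-values.

    ``y`` is the response (aligned to ``candidates``' index); entry and
    removal use the partial-F p-value of each term given the current
    model. Requires ``p_enter < p_remove`` (otherwise terms could cycle).
    """
    if not p_enter < p_remove:
        raise ValueError("p_enter must be smaller than p_remove")
    X = candidates.copy()
    y = np.asarray(y, float)
    if len(y) != len(X):
        raise ValueError("response and candidate table lengths differ")
    if len(y) <= 2:
        raise ValueError("need more than 2 observations")
    if X.shape[1] == 0:
        raise ValueError("empty candidate table")
    if X.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("candidates and response must be complete "
                         "(listwise-delete before fitting)")

    included: list[str] = []
    trace: list[tuple[str, str, float]] = []
    for _ in range(max_iter):
        changed = False
        # forward step: best candidate below the entry threshold
        best_term, best_p = None, np.inf
        for cand in X.columns:
            if cand in included or len(included) + 2 >= len(y):
                continue
            p = _entry_pvalue(y, X, included, cand)
            if p is not None and p < best_p:
                best_term, best_p = cand, p
        if best_term is not None and best_p < p_enter:
            included.append(best_term)
            trace.append((best_term, "add", best_p))
            changed = True
        # backward step: drop anything above the removal threshold
        while included:
            res = _ols(y, X, included)
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                trace.append((worst, "remove", float(pvals[worst])))
                changed = True
            else:
                break
        if not changed:
            break
    else:
        logger.warning("stepwise selection hit max_iter=%d", max_iter)

    res = _ols(y, X, included)
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["ci_low", "ci_high"]
    params = pd.DataFrame({
        "estimate": res.params, "se": res.bse,
        "t": res.tvalues, "p": res.pvalues,
    }).join(ci)
    params.index = ["Intercept" if i == "const" else i for i in params.index]
    fvalue = float(res.fvalue) if included else None
    f_pvalue = float(res.f_pvalue) if included else None
    rsq = float(res.rsquared) if included else 0.0
    rsq_adj = float(res.rsquared_adj) if included else 0.0
    return StepwiseFit(params, included, rsq, rsq_adj, fvalue, f_pvalue,
                       float(res.df_resid), int(res.nobs), trace, res)


def assemble_posthoc_inputs(prediction, covariates, subset: int | None = 1
                            ) -> tuple[pd.Series, pd.DataFrame]:
    """Regression-ready (response, design) from predictions and covariates.

    The response is each subject's repeat-averaged out-of-fold decision
    score; the candidates are all covariate columns on their raw scales.
    ``subset`` restricts to one labeled class (default +1, the group for
    which forensic covariates exist); ``None`` keeps everyone. Subjects
    with any missing covariate are listwise-deleted with a logged id.
    """
    data = covariates.data if hasattr(covariates, "data") else covariates
    if data.shape[1] == 0:
        raise ValueError("empty covariate table")
    ids = np.asarray(prediction.subject_ids)
    scores = prediction.mean_scores
    keep = np.ones(len(ids), bool)
    if subset is not None:
        if prediction.labels is None:
            raise ValueError("cannot subset by class: predictions unlabeled")
        keep &= prediction.labels == subset
    resp = pd.Series(scores[keep], index=pd.Index(ids[keep], name="subject_id"),
                     name="decision_score")
    resp = resp[resp.index.isin(data.index)]
    X = data.loc[resp.index]
    complete = X.notna().all(axis=1)
    dropped = list(X.index[~complete])
    if dropped:
        logger.info("listwise-deleted %d subjects with missing covariates: %s",
                    len(dropped), dropped[:5])
    X = X[complete]
    resp = resp[complete]
    if len(resp) == 0:
        raise ValueError("no usable subjects after alignment")
    return resp, X
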