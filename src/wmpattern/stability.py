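"""Permutation significance and feature-stability interpretation.

Two complementary views of what the classifier learned:

* the **cross-validation ratio** (CVR) of a feature is its mean weight
  across all models in which the wrapper selected it, divided by the
  standard error of that mean (SD / sqrt(m)) — a Z-score-like stability
  index in the spirit of the bootstrap ratio from the partial-least-
  squares literature; and
* **sign-based consistency**: an exact two-sided binomial test of whether
  a feature's weight received the same sign across models more often than
  the 50% expected by chance, with Benjamini-Hochberg FDR control across
  the evaluated features.

Model-level significance uses a label-permutation test: the whole nested
cross-validation pipeline — wrapper selection included — is rerun on
uniformly permuted labels, and the observed balanced accuracy is compared
against the null distribution with the add-one-corrected p-value
p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cv import DEFAULT_C_GRID, build_cv_plan
from .io import FeatureTable
from .simulate import generate_null_labels

logger = logging.getLogger(__name__)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values).

    NaN entries (features never evaluated) stay NaN and do not count
    toward the family size.
    """
    p = np.asarray(p_values, float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.shape, bool)
    adj = np.full(p.shape, np.nan)
    if valid.any():
        rej, p_adj, *_ = multipletests(p[valid], alpha=q, method="fdr_bh")
        flags[valid] = rej
        adj[valid] = p_adj
    return flags, adj


def compute_cvr(records) -> pd.DataFrame:
    """Per-feature selection count, mean weight, SD and CVR.

    Statistics run over the models in which the wrapper selected the
    feature (a zero-weight feature does not influence the decision score
    and is excluded). CVR = mean / (SD / sqrt(m)) with the sample SD; a
    zero SD yields a signed infinity sentinel, and features selected in
    fewer than one model report absent statistics.
    """
    W, M = records.weights, records.masks
    if W.shape[0] < 2:
        raise ValueError("need at least 2 models for stability statistics")
    rows = []
    for j, name in enumerate(records.feature_names):
        sel = M[:, j]
        m = int(sel.sum())
        if m == 0:
            rows.append({"feature": name, "m": 0, "mean_w": np.nan,
                         "sd_w": np.nan, "cvr": np.nan})
            continue
        w = W[sel, j]
        mean = float(w.mean())
        sd = float(w.std(ddof=1)) if m > 1 else 0.0
        if sd == 0.0:
            cvr = np.sign(mean) * np.inf if mean != 0 else 0.0
            if m > 1:
                logger.warning("feature %r has zero weight variance; "
                               "CVR reported as signed infinity", name)
        else:
            cvr = mean / (sd / np.sqrt(m))
        rows.append({"feature": name, "m": m, "mean_w": mean,
                     "sd_w": sd, "cvr": cvr})
    return pd.DataFrame(rows).set_index("feature")


def sign_consistency(records, q: float = 0.05) -> pd.DataFrame:
    """Exact two-sided binomial test of weight-sign consistency per feature.

    For each feature, the positive and negative signs it received across
    the models that selected it are tested against the chance rate 0.5;
    the resulting p-values are BH-FDR flagged at threshold ``q`` across
    all evaluated features.
    """
    W, M = records.weights, records.masks
    rows = []
    for j, name in enumerate(records.feature_names):
        sel = M[:, j]
        w = W[sel, j]
        n_pos = int((w > 0).sum())
        n_neg = int((w < 0).sum())
        n_eff = n_pos + n_neg
        if n_eff == 0:
            rows.append({"feature": name, "n_pos_sign": 0, "n_neg_sign": 0,
                         "p_sign": np.nan})
            continue
        p = stats.binomtest(n_pos, n_eff, 0.5).pvalue
        rows.append({"feature": name, "n_pos_sign": n_pos,
                     "n_neg_sign": n_neg, "p_sign": float(p)})
    df = pd.DataFrame(rows).set_index("feature")
    flags, adj = bh_fdr(df["p_sign"].to_numpy(), q=q)
    df["p_adj"] = adj
    df["significant"] = flags
    return df


def feature_stability(records, q: float = 0.05) -> pd.DataFrame:
    """Combined stability table: CVR statistics plus sign-consistency."""
    return compute_cvr(records).join(sign_consistency(records, q=q))


@dataclass
class PermutationResult:
    """Observed BAC versus the label-permutation null distribution."""

    observed_bac: float
    null_bacs: np.ndarray | None
    n_perm: int
    n_ge: int

    @property
    def p_value(self) -> float:
        return (1 + self.n_ge) / (1 + self.n_perm)


def permutation_test(ft: FeatureTable, n_perm: int = 200, seed: int = 0,
                     k_outer: int = 10, r_outer: int = 10,
                     k_inner: int = 10, r_inner: int = 10,
                     c_grid=DEFAULT_C_GRID, eps: float = 1e-6,
                     max_features: int | None = None,
                     observed: float | None = None,
                     keep_nulls: bool = True) -> PermutationResult:
    """Label-permutation test of the cross-validated balanced accuracy.

    Every permutation reruns the complete nested pipeline — fold
    assignment, wrapper selection, hyperparameter search — on labels
    permuted uniformly at random (class counts preserved). ``observed``
    may carry the BAC of an already-completed unpermuted run; otherwise it
    is computed first. The default ``n_perm`` is desk-scale; study-scale
    analyses pass 5000.
    """
    from .model import run_nested_cv  # local import breaks the cycle

    if ft.labels is None:
        raise ValueError("permutation test needs a labeled table")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ss = np.random.SeedSequence(seed)
    plan_seed, perm_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                            for s in ss.spawn(2))

    def _bac_for(table: FeatureTable) -> float:
        plan = build_cv_plan(table.labels, k_outer, r_outer,
                             k_inner, r_inner, plan_seed)
        _, _, confusion, _ = run_nested_cv(
            table, plan, c_grid, eps=eps, max_features=max_features,
            keep_inner_models=False)
        return confusion.bac

    if observed is None:
        observed = _bac_for(ft)
    null = np.empty(n_perm)
    for i in range(n_perm):
        permuted = generate_null_labels(ft, seed=perm_seed + i)
        null[i] = _bac_for(permuted)
    n_ge = int(np.sum(null >= observed))
    return PermutationResult(observed, null if keep_nulls else None,
                             n_perm, n_ge)
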