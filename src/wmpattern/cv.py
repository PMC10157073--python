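"""Cross-validation plans, fold-wise rescaling, linear SVM fits and the
greedy forward wrapper.

All rescaling and feature selection is refit strictly inside each training
partition — the test side of a fold never influences the scaler, the
hyperparameter search, or the selected feature subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from ._svm import fit_linear_svm

logger = logging.getLogger(__name__)

#: default regularization grid: 2^-6 ... 2^4 (11 values)
DEFAULT_C_GRID = tuple(float(2.0 ** k) for k in range(-6, 5))


# -- fold plans ------------------------------------------------------------

@dataclass
class CVPlan:
    """Stratified repeated k-fold assignments for the outer cycle, plus the
    parameters of the inner cycle (whose splits are drawn per outer
    training partition)."""

    k_outer: int
    r_outer: int
    k_inner: int
    r_inner: int
    seed: int
    outer_splits: list[list[tuple[np.ndarray, np.ndarray]]] = field(repr=False)

    @property
    def n_outer_partitions(self) -> int:
        return self.r_outer * self.k_outer


def _repeated_stratified_splits(labels: np.ndarray, k: int, r: int,
                                seed_seq: np.random.SeedSequence,
                                level: str) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    n = labels.size
    counts = [int(np.sum(labels == c)) for c in (1, -1)]
    if min(counts) == 0:
        raise ValueError("both classes must be present")
    if k > n:
        raise ValueError(f"{level}: {k} folds exceed {n} subjects")
    states = seed_seq.generate_state(r)
    splits: list[list[tuple[np.ndarray, np.ndarray]]] = []
    if k == n:
        logger.warning("%s: leave-one-out requested; stratification waived", level)
        for rep in range(r):
            rng = np.random.default_rng(states[rep])
            order = rng.permutation(n)
            kf = KFold(n_splits=k)
            splits.append([(order[tr], order[te]) for tr, te in kf.split(np.empty(n))])
        return splits
    if k > min(counts):
        raise ValueError(
            f"{level}: {k} folds infeasible with minority class of "
            f"{min(counts)}; choose k <= {min(counts)}"
        )
    for rep in range(r):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(states[rep] % (2 ** 32 - 1)))
        splits.append([(tr, te) for tr, te in skf.split(np.empty(n), labels)])
    return splits


def build_cv_plan(labels, k_outer: int = 10, r_outer: int = 10,
                  k_inner: int = 10, r_inner: int = 10,
                  seed: int = 0) -> CVPlan:
    """Stratified repeated outer folds, deterministic given the seed.

    Every outer test fold contains at least one subject of each class
    (guaranteed by stratification whenever ``k_outer`` is at most the
    minority-class count); requesting leave-one-out (``k_outer == n``)
    waives stratification with a warning.
    """
    labels = np.asarray(labels, int)
    ss = np.random.SeedSequence(seed)
    outer_ss, _ = ss.spawn(2)
    outer = _repeated_stratified_splits(labels, k_outer, r_outer, outer_ss, "outer")
    return CVPlan(k_outer, r_outer, k_inner, r_inner, seed, outer)


def inner_splits_for(plan: CVPlan, train_labels: np.ndarray,
                     repeat: int, fold: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Inner-cycle splits for one outer training partition.

    Seeded deterministically from the plan seed and the (repeat, fold)
    coordinates, so identical plans reproduce identical inner cycles.
    """
    ss = np.random.SeedSequence(
        entropy=plan.seed, spawn_key=(1, repeat, fold))
    reps = _repeated_stratified_splits(train_labels, plan.k_inner,
                                       plan.r_inner, ss, "inner")
    return [split for rep in reps for split in rep]


# -- fold-wise min-max rescaling -------------------------------------------

@dataclass(frozen=True)
class ScalerState:
    """Per-feature training minima/maxima for [0, 1] rescaling."""

    min_: np.ndarray
    max_: np.ndarray


def fit_scaler(train_matrix: np.ndarray) -> ScalerState:
    X = np.asarray(train_matrix, float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    return ScalerState(X.min(axis=0), X.max(axis=0))


def apply_scaler(state: ScalerState, matrix: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) with out-of-range values clipped to [0, 1].

    Features constant in training map to 0.5 regardless of input value.
    """
    X = np.asarray(matrix, float)
    rng = state.max_ - state.min_
    constant = rng == 0
    if constant.any():
        logger.warning("%d constant training feature(s) mapped to 0.5",
                       int(constant.sum()))
    safe = np.where(constant, 1.0, rng)
    out = np.clip((X - state.min_) / safe, 0.0, 1.0)
    out[:, constant] = 0.5
    return out


# -- linear max-margin model -----------------------------------------------

def train_linear_svm(X_scaled: np.ndarray, y: np.ndarray,
                     C: float) -> tuple[np.ndarray, float]:
    """Maximum-margin linear classifier (hinge loss, penalty C).

    Returns (weights, bias); decision score = w @ x + b, positive score
    predicts +1. Deterministic for fixed input.
    """
    return fit_linear_svm(X_scaled, np.asarray(y, float), C)


def _bac_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    sens = np.mean(y_pred[pos] == 1) if pos.any() else 0.0
    spec = np.mean(y_pred[neg] == -1) if neg.any() else 0.0
    return 0.5 * (float(sens) + float(spec))


# -- greedy forward wrapper selection --------------------------------------

@dataclass
class SelectionResult:
    """Winning feature subset and hyperparameter from the inner cycle."""

    selected: tuple[int, ...]
    C: float | None
    bac: float
    trace: list[tuple[int, float, float]]  # (feature, C, inner BAC) per step


def _prescale_splits(X: np.ndarray, y: np.ndarray, splits):
    """Scale the full feature set once per inner split (training stats only)."""
    pre = []
    for tr, va in splits:
        state = fit_scaler(X[tr])
        pre.append((apply_scaler(state, X[tr]), y[tr],
                    apply_scaler(state, X[va]), y[va]))
    return pre


def _mean_inner_bac(pre, cols: list[int], C: float) -> float:
    total = 0.0
    for Xtr, ytr, Xva, yva in pre:
        w, b = fit_linear_svm(Xtr[:, cols], ytr, C)
        scores = Xva[:, cols] @ w + b
        pred = np.where(scores > 0, 1, -1)
        total += _bac_from_predictions(yva, pred)
    return total / len(pre)


def greedy_forward_select(X: np.ndarray, y: np.ndarray, splits,
                          c_grid=DEFAULT_C_GRID, eps: float = 1e-6,
                          max_features: int | None = None) -> SelectionResult:
    """Greedy forward wrapper selection scored by mean inner-validation BAC.

    Starts from the empty set (baseline BAC 0.5, chance level) and at each
    step adds the candidate feature — jointly with the best penalty C from
    the grid — that maximizes the mean balanced accuracy over the inner
    validation folds; stops when no candidate improves the running best by
    more than ``eps`` or all features are included. Ties are broken toward
    the lower feature index, then the lower C (candidates are scanned in
    that order and only strict improvements replace the incumbent).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    d = X.shape[1]
    if d == 0:
        raise ValueError("need at least one feature")
    pre = _prescale_splits(X, y, splits)
    selected: list[int] = []
    best_bac = 0.5
    winning_c: float | None = None
    trace: list[tuple[int, float, float]] = []
    limit = d if max_features is None else min(max_features, d)
    while len(selected) < limit:
        step_best = (best_bac, None, None)  # (bac, feature, C)
        for f in range(d):
            if f in selected:
                continue
            cols = selected + [f]
            for C in c_grid:
                bac = _mean_inner_bac(pre, cols, C)
                if bac > step_best[0] + eps:
                    step_best = (bac, f, C)
        if step_best[1] is None:
            break
        best_bac, f, winning_c = step_best
        selected.append(f)
        trace.append((f, winning_c, best_bac))
    return SelectionResult(tuple(selected), winning_c, best_bac, trace)
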