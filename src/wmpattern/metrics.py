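"""Confusion-matrix and prevalence-adjusted diagnostic metrics.

Beyond the usual sensitivity/specificity/predictive values this module
implements the prevalence-aware summary indices used to judge a binary
diagnostic model in populations whose base rate differs from the study
sample:

* NND (number needed to diagnose) = 1 / Youden = 1 / (sens + spec - 1)
* PSI (predictive summary index)  = PPV + NPV - 1
* NNP (number needed to predict)  = 1 / PSI

PPV and NPV at an assumed prevalence pi follow Bayes' rule

    PPV(pi) = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
    NPV(pi) = spec * (1 - pi) / (spec * (1 - pi) + (1 - sens) * pi)

so PSI and NNP become functions of prevalence; :func:`prevalence_sweep`
tabulates them over a grid of assumed base rates.

Undefined ratios (0/0 denominators) are reported as ``None`` ("absent"),
and non-positive Youden/PSI yield ``inf`` for the corresponding "number
needed", never an exception, so ensemble sweeps cannot abort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: prevalence grid used in the study-style sweep (1% ... 70%)
DEFAULT_PREVALENCES = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (display convention for printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def _inverse(x: float | None) -> float | None:
    """1/x for positive x, +inf for x <= 0, absent for absent."""
    if x is None:
        return None
    if x <= 0:
        logger.info("non-positive index %g; reporting inf", x)
        return float("inf")
    return 1.0 / x


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts (+1 = positive class) with derived metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None = None

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion matrix")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         scores=None) -> "ConfusionSummary":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        if y_true.size == 0:
            raise ValueError("empty input")
        if y_true.shape != y_pred.shape:
            raise ValueError("length mismatch")
        for arr in (y_true, y_pred):
            if not np.isin(arr, (-1, 1)).all():
                raise ValueError("labels must be in {+1, -1}")
        auc = None
        if scores is not None and len(np.unique(y_true)) == 2:
            auc = auc_from_scores(y_true, scores)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            auc=auc,
        )

    # -- derived metrics ---------------------------------------------------

    @property
    def sens(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def spec(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def bac(self) -> float | None:
        if self.sens is None or self.spec is None:
            return None
        return 0.5 * (self.sens + self.spec)

    @property
    def ppv(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def youden(self) -> float | None:
        if self.sens is None or self.spec is None:
            return None
        return self.sens + self.spec - 1.0

    @property
    def nnd(self) -> float | None:
        return _inverse(self.youden)

    @property
    def psi(self) -> float | None:
        if self.ppv is None or self.npv is None:
            return None
        return self.ppv + self.npv - 1.0

    @property
    def nnp(self) -> float | None:
        return _inverse(self.psi)

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / (self.tp + self.tn + self.fp + self.fn)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sens": self.sens, "spec": self.spec, "bac": self.bac,
            "ppv": self.ppv, "npv": self.npv, "nnd": self.nnd,
            "psi": self.psi, "auc": self.auc,
        }


def confusion_from_predictions(y_true, y_pred, scores=None) -> ConfusionSummary:
    """Confusion summary from ±1 label vectors (+1 is the positive class)."""
    return ConfusionSummary.from_predictions(y_true, y_pred, scores=scores)


def auc_from_scores(y_true, scores) -> float:
    """Rank-based AUC (Mann-Whitney statistic / (n+ * n-)); ties count 1/2."""
    y_true = np.asarray(y_true, int)
    scores = np.asarray(scores, float)
    pos = scores[y_true == 1]
    neg = scores[y_true == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u1 = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u1 / (pos.size * neg.size))


@dataclass(frozen=True)
class PrevalenceRow:
    """Predictive values at one assumed prevalence."""

    prevalence: float
    ppv: float | None
    npv: float | None
    psi: float | None
    nnp: float | None


def predictive_values_at_prevalence(sens: float, spec: float,
                                    prevalence: float) -> PrevalenceRow:
    """Bayes-adjusted PPV/NPV/PSI/NNP at one assumed prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly between 0 and 1")
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    pi = prevalence
    ppv = _ratio(sens * pi, sens * pi + (1 - spec) * (1 - pi))
    npv = _ratio(spec * (1 - pi), spec * (1 - pi) + (1 - sens) * pi)
    psi = None if (ppv is None or npv is None) else ppv + npv - 1.0
    return PrevalenceRow(pi, ppv, npv, psi, _inverse(psi))


def prevalence_sweep(sens: float, spec: float,
                     prevalences=DEFAULT_PREVALENCES,
                     printed_rounding: bool = False) -> list[PrevalenceRow]:
    """Sweep predictive values over assumed prevalence rates.

    With ``printed_rounding=True`` sensitivity and specificity are first
    rounded half-up to one decimal when expressed as percentages (64.3%,
    86.7%, ...) before entering Bayes' rule — the convention under which
    the published sweep tables are reproduced digit-for-digit. The default
    keeps full precision.
    """
    if printed_rounding:
        sens = round_half_up(100 * sens, 1) / 100
        spec = round_half_up(100 * spec, 1) / 100
    return [predictive_values_at_prevalence(sens, spec, pi) for pi in prevalences]


def sweep_table(rows: list[PrevalenceRow], printed_style: bool = False):
    """Sweep as a DataFrame (column order: Prevalence, PPV, NPV, PSI, NNP).

    ``printed_style`` applies the display rounding used in the published
    table: whole percentages for prevalence/PPV/NPV/PSI, two decimals for
    NNP.
    """
    import pandas as pd

    if printed_style:
        data = [{
            "Prevalence (%)": round_half_up(100 * r.prevalence),
            "PPV (%)": round_half_up(100 * r.ppv),
            "NPV (%)": round_half_up(100 * r.npv),
            "PSI (%)": round_half_up(100 * r.psi),
            "NNP": round_half_up(r.nnp, 2),
        } for r in rows]
    else:
        data = [{
            "Prevalence": r.prevalence, "PPV": r.ppv, "NPV": r.npv,
            "PSI": r.psi, "NNP": r.nnp,
        } for r in rows]
    return pd.DataFrame(data)
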