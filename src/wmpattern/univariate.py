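"""Univariate group comparisons: Mann-Whitney U, 2x2 chi-square, FDR family.

These are the classical per-variable group tests run alongside the
multivariate model: a non-parametric rank test for continuous variables, a
Pearson chi-square (no continuity correction) for 2x2 frequency tables,
and Benjamini-Hochberg FDR correction over an explicitly declared family
of tests. The per-feature screen of the whole feature table is the
standard demonstration that a multivariate signal need not be visible to
any single-feature test at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable
from .stability import bh_fdr

#: exact Mann-Whitney p-values when n1*n2 is at most this and there are no ties
EXACT_U_LIMIT = 400


@dataclass
class GroupTestResult:
    """One univariate comparison (U test or chi-square)."""

    name: str
    kind: str  # "U" | "chi2"
    statistic: float
    p: float
    p_adj: float | None = None
    group_summaries: dict = field(default_factory=dict)


def mann_whitney_u(x, y, name: str = "") -> GroupTestResult:
    """Two-sided Mann-Whitney U test; U reported for the first group.

    U1 = sum of first-group ranks - n1(n1+1)/2. Exact p-value for
    n1*n2 <= 400 without ties, normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_U_LIMIT and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult(
        name, "U", float(res.statistic), float(res.pvalue),
        group_summaries={
            "mean_1": float(x.mean()), "sd_1": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "mean_2": float(y.mean()), "sd_2": float(y.std(ddof=1)) if y.size > 1 else 0.0,
        })


def chi_square_2x2(table, name: str = "") -> GroupTestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative count")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return GroupTestResult(name, "chi2", float(chi2), float(p),
                           group_summaries={"counts": t.astype(int).tolist()})


def apply_fdr(results: list[GroupTestResult],
              q: float = 0.05) -> list[GroupTestResult]:
    """BH-FDR adjust an explicit family of test results (in place)."""
    flags, adj = bh_fdr([r.p for r in results], q=q)
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def group_screen(ft: FeatureTable, q: float = 0.05) -> pd.DataFrame:
    """Per-feature U tests (positive vs negative class) with BH-FDR.

    The FDR family is the full feature set of the table. Returns a frame
    indexed by feature with U, raw and adjusted p, and the rejection flag;
    the number of significant features is ``df["significant"].sum()``.
    """
    if ft.labels is None:
        raise ValueError("group screen needs a labeled table")
    pos = ft.values[ft.labels == 1]
    neg = ft.values[ft.labels == -1]
    results = [mann_whitney_u(pos[:, j], neg[:, j], name=fname)
               for j, fname in enumerate(ft.feature_names)]
    apply_fdr(results, q=q)
    flags, _ = bh_fdr([r.p for r in results], q=q)
    return pd.DataFrame({
        "U": [r.statistic for r in results],
        "p": [r.p for r in results],
        "p_adj": [r.p_adj for r in results],
        "significant": flags,
    }, index=pd.Index(ft.feature_names, name="feature"))
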