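"""Reading, writing and validation of cohort tables.

The canonical in-memory containers are :class:`FeatureTable` (subject x
feature matrix with optional ±1 group labels) and :class:`CovariateTable`
(per-subject numeric covariates, missingness allowed). Group labels follow
the convention positive class = +1 (the clinical group of interest),
negative class = -1 (healthy controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import canonical_feature_names

logger = logging.getLogger(__name__)

#: fixed token -> label dictionary; mapping an already-mapped label is a no-op
LABEL_MAP = {
    "PO": 1, "1": 1, "+1": 1,
    "HC": -1, "-1": -1, "0": -1,
}


def map_label(token) -> int:
    """Map a label token to {+1, -1} using the fixed dictionary.

    Accepts the integers ±1 unchanged (so mapping twice equals mapping
    once) and raises on anything else.
    """
    if isinstance(token, (int, np.integer)) and int(token) in (1, -1):
        return int(token)
    key = str(token).strip()
    # integers arriving as floats ("1.0") or ints via pandas
    if key.endswith(".0"):
        key = key[:-2]
    if key not in LABEL_MAP:
        raise ValueError(
            f"unknown group label token {token!r}; expected one of {sorted(LABEL_MAP)}"
        )
    return LABEL_MAP[key]


@dataclass
class FeatureTable:
    """A validated subject x feature matrix with optional ±1 labels."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, d = self.values.shape
        if n == 0 or d == 0:
            raise ValueError("empty feature table")
        if len(self.subject_ids) != n:
            raise ValueError("subject id count does not match matrix rows")
        if len(self.feature_names) != d:
            raise ValueError("feature name count does not match matrix columns")
        dup = _first_duplicate(self.subject_ids)
        if dup is not None:
            raise ValueError(f"duplicated subject id: {dup!r}")
        dup = _first_duplicate(self.feature_names)
        if dup is not None:
            raise ValueError(f"duplicated feature name: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing or non-finite feature value for subject "
                f"{self.subject_ids[i]!r}, feature {self.feature_names[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray([map_label(t) for t in self.labels], dtype=int)
            if len(self.labels) != n:
                raise ValueError("label count does not match matrix rows")
            counts = {c: int(np.sum(self.labels == c)) for c in (1, -1)}
            # two-group tables need >= 2 per class; single-group views
            # (e.g. the positive-class slice fed to the post-hoc stage)
            # are allowed and rejected later by the classifier itself
            if all(v > 0 for v in counts.values()) and min(counts.values()) < 2:
                cls = min(counts, key=counts.get)
                raise ValueError(f"fewer than 2 subjects in class {cls:+d}")
        if set(self.feature_names) - set(canonical_feature_names()):
            logger.warning(
                "feature table contains non-canonical feature names; "
                "proceeding generically"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[int, int]:
        if self.labels is None:
            raise ValueError("table has no labels")
        return {c: int(np.sum(self.labels == c)) for c in (1, -1)}

    def with_labels(self, labels) -> "FeatureTable":
        return FeatureTable(
            list(self.subject_ids), list(self.feature_names),
            self.values.copy(), np.asarray(labels),
        )

    def to_dataframe(self, label_column: str | None = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names,
                          index=pd.Index(self.subject_ids, name="subject_id"))
        if self.labels is not None and label_column:
            df.insert(0, label_column, self.labels)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       label_column: str | None = None) -> "FeatureTable":
        """Build from a DataFrame indexed by subject id."""
        labels = None
        if label_column is not None:
            if label_column not in df.columns:
                raise ValueError(f"label column {label_column!r} not found")
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
        feats = df.apply(pd.to_numeric, errors="coerce")
        if feats.isna().any().any() and not df.isna().any().any():
            col = feats.columns[feats.isna().any()][0]
            raise ValueError(f"non-numeric feature cell in column {col!r}")
        return cls(list(df.index.astype(str)), list(df.columns),
                   feats.to_numpy(dtype=float), labels)


@dataclass
class CovariateTable:
    """Per-subject numeric covariates; missing values allowed but flagged."""

    data: pd.DataFrame  # indexed by subject id

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        dup = _first_duplicate(list(self.data.index))
        if dup is not None:
            raise ValueError(f"duplicated subject id: {dup!r}")
        self.data = self.data.apply(pd.to_numeric, errors="raise")
        miss = self.data.isna().sum()
        for col, n in miss[miss > 0].items():
            logger.warning("covariate %r has %d missing values", col, int(n))

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def missing_counts(self) -> pd.Series:
        return self.data.isna().sum()


@dataclass
class AlignedCohort:
    """Row-aligned view of a feature table and its covariates."""

    feature_table: FeatureTable
    covariates: pd.DataFrame
    dropped_subjects: list[str] = field(default_factory=list)


# -- delimited text I/O ----------------------------------------------------

def _detect_delimiter(path, delimiter: str) -> str:
    if delimiter in (",", "tab", "\t", "comma"):
        return {"comma": ",", "tab": "\t"}.get(delimiter, delimiter)
    if delimiter != "auto":
        raise ValueError(f"unsupported delimiter {delimiter!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_feature_table(path, label_column: str | None = None,
                       delimiter: str = "auto") -> FeatureTable:
    """Read a delimited subject x feature table.

    The first column is the subject id; ``label_column`` (if given) is
    mapped to ±1 via the fixed token dictionary.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    return FeatureTable.from_dataframe(df, label_column=label_column)


def write_feature_table(ft: FeatureTable, path, delimiter: str = ",",
                        label_column: str = "group") -> None:
    """Write a table at full float precision so it round-trips bit-identically."""
    sep = {"comma": ",", "tab": "\t"}.get(delimiter, delimiter)
    # default float repr is shortest-round-trip, so values survive exactly
    ft.to_dataframe(label_column).to_csv(path, sep=sep)


def read_covariates(path, delimiter: str = "auto") -> CovariateTable:
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"empty covariate table: {path}")
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path, delimiter: str = ",") -> None:
    sep = {"comma": ",", "tab": "\t"}.get(delimiter, delimiter)
    cov.data.to_csv(path, sep=sep)


def align_covariates(ft: FeatureTable, cov: CovariateTable) -> AlignedCohort:
    """Row-align covariates to a feature table on shared subject ids.

    Subjects missing from the covariate table are excluded from the view
    (they still participate in every stage that does not need covariates);
    covariate rows with no matching subject are dropped with a warning.
    """
    shared = [s for s in ft.subject_ids if s in set(cov.subject_ids)]
    if not shared:
        raise ValueError("no overlapping subject ids between features and covariates")
    extra = sorted(set(cov.subject_ids) - set(ft.subject_ids))
    if extra:
        logger.warning("%d covariate rows have no matching subject: %s",
                       len(extra), extra[:5])
    dropped = [s for s in ft.subject_ids if s not in set(shared)]
    if dropped:
        logger.info("%d subjects lack covariates and are excluded from "
                    "covariate-based stages", len(dropped))
    idx = [ft.subject_ids.index(s) for s in shared]
    sub = FeatureTable(
        shared, list(ft.feature_names), ft.values[idx],
        None if ft.labels is None else ft.labels[idx],
    )
    return AlignedCohort(sub, cov.data.loc[shared], dropped)


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None
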