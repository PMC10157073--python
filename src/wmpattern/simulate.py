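"""Synthetic cohort generation.

The generator emulates the statistical structure the downstream analysis
assumes: a small two-group cohort (defaults 14 positive vs 15 negative
subjects) of 72 white-matter features with

* exchangeable correlation within each modality block (all FA features
  share a latent factor, likewise MD, RD, AD and SC),
* a sparse, mixed-sign standardized mean shift between groups (default
  20 of 72 features, magnitudes 0.3-0.8 SD) — individually too small to
  survive a per-feature screen at n = 14/15 but jointly separable by a
  multivariate classifier,
* features shifted/scaled into plausible DTI ranges (FA in [0, 1],
  diffusivities positive, in units of 1e-3 mm^2/s), and
* covariates generated as linear functions of each subject's true latent
  discriminant score plus noise, alongside pure-noise distractors, with
  one 3-level ordinal risk-rating covariate obtained by thresholding a
  latent normal.

The default effect placement follows the qualitative direction map of the
discriminative pattern this analysis is designed to recover: anterior
cingulate FA raised in the positive class, left-amygdala MD/RD lowered,
left-hemisphere prefrontal-amygdala connectivity raised and its
right-hemisphere counterpart lowered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import canonical_feature_names, modality_blocks
from .io import CovariateTable, FeatureTable

#: per-modality location/scale used to map standardized features into
#: plausible DTI ranges (diffusivities in 1e-3 mm^2/s)
MODALITY_SCALES = {
    "FA": (0.45, 0.05),
    "MD": (0.85, 0.06),
    "RD": (0.65, 0.06),
    "AD": (1.15, 0.07),
    "SC": (0.50, 0.12),
    "other": (0.0, 1.0),
}


def default_effects() -> dict[str, float]:
    """Default sparse standardized group shift (positive class minus negative).

    20 nonzero entries, magnitudes 0.3-0.8 SD, mixed signs.
    """
    return {
        # FA raised in ACC / left amygdala, lowered right amygdala, CC1, right sgACC
        "FA_pgACC_right": 0.80,
        "FA_pgACC_left": 0.80,
        "FA_dACC_right": 0.70,
        "FA_rACC_right": 0.55,
        "FA_amygdala_left": 0.50,
        "FA_amygdala_right": -0.40,
        "FA_CC1": -0.40,
        "FA_sgACC_right": -0.45,
        # diffusivity lowered in the left amygdala
        "RD_amygdala_left": -0.80,
        "RD_dACC_left": -0.40,
        "RD_CC3": -0.40,
        "MD_amygdala_left": -0.70,
        "MD_CC5": -0.40,
        # weaker axial-diffusivity contributions
        "AD_pgACC_left": 0.45,
        "AD_sgACC_left": -0.40,
        "AD_sgACC_right": 0.40,
        # connectivity: left raised, right lowered
        "SC_amygdala_to_PFC_left": 0.80,
        "SC_PFC_to_amygdala_left": 0.70,
        "SC_amygdala_to_PFC_right": -0.80,
        "SC_PFC_to_amygdala_right": -0.45,
    }


@dataclass
class CovariateLink:
    """One generated covariate: intercept + slope * latent score + noise."""

    intercept: float
    slope: float
    noise_sd: float
    kind: str = "continuous"  # "continuous" | "count" | "ordinal3"


def default_covariate_links() -> dict[str, CovariateLink]:
    """Covariate generator settings.

    Location/scale anchored to the descriptive statistics of the study
    population the generator emulates (e.g. age ~40, ~4.5 child victims,
    risk-checklist total ~13); age, verbal IQ and education are pure-noise
    distractors, the forensic scores are linked to the latent score.
    """
    return {
        "age": CovariateLink(42.0, 0.0, 10.0),
        "verbal_iq": CovariateLink(106.0, 0.0, 10.0),
        "years_education": CovariateLink(12.5, 0.0, 1.2),
        "n_child_victims": CovariateLink(4.5, 2.0, 1.5, kind="count"),
        "svr20_total": CovariateLink(12.8, 3.0, 2.5),
        "svr20_final_assessment": CovariateLink(0.0, 1.0, 0.6, kind="ordinal3"),
        "pcl_r_total": CovariateLink(9.0, 2.0, 5.0),
        "msi_sexual_knowledge": CovariateLink(15.9, 2.0, 2.0),
    }


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort; same spec + seed => same cohort."""

    n_pos: int = 14
    n_neg: int = 15
    feature_names: list[str] = field(default_factory=canonical_feature_names)
    effects: dict[str, float] | None = None  # None -> default_effects()
    rho: float = 0.3
    covariate_links: dict[str, CovariateLink] = field(
        default_factory=default_covariate_links)
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("negative group size")
        if self.n_pos + self.n_neg < 2:
            raise ValueError("need at least 2 subjects")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                "within-block correlation must be in [0, 1) for a "
                "positive-definite exchangeable correlation matrix"
            )
        if self.effects is None:
            self.effects = default_effects()
        unknown = set(self.effects) - set(self.feature_names)
        if unknown:
            raise ValueError(f"effects name unknown features: {sorted(unknown)[:3]}")

    def effect_vector(self) -> np.ndarray:
        e = np.zeros(len(self.feature_names))
        for name, val in self.effects.items():
            e[self.feature_names.index(name)] = val
        return e

    @classmethod
    def null(cls, **kwargs) -> "SyntheticSpec":
        """Spec with no group effect (all shifts zero)."""
        kwargs.setdefault("effects", {})
        return cls(**kwargs)


@dataclass
class SyntheticCohort:
    features: FeatureTable
    covariates: CovariateTable
    truth: dict


def _standardized_features(spec: SyntheticSpec, n: int, labels: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Block-correlated standard normals with the group shift applied.

    Returns (z, latent) where latent is each subject's true discriminant
    score, the projection of the standardized features onto the effect
    direction.
    """
    d = len(spec.feature_names)
    z = np.empty((n, d))
    for _, cols in modality_blocks(spec.feature_names).items():
        shared = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, len(cols)))
        z[:, cols] = np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * idio
    e = spec.effect_vector()
    z += 0.5 * np.outer(labels, e)  # group means differ by exactly e
    norm = np.linalg.norm(e)
    latent = z @ e / norm if norm > 0 else np.zeros(n)
    return z, latent


def _to_physical(z: np.ndarray, names: list[str]) -> np.ndarray:
    x = np.empty_like(z)
    for mod, cols in modality_blocks(names).items():
        loc, scale = MODALITY_SCALES[mod]
        x[:, cols] = loc + scale * z[:, cols]
    fa_cols = modality_blocks(names).get("FA", [])
    if fa_cols:
        x[:, fa_cols] = np.clip(x[:, fa_cols], 0.0, 1.0)
    for mod in ("MD", "RD", "AD", "SC"):
        cols = modality_blocks(names).get(mod, [])
        if cols:
            x[:, cols] = np.clip(x[:, cols], 1e-6, None)
    return x


def _covariates(spec: SyntheticSpec, latent: np.ndarray, ids: list[str],
                rng: np.random.Generator) -> CovariateTable:
    cols = {}
    for name, link in spec.covariate_links.items():
        noise = rng.standard_normal(len(latent)) * link.noise_sd
        raw = link.intercept + link.slope * latent + noise
        if link.kind == "count":
            raw = np.clip(np.round(raw), 0, None)
        elif link.kind == "ordinal3":
            # 3-level professional risk rating {0, 1, 2} by thresholding
            raw = np.digitize(raw, (-0.8, 0.6)).astype(float)
        cols[name] = raw
    return CovariateTable(pd.DataFrame(cols, index=pd.Index(ids, name="subject_id")))


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a labeled cohort with covariates and ground truth.

    Requires at least 2 subjects per class; use
    :func:`generate_external_cohort` for unlabeled single-group draws.
    """
    if spec.n_pos < 2 or spec.n_neg < 2:
        raise ValueError("labeled cohorts need >= 2 subjects per class")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.concatenate([np.ones(spec.n_pos, int), -np.ones(spec.n_neg, int)])
    ids = [f"PO{i + 1:03d}" for i in range(spec.n_pos)] + \
          [f"HC{i + 1:03d}" for i in range(spec.n_neg)]
    z, latent = _standardized_features(spec, n, labels, rng)
    x = _to_physical(z, spec.feature_names)
    ft = FeatureTable(ids, list(spec.feature_names), x, labels)
    cov = _covariates(spec, latent, ids, rng)
    truth = {
        "effect_vector": dict(spec.effects),
        "latent_scores": dict(zip(ids, latent.tolist())),
        "rho": spec.rho,
        "seed": spec.seed,
    }
    return SyntheticCohort(ft, cov, truth)


def generate_external_cohort(n: int = 53, feature_names: list[str] | None = None,
                             rho: float = 0.3, seed: int = 0,
                             effects: dict[str, float] | None = None) -> FeatureTable:
    """Unlabeled external cohort drawn from the negative-class distribution."""
    if n < 1:
        raise ValueError("need at least 1 subject")
    names = list(feature_names) if feature_names else canonical_feature_names()
    spec = SyntheticSpec(n_pos=2, n_neg=2, feature_names=names, rho=rho,
                         effects=effects if effects is not None else None,
                         seed=seed)
    rng = np.random.default_rng(seed)
    labels = -np.ones(n, int)
    z, _ = _standardized_features(spec, n, labels, rng)
    x = _to_physical(z, names)
    ids = [f"EXT{i + 1:03d}" for i in range(n)]
    return FeatureTable(ids, names, x, None)


def generate_null_labels(ft: FeatureTable, seed: int) -> FeatureTable:
    """Return a copy of the table with labels permuted uniformly at random.

    Class counts are preserved exactly; features are untouched. Used to
    build the permutation null distribution for model significance.
    """
    if ft.labels is None:
        raise ValueError("cannot permute labels of an unlabeled table")
    rng = np.random.default_rng(seed)
    return ft.with_labels(ft.labels[rng.permutation(ft.n_subjects)])
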