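"""Canonical white-matter feature vocabulary.

The study design samples four diffusion scalars (FA, MD, RD, AD) in 17
regions of interest — five anterior-cingulate subdivisions per hemisphere,
the two amygdalae, and five corpus-callosum segments — plus four structural
connectivity (normalized probabilistic fiber count) features between the
prefrontal cortex and the amygdala, one per direction and hemisphere.
That yields the canonical 72-column feature table this package analyzes.

Non-canonical feature names are allowed everywhere (the pipeline is
generic); readers only emit a warning when a table deviates from this
vocabulary.
"""

from __future__ import annotations

# ACC subdivisions: caudal, dorsal, rostral, subgenual, pregenual
ACC_SUBDIVISIONS = ("cACC", "dACC", "rACC", "sgACC", "pgACC")

#: 17 regions of interest: 10 ACC spheres, 2 amygdalae, 5 corpus-callosum segments
ROI_NAMES: tuple[str, ...] = tuple(
    f"{acc}_{side}" for acc in ACC_SUBDIVISIONS for side in ("left", "right")
) + ("amygdala_left", "amygdala_right") + tuple(f"CC{i}" for i in range(1, 6))

#: diffusion scalar modalities
MODALITIES = ("FA", "MD", "RD", "AD")

#: structural connectivity features (normalized fiber counts, directional)
SC_FEATURES: tuple[str, ...] = (
    "SC_amygdala_to_PFC_left",
    "SC_PFC_to_amygdala_left",
    "SC_amygdala_to_PFC_right",
    "SC_PFC_to_amygdala_right",
)


def canonical_feature_names() -> list[str]:
    """The canonical 72 feature names: 17 ROIs x {FA, MD, RD, AD} + 4 SC."""
    names = [f"{mod}_{roi}" for mod in MODALITIES for roi in ROI_NAMES]
    names.extend(SC_FEATURES)
    return names


def feature_modality(name: str) -> str:
    """Modality block a feature belongs to ("FA", "MD", "RD", "AD" or "SC").

    Names that do not start with a known modality prefix fall into the
    catch-all block "other".
    """
    prefix = name.split("_", 1)[0]
    if prefix in MODALITIES or prefix == "SC":
        return prefix
    return "other"


def modality_blocks(names: list[str]) -> dict[str, list[int]]:
    """Group feature column indices by modality block."""
    blocks: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        blocks.setdefault(feature_modality(name), []).append(j)
    return blocks
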