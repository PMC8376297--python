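"""AAL-116 parcellation labels and lobe-level bookkeeping.

The 116-region Automated Anatomical Labeling atlas is used here purely as
a labeling convention for connectivity matrices: 78 cortical regions, 12
subcortical nuclei (hippocampus, amygdala, caudate, putamen, pallidum and
thalamus, bilaterally) and 26 cerebellar regions (hemispheric lobules and
vermis).  The pipeline itself is atlas-agnostic; any region list works.
"""

from __future__ import annotations

__all__ = ["AAL116_LABELS", "region_category", "category_counts", "default_labels"]

_CORTICAL_1_90 = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_CEREBELLAR = [
    "Cerebelum_Crus1_L", "Cerebelum_Crus1_R", "Cerebelum_Crus2_L",
    "Cerebelum_Crus2_R", "Cerebelum_3_L", "Cerebelum_3_R",
    "Cerebelum_4_5_L", "Cerebelum_4_5_R", "Cerebelum_6_L", "Cerebelum_6_R",
    "Cerebelum_7b_L", "Cerebelum_7b_R", "Cerebelum_8_L", "Cerebelum_8_R",
    "Cerebelum_9_L", "Cerebelum_9_R", "Cerebelum_10_L", "Cerebelum_10_R",
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

#: The 116 region labels in standard AAL order (L/R interleaved for the
#: 90 cerebral regions, then 26 cerebellar regions).
AAL116_LABELS: list[str] = [
    f"{name}_{side}" for name in _CORTICAL_1_90 for side in ("L", "R")
] + list(_CEREBELLAR)

_SUBCORTICAL_STEMS = {
    "Hippocampus", "Amygdala", "Caudate", "Putamen", "Pallidum", "Thalamus",
}


def region_category(label: str) -> str:
    """Classify a region label as ``cortical``, ``subcortical`` or ``cerebellar``."""
    if label.startswith(("Cerebelum", "Vermis")):
        return "cerebellar"
    stem = label.rsplit("_", 1)[0]
    if stem in _SUBCORTICAL_STEMS:
        return "subcortical"
    return "cortical"


def category_counts(labels: list[str] | None = None) -> dict[str, int]:
    """Count regions per lobe-level category (default: the AAL-116 list)."""
    labels = AAL116_LABELS if labels is None else labels
    counts = {"cortical": 0, "subcortical": 0, "cerebellar": 0}
    for lab in labels:
        counts[region_category(lab)] += 1
    return counts


def default_labels(n_regions: int) -> list[str]:
    """AAL names when the region count matches 116, generic names otherwise."""
    if n_regions == 116:
        return list(AAL116_LABELS)
    return [f"ROI_{k:03d}" for k in range(n_regions)]
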