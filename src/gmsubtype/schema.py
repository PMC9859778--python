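"""Region-of-interest schema for the 96-ROI gray-matter parcellation.

The atlas layout mirrors an adult-lifespan template parcellation: 82
cortical ROIs (41 bilateral pairs), 12 subcortical ROIs (6 bilateral
pairs) and 2 brainstem ROIs.  The bilateral caudate, putamen and
pallidum are flagged as basal ganglia for the basal-ganglia/cortical
volume ratio.  Each cortical ROI carries a lobe tag so that simulation
and reporting code can address regional (e.g. fronto-occipital)
patterns by name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

CORTICAL = "cortical"
SUBCORTICAL = "subcortical"
BRAINSTEM = "brainstem"

# (base name, lobe) for the 41 bilateral cortical pairs
_CORTICAL_PAIRS: list[tuple[str, str]] = [
    ("Precentral", "frontal"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "frontal"),
    ("Supp_Motor_Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Frontal_Pole", "frontal"),
    ("Insula", "insula"),
    ("Cingulum_Ant", "cingulate"),
    ("Cingulum_Mid", "cingulate"),
    ("Cingulum_Post", "cingulate"),
    ("Parahippocampal", "temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Occipital_Pole", "occipital"),
    ("Fusiform", "temporal"),
    ("Postcentral", "parietal"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral_Lobule", "parietal"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
]

_SUBCORTICAL_PAIRS: list[tuple[str, bool]] = [
    # (base name, is basal ganglia)
    ("Hippocampus", False),
    ("Amygdala", False),
    ("Caudate", True),
    ("Putamen", True),
    ("Pallidum", True),
    ("Thalamus", False),
]

_BRAINSTEM = ["Midbrain", "Pons"]


@dataclass(frozen=True)
class ROI:
    """A single region of interest."""

    name: str
    roi_class: str  # cortical | subcortical | brainstem
    hemisphere: str  # L | R | M (midline / unpaired)
    lobe: str
    is_basal_ganglia: bool = False


@dataclass
class ROISchema:
    """Names and classes of the ROIs defining a cohort's volume columns."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(names) != len(set(names)):
            raise ValueError("duplicate ROI names in schema")

    # -- selections -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def by_class(self, roi_class: str) -> list[str]:
        return [r.name for r in self.rois if r.roi_class == roi_class]

    @property
    def cortical(self) -> list[str]:
        return self.by_class(CORTICAL)

    @property
    def subcortical(self) -> list[str]:
        return self.by_class(SUBCORTICAL)

    @property
    def brainstem(self) -> list[str]:
        return self.by_class(BRAINSTEM)

    @property
    def basal_ganglia(self) -> list[str]:
        return [r.name for r in self.rois if r.is_basal_ganglia]

    def by_lobe(self, lobe: str) -> list[str]:
        return [r.name for r in self.rois if r.lobe == lobe]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def validate_full(self) -> None:
        """Check the canonical 96-ROI layout (82/12/2, 6 basal ganglia)."""
        counts = (len(self.cortical), len(self.subcortical), len(self.brainstem))
        if counts != (82, 12, 2):
            raise ValueError(
                f"expected 82 cortical / 12 subcortical / 2 brainstem ROIs, got {counts}"
            )
        if len(self.basal_ganglia) != 6:
            raise ValueError(
                f"expected 6 basal-ganglia ROIs, got {len(self.basal_ganglia)}"
            )

    # -- serialization ----------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"rois": [asdict(r) for r in self.rois]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROISchema":
        payload = json.loads(Path(path).read_text())
        return cls(rois=[ROI(**r) for r in payload["rois"]])


def default_schema() -> ROISchema:
    """The canonical 96-ROI schema (82 cortical, 12 subcortical, 2 brainstem)."""
    rois: list[ROI] = []
    for base, lobe in _CORTICAL_PAIRS:
        for hemi in ("L", "R"):
            rois.append(ROI(f"{base}_{hemi}", CORTICAL, hemi, lobe))
    for base, is_bg in _SUBCORTICAL_PAIRS:
        for hemi in ("L", "R"):
            rois.append(ROI(f"{base}_{hemi}", SUBCORTICAL, hemi, "subcortical", is_bg))
    for base in _BRAINSTEM:
        rois.append(ROI(base, BRAINSTEM, "M", "brainstem"))
    schema = ROISchema(rois=rois)
    schema.validate_full()
    return schema
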