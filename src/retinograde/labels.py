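"""Grade labels for diabetic retinopathy (DR) and diabetic macular edema (DME).

DR is graded by lesion load (microaneurysms, haemorrhages, exudates,
neovascularisation); DME is graded by how close hard exudates sit to the
fovea.  A :class:`GradeLabel` carries both grades; a healthy retina by
definition carries no macular edema.
"""

from __future__ import annotations

from dataclasses import dataclass

DR_GRADES = (
    "healthy",
    "mild_NPDR",
    "moderate_NPDR",
    "severe_NPDR",
    "proliferative_DR",
)

DME_GRADES = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class GradeLabel:
    """Joint DR/DME grade of one fundus image."""

    dr_grade: str
    dme_grade: str

    def __post_init__(self) -> None:
        if self.dr_grade not in DR_GRADES:
            raise ValueError(
                f"unknown dr_grade {self.dr_grade!r}; expected one of {DR_GRADES}"
            )
        if self.dme_grade not in DME_GRADES:
            raise ValueError(
                f"unknown dme_grade {self.dme_grade!r}; expected one of {DME_GRADES}"
            )
        if self.dr_grade == "healthy" and self.dme_grade != "none":
            raise ValueError("a healthy retina cannot carry macular edema")

    @property
    def name(self) -> str:
        return f"{self.dr_grade}+{self.dme_grade}"

    @classmethod
    def from_name(cls, name: str) -> "GradeLabel":
        dr, _, dme = name.partition("+")
        return cls(dr, dme or "none")


#: Default joint label space: healthy plus the four DR grades, with the DME
#: grades subsumed — every DR grade and every DME grade appears at least
#: once, each DME grade paired with a distinct DR grade (edema severity
#: co-progresses with retinopathy severity).
JOINT_CLASSES = (
    GradeLabel("healthy", "none"),
    GradeLabel("mild_NPDR", "none"),
    GradeLabel("moderate_NPDR", "none"),
    GradeLabel("severe_NPDR", "none"),
    GradeLabel("proliferative_DR", "none"),
    GradeLabel("moderate_NPDR", "mild"),
    GradeLabel("severe_NPDR", "moderate"),
    GradeLabel("proliferative_DR", "severe"),
)

#: Pixel classes produced by the segmenter.
SEGMENT_CLASSES = (
    "background",
    "vessel",
    "optic_disc",
    "fovea",
    "microaneurysm",
    "haemorrhage",
    "hard_exudate",
    "soft_exudate",
)

#: Structure masks carried by a synthetic sample (all but background).
MASK_CLASSES = SEGMENT_CLASSES[1:]

#: Lesion (pathology) mask names — empty for a healthy retina.
LESION_CLASSES = ("microaneurysm", "haemorrhage", "hard_exudate", "soft_exudate")
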