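"""Endpoint-derivation rules for a venous tumour thrombus (VTT) trial.

Covers the Mayo level classification of thrombus extent (0 = renal vein
only up to 4 = above the diaphragm), the per-patient improvement call,
summed thrombus length and its percent change, the bespoke VTT partial
response call (>30% length reduction), RECIST v1.1 target-lesion response,
the planned-vs-performed surgical approach comparison, and eligibility
formulas (Cockcroft–Gault creatinine clearance and the screening checks).

All lengths are millimetres; the 2 cm Mayo boundary is 20 mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Side",
    "TipLandmark",
    "Timepoint",
    "ImprovementCall",
    "RecistCategory",
    "SurgicalChangeCall",
    "VTTAssessment",
    "VTTLengths",
    "SurgicalPlanRecord",
    "SurgicalChangeResult",
    "LesionMeasurements",
    "PatientBaseline",
    "EligibilityResult",
    "classify_mayo",
    "mayo_improvement",
    "vtt_sum",
    "vtt_percent_change",
    "vtt_response",
    "recist_classify",
    "surgical_change",
    "cockcroft_gault",
    "eligibility_check",
]

MAYO_BOUNDARY_MM = 20.0  # level 1 is strictly below 2 cm above the ostium
VTT_PR_THRESHOLD_PCT = 30.0  # VTT partial response: strictly more than 30% reduction


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class TipLandmark(enum.IntEnum):
    """Anatomical position of the thrombus tip, ordered caudad to craniad.

    The integer rank gives the anatomical ordering used by the
    monotonicity and level-0 sub-level rules.  RV_LATERAL_TO_GONADAL only
    exists on the left (the right gonadal vein drains directly to the IVC).
    """

    RV_BRANCHES = 0
    RV_LATERAL_TO_GONADAL = 1
    RV_MAIN = 2
    IVC = 3
    IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM = 4
    IVC_ABOVE_DIAPHRAGM = 5


_RV_LANDMARKS = {
    TipLandmark.RV_BRANCHES,
    TipLandmark.RV_LATERAL_TO_GONADAL,
    TipLandmark.RV_MAIN,
}


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    WEEK3 = "week3"
    WEEK9 = "week9"


class ImprovementCall(str, enum.Enum):
    IMPROVED = "improved"
    STABLE = "stable"
    WORSENED = "worsened"


class RecistCategory(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class SurgicalChangeCall(str, enum.Enum):
    LESS_EXTENSIVE = "less_extensive"
    UNCHANGED = "unchanged"
    MORE_EXTENSIVE = "more_extensive"


@dataclass(frozen=True)
class VTTAssessment:
    """One timepoint's anatomical description of the thrombus tip."""

    side: Side
    tip_landmark: TipLandmark
    tip_distance_above_ostium: float | None = None  # mm, required for IVC landmark
    timepoint: Timepoint = Timepoint.BASELINE

    def __post_init__(self) -> None:
        if (
            self.tip_landmark is TipLandmark.RV_LATERAL_TO_GONADAL
            and self.side is not Side.LEFT
        ):
            raise ValueError("RV_LATERAL_TO_GONADAL is defined only for left-sided thrombi")
        if self.tip_landmark is TipLandmark.IVC and self.tip_distance_above_ostium is None:
            raise ValueError("IVC landmark requires tip_distance_above_ostium (mm)")
        if self.tip_distance_above_ostium is not None and self.tip_distance_above_ostium < 0:
            raise ValueError("tip_distance_above_ostium must be >= 0 mm")


@dataclass(frozen=True)
class VTTLengths:
    """Measurable thrombus components (mm) at one timepoint.

    ``ivc_above_mm``/``ivc_below_mm`` are measured from the midpoint of the
    renal-vein ostium; both are zero for renal-vein-only thrombi.
    """

    rv_mm: float
    ivc_above_mm: float = 0.0
    ivc_below_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rv_mm", "ivc_above_mm", "ivc_below_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 mm")


@dataclass(frozen=True)
class SurgicalPlanRecord:
    """Planned or performed surgical descriptors for one patient.

    ``level_of_control`` is the six-step ordinal of how high the vena cava
    must be controlled (1 = thrombus milked into the renal vein and side
    clamped … 6 = suprahepatic, supradiaphragmatic clamping).
    ``incision_rank`` is an ordinal extent rank for the incision (larger =
    more extensive).
    """

    approach: str  # "open" | "minimally_invasive"
    incision_rank: int
    level_of_control: int
    incision_label: str = ""
    venovenous_bypass: bool = False
    hypothermic_cardiac_arrest: bool = False
    pringle: bool = False

    def __post_init__(self) -> None:
        if self.approach not in ("open", "minimally_invasive"):
            raise ValueError(f"approach must be open|minimally_invasive, got {self.approach!r}")
        if not 1 <= self.level_of_control <= 6:
            raise ValueError(f"level_of_control must be in 1..6, got {self.level_of_control}")
        if self.incision_rank < 0:
            raise ValueError("incision_rank must be >= 0")


@dataclass(frozen=True)
class SurgicalChangeResult:
    call: SurgicalChangeCall
    open_to_minimally_invasive: bool
    lower_level_of_control: bool
    smaller_incision: bool
    minimally_invasive_to_open: bool
    higher_level_of_control: bool
    larger_incision: bool


@dataclass(frozen=True)
class LesionMeasurements:
    """Sum of target-lesion diameters (mm) at one timepoint."""

    target_sum_mm: float
    new_lesion: bool = False
    timepoint: Timepoint = Timepoint.BASELINE

    def __post_init__(self) -> None:
        if self.target_sum_mm < 0:
            raise ValueError("target_sum_mm must be >= 0")


def classify_mayo(a: VTTAssessment) -> int:
    """Mayo level (0-4) of thrombus extent from the tip landmark.

    Level 0: limited to the renal vein; 1: IVC < 2 cm above the ostium;
    2: IVC >= 2 cm above the ostium but below the hepatic veins; 3: at or
    above the hepatic veins, below the diaphragm; 4: above the diaphragm.
    The 2.0 cm boundary is assigned level 2 (level 1 is defined strictly
    as < 2 cm).
    """
    lm = a.tip_landmark
    if lm in _RV_LANDMARKS:
        return 0
    if lm is TipLandmark.IVC:
        return 1 if a.tip_distance_above_ostium < MAYO_BOUNDARY_MM else 2
    if lm is TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM:
        return 3
    return 4  # IVC_ABOVE_DIAPHRAGM


def mayo_improvement(baseline: VTTAssessment, followup: VTTAssessment) -> ImprovementCall:
    """Per-patient improvement call between two assessments of one thrombus.

    For a baseline Mayo level >= 1 the call follows the level: a lower
    level at follow-up is improvement, a higher level worsening.  For a
    level-0 (renal-vein-only) baseline, improvement is a caudad move of
    the tip within the renal vein (main RV to branches on the right; main
    RV to lateral-to-gonadal, or lateral-to-gonadal to branches, on the
    left) because such regression enables minimally invasive surgery;
    worsening is extension into the IVC; a craniad move within the renal
    vein is recorded as stable.
    """
    if baseline.side is not followup.side:
        raise ValueError("baseline and follow-up must describe the same side")
    level0 = classify_mayo(baseline)
    level1 = classify_mayo(followup)
    if level0 >= 1:
        if level1 < level0:
            return ImprovementCall.IMPROVED
        if level1 > level0:
            return ImprovementCall.WORSENED
        return ImprovementCall.STABLE
    # level-0 baseline: sub-level rules within the renal vein
    if level1 > 0:
        return ImprovementCall.WORSENED
    if followup.tip_landmark < baseline.tip_landmark:
        return ImprovementCall.IMPROVED
    return ImprovementCall.STABLE


def vtt_sum(lengths: VTTLengths) -> float:
    """Total thrombus length (mm): RV + IVC-above-ostium + IVC-below-ostium."""
    return lengths.rv_mm + lengths.ivc_above_mm + lengths.ivc_below_mm


def vtt_percent_change(baseline: VTTLengths, followup: VTTLengths) -> float:
    """Percent reduction in summed thrombus length: 100 x (1 - Sum_T / Sum_0).

    Positive values are shrinkage, negative values growth.  Undefined for
    a zero baseline sum.
    """
    sum0 = vtt_sum(baseline)
    if sum0 <= 0:
        raise ValueError("percent change undefined: baseline thrombus length sum is zero")
    return 100.0 * (1.0 - vtt_sum(followup) / sum0)


def vtt_response(percent_change: float) -> bool:
    """Thrombus partial response: strictly more than 30% length reduction."""
    return percent_change > VTT_PR_THRESHOLD_PCT


def recist_classify(
    baseline: LesionMeasurements,
    current: LesionMeasurements,
    nadir: LesionMeasurements,
) -> RecistCategory:
    """RECIST v1.1 target-lesion response category.

    CR: disappearance of all target lesions; PR: >=30% decrease in the sum
    from baseline; PD: a new lesion, or >=20% increase from the nadir that
    is also >=5 mm absolute; otherwise SD.  A new lesion always yields PD.
    """
    if current.new_lesion:
        return RecistCategory.PD
    increase = current.target_sum_mm - nadir.target_sum_mm
    if nadir.target_sum_mm > 0:
        pd_by_growth = increase / nadir.target_sum_mm >= 0.20 and increase >= 5.0
    else:
        pd_by_growth = increase >= 5.0
    if pd_by_growth:
        return RecistCategory.PD
    if current.target_sum_mm == 0:
        return RecistCategory.CR
    if baseline.target_sum_mm > 0:
        decrease = (baseline.target_sum_mm - current.target_sum_mm) / baseline.target_sum_mm
        if decrease >= 0.30:
            return RecistCategory.PR
    return RecistCategory.SD


def surgical_change(
    planned: SurgicalPlanRecord, performed: SurgicalPlanRecord
) -> SurgicalChangeResult:
    """Compare planned vs performed surgery and call the direction of change.

    Less extensive if any of: open converted to minimally invasive, a
    lower level of venous control, or a smaller incision; more extensive
    if any criterion moved the opposite way and none improved.
    """
    o2m = planned.approach == "open" and performed.approach == "minimally_invasive"
    m2o = planned.approach == "minimally_invasive" and performed.approach == "open"
    lower = performed.level_of_control < planned.level_of_control
    higher = performed.level_of_control > planned.level_of_control
    smaller = performed.incision_rank < planned.incision_rank
    larger = performed.incision_rank > planned.incision_rank
    if o2m or lower or smaller:
        call = SurgicalChangeCall.LESS_EXTENSIVE
    elif m2o or higher or larger:
        call = SurgicalChangeCall.MORE_EXTENSIVE
    else:
        call = SurgicalChangeCall.UNCHANGED
    return SurgicalChangeResult(
        call=call,
        open_to_minimally_invasive=o2m,
        lower_level_of_control=lower,
        smaller_incision=smaller,
        minimally_invasive_to_open=m2o,
        higher_level_of_control=higher,
        larger_incision=larger,
    )


def cockcroft_gault(age: float, weight: float, sex: str, serum_creatinine: float) -> float:
    """Cockcroft–Gault estimated creatinine clearance (mL/min).

    ``(140 - age) x weight / (72 x serum creatinine [mg/dL])``, scaled by
    0.85 for females.
    """
    if age <= 0 or weight <= 0 or serum_creatinine <= 0:
        raise ValueError("age, weight and serum_creatinine must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male|female, got {sex!r}")
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "female":
        crcl *= 0.85
    return crcl


@dataclass(frozen=True)
class PatientBaseline:
    """Screening covariates for the eligibility check.

    ``None`` marks a value not recorded; the corresponding criterion is
    then reported as indeterminate rather than failed.
    """

    age: float | None = None
    weight: float | None = None
    sex: str | None = None
    ecog: int | None = None
    urinalysis_protein_plus: int | None = None  # dipstick protein, 0..4 "+"
    urine_protein_g_24h: float | None = None
    protein_creatinine_ratio: float | None = None  # mg/mmol
    serum_creatinine: float | None = None  # mg/dL
    creatinine_uln: float | None = None  # assay upper limit of normal, mg/dL
    biopsy_ccrcc: bool | None = None
    m_stage: str | None = None  # "M0" | "M1"
    mskcc_risk: str | None = None  # "favourable" | "intermediate" | "poor"


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    violations: tuple[str, ...]
    indeterminate: tuple[str, ...]


def eligibility_check(baseline: PatientBaseline) -> EligibilityResult:
    """Apply the screening eligibility criteria to one patient.

    Criteria: age > 18; ECOG performance status < 2; proteinuria below
    threshold on any of dipstick (< 2+), 24-h protein (< 2 g) or
    protein:creatinine ratio (< 200 mg/mmol); renal function adequate by
    either serum creatinine <= 1.5 x ULN or Cockcroft–Gault clearance
    >= 30 mL/min; biopsy-proven clear cell histology; and, for metastatic
    patients, MSKCC risk not poor.  Criteria whose inputs are missing are
    listed as indeterminate and do not fail the patient.
    """
    violations: list[str] = []
    indeterminate: list[str] = []

    def judge(name: str, value: bool | None) -> None:
        if value is None:
            indeterminate.append(name)
        elif not value:
            violations.append(name)

    b = baseline
    judge("age_over_18", None if b.age is None else b.age > 18)
    judge("ecog_below_2", None if b.ecog is None else b.ecog < 2)

    protein_tests = [
        None if b.urinalysis_protein_plus is None else b.urinalysis_protein_plus < 2,
        None if b.urine_protein_g_24h is None else b.urine_protein_g_24h < 2.0,
        None if b.protein_creatinine_ratio is None else b.protein_creatinine_ratio < 200.0,
    ]
    known = [t for t in protein_tests if t is not None]
    judge("proteinuria_below_threshold", any(known) if known else None)

    creat_ok = None
    if b.serum_creatinine is not None and b.creatinine_uln is not None:
        creat_ok = b.serum_creatinine <= 1.5 * b.creatinine_uln
    crcl_ok = None
    if None not in (b.age, b.weight, b.sex, b.serum_creatinine):
        crcl_ok = cockcroft_gault(b.age, b.weight, b.sex, b.serum_creatinine) >= 30.0
    renal_tests = [t for t in (creat_ok, crcl_ok) if t is not None]
    judge("renal_function_adequate", any(renal_tests) if renal_tests else None)

    judge("biopsy_proven_ccrcc", b.biopsy_ccrcc)

    if b.m_stage is None:
        indeterminate.append("mskcc_not_poor_if_m1")
    elif b.m_stage == "M1":
        judge("mskcc_not_poor_if_m1", None if b.mskcc_risk is None else b.mskcc_risk != "poor")

    return EligibilityResult(
        eligible=not violations,
        violations=tuple(violations),
        indeterminate=tuple(indeterminate),
    )
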