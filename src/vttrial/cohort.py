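"""Synthetic trial cohorts: seeded generator, reference cohort, CSV I/O.

Patient-level data from the trial are not public, so the package carries
two substitutes:

* :func:`generate_cohort` draws seeded cohorts with the statistical
  structure the trial assumed — a categorical baseline Mayo distribution,
  per-level probabilities of a one-level improvement by week 9, a Gaussian
  model for percent change in thrombus length, a week-3 scan whose
  direction of change tracks week 9, occasional missing week-9 scans, and
  a surgery-dropout process.
* :func:`reference_cohort` is a hand-constructed, fully deterministic
  20-patient cohort (synthetic — no real patient resembles any row)
  reproducing the trial's printed aggregates: baseline Mayo distribution
  4/3/9/2/2, seven improvements (six IVC, one left-sided renal-vein-only
  via the gonadal rule), no worsening, and 15 patients with any length
  reduction.  It is the test surface for aggregate outputs only.

A cohort is four pandas DataFrames with fixed CSV schemas (assessments,
surgery, adverse events, per-patient covariates).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .endpoints import Side, Timepoint, TipLandmark

log = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "Cohort",
    "CohortSchemaError",
    "generate_cohort",
    "reference_cohort",
    "write_cohort",
    "read_cohort",
    "ASSESSMENT_COLUMNS",
    "SURGERY_COLUMNS",
    "AE_COLUMNS",
    "PATIENT_COLUMNS",
]

ASSESSMENT_COLUMNS = [
    "patient_id",
    "timepoint",
    "side",
    "tip_landmark",
    "tip_distance_mm",
    "rv_mm",
    "ivc_above_mm",
    "ivc_below_mm",
    "target_sum_mm",
    "new_lesion",
]
SURGERY_COLUMNS = [
    "patient_id",
    "phase",
    "approach",
    "incision_rank",
    "level_of_control",
    "venovenous_bypass",
    "hypothermic_cardiac_arrest",
    "pringle",
]
AE_COLUMNS = ["patient_id", "term", "grade", "related"]
PATIENT_COLUMNS = [
    "patient_id",
    "registered",
    "received_dose",
    "central_review_excluded",
    "age",
    "weight",
    "sex",
    "ecog",
    "m_stage",
    "mskcc_risk",
    "serum_creatinine",
    "creatinine_uln",
    "biopsy_ccrcc",
    "urinalysis_protein_plus",
]

_LANDMARKS = {lm.name for lm in TipLandmark}
_TIMEPOINTS = {tp.value for tp in Timepoint}
_SIDES = {s.value for s in Side}

# Default adverse-event profile: (term, any-grade probability, grade-3
# probability given any grade), echoing the most frequent related events.
_AE_PROFILE = [
    ("hypertension", 0.86, 0.28),
    ("fatigue", 0.67, 0.15),
    ("proteinuria", 0.48, 0.10),
    ("voice_alteration", 0.48, 0.0),
    ("mucositis", 0.43, 0.23),
    ("diarrhoea", 0.38, 0.0),
]


class CohortSchemaError(ValueError):
    """A cohort CSV violated the documented schema."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the cohort generator.

    Defaults reproduce the study conditions: 20 patients, baseline Mayo
    levels 0-4 distributed 4/3/9/2/2, improvement probability 0.25 for
    renal-vein-only and 0.375 for IVC thrombi, week-9 percent length
    change ~ N(27.2, 18^2) with week-3 change about half of week 9, 15%
    missing week-9 scans, and 19% surgical dropout.
    """

    n_patients: int = 20
    baseline_level_probs: tuple[float, ...] = (0.20, 0.15, 0.45, 0.10, 0.10)
    improvement_prob: tuple[float, ...] = (0.25, 0.375, 0.375, 0.375, 0.375)
    length_change_mean: float = 27.2
    length_change_sd: float = 18.0
    week3_fraction: float = 0.5
    week3_consistency: float = 1.0
    missing_week9_prob: float = 0.15
    no_surgery_prob: float = 0.19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.baseline_level_probs) != 5:
            raise ValueError("baseline_level_probs must cover Mayo levels 0..4")
        if abs(sum(self.baseline_level_probs) - 1.0) > 1e-9:
            raise ValueError("baseline_level_probs must sum to 1")
        if len(self.improvement_prob) != 5:
            raise ValueError("improvement_prob must cover Mayo levels 0..4")
        for name in (
            "week3_consistency",
            "missing_week9_prob",
            "no_surgery_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in self.baseline_level_probs + self.improvement_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.length_change_sd < 0:
            raise ValueError("length_change_sd must be >= 0")


@dataclass
class Cohort:
    """One trial cohort as schema-fixed DataFrames."""

    patients: pd.DataFrame
    assessments: pd.DataFrame
    surgery: pd.DataFrame
    ae: pd.DataFrame

    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])


# ---------------------------------------------------------------------------
# generator internals


def _baseline_anatomy(level: int, side: str, rng: np.random.Generator):
    """Draw (landmark, tip_distance, rv, ivc_above, ivc_below) for a level."""
    rv = float(np.round(rng.uniform(25, 60), 1))
    if level == 0:
        return TipLandmark.RV_MAIN.name, np.nan, rv, 0.0, 0.0
    below = float(np.round(rng.uniform(0, 25), 1))
    if level == 1:
        d = float(np.round(rng.uniform(5, 19), 1))
        return TipLandmark.IVC.name, d, rv, d, below
    if level == 2:
        d = float(np.round(rng.uniform(25, 80), 1))
        return TipLandmark.IVC.name, d, rv, d, below
    if level == 3:
        above = float(np.round(rng.uniform(90, 150), 1))
        return TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM.name, np.nan, rv, above, below
    above = float(np.round(rng.uniform(150, 220), 1))
    return TipLandmark.IVC_ABOVE_DIAPHRAGM.name, np.nan, rv, above, below


def _improved_anatomy(level: int, side: str, rng: np.random.Generator):
    """Tip position after a one-level improvement from ``level``."""
    if level == 0:
        lm = (
            TipLandmark.RV_LATERAL_TO_GONADAL
            if side == Side.LEFT.value
            else TipLandmark.RV_BRANCHES
        )
        return lm.name, np.nan
    if level == 1:
        return TipLandmark.RV_MAIN.name, np.nan
    if level == 2:
        return TipLandmark.IVC.name, float(np.round(rng.uniform(5, 19), 1))
    if level == 3:
        return TipLandmark.IVC.name, float(np.round(rng.uniform(25, 80), 1))
    return TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM.name, np.nan


def _followup_lengths(rv0, above0, below0, tip_landmark, tip_distance, factor):
    """Scale component lengths to ``factor`` x baseline, keeping the
    IVC-above component equal to the tip distance when the tip is in the IVC."""
    total = max(0.0, (rv0 + above0 + below0) * factor)
    if tip_landmark in (
        TipLandmark.RV_BRANCHES.name,
        TipLandmark.RV_LATERAL_TO_GONADAL.name,
        TipLandmark.RV_MAIN.name,
    ):
        return round(total, 1), 0.0, 0.0
    above = tip_distance if not np.isnan(tip_distance) else max(0.0, above0 * factor)
    rest = max(0.0, total - above)
    base_rest = rv0 + below0
    if base_rest > 0:
        rv = rest * rv0 / base_rest
        below = rest * below0 / base_rest
    else:
        rv, below = rest, 0.0
    return round(rv, 1), round(above, 1), round(below, 1)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one synthetic cohort; deterministic for a given config/seed."""
    rng = np.random.default_rng(config.seed)
    pat_rows, ass_rows, surg_rows, ae_rows = [], [], [], []
    levels = rng.choice(5, size=config.n_patients, p=config.baseline_level_probs)
    for i in range(config.n_patients):
        pid = f"S{i + 1:04d}"
        level = int(levels[i])
        side = Side.LEFT.value if rng.random() < 0.5 else Side.RIGHT.value
        improved = rng.random() < config.improvement_prob[level]

        lm0, d0, rv0, above0, below0 = _baseline_anatomy(level, side, rng)

        # week-9 percent length reduction; Mayo responders always shrink
        pct9 = rng.normal(config.length_change_mean, config.length_change_sd)
        if improved:
            while pct9 <= 0.0:
                pct9 = rng.normal(config.length_change_mean, config.length_change_sd)
        pct3 = config.week3_fraction * pct9 + rng.normal(0.0, 5.0)
        if rng.random() < config.week3_consistency and pct3 * pct9 < 0:
            pct3 = -pct3  # enforce direction concordance with week 9

        if improved:
            lm9, d9 = _improved_anatomy(level, side, rng)
        else:
            lm9, d9 = lm0, d0
            if lm9 == TipLandmark.IVC.name:
                # shrink/grow the tip with the length change but stay in band
                lo, hi = (5.0, 19.0) if level == 1 else (21.0, 300.0)
                d9 = float(np.round(min(max(d0 * (1 - pct9 / 100.0), lo), hi), 1))
        rv9, above9, below9 = _followup_lengths(rv0, above0, below0, lm9, d9, 1 - pct9 / 100.0)

        missing9 = rng.random() < config.missing_week9_prob
        # the last available scan carries the response; with a week-9 scan
        # present the week-3 scan shows only the early length trend
        if missing9:
            lm3, d3 = lm9, d9
            rv3, above3, below3 = rv9, above9, below9
        else:
            lm3, d3 = lm0, d0
            f3 = 1 - pct3 / 100.0
            if lm3 == TipLandmark.IVC.name:
                lo, hi = (5.0, 19.0) if level == 1 else (21.0, 300.0)
                d3 = float(np.round(min(max(d0 * f3, lo), hi), 1))
            rv3, above3, below3 = _followup_lengths(rv0, above0, below0, lm3, d3, f3)

        # RECIST target lesions: primary included, slow shrink on average
        t0 = float(np.round(rng.uniform(60, 150), 1))
        rec9 = rng.normal(12.0, 12.0)
        t9 = float(np.round(max(0.0, t0 * (1 - rec9 / 100.0)), 1))
        t3 = float(np.round(max(0.0, t0 * (1 - 0.5 * rec9 / 100.0)), 1))
        new_lesion9 = bool(rng.random() < 0.05)

        ass_rows.append([pid, "baseline", side, lm0, d0, rv0, above0, below0, t0, False])
        ass_rows.append([pid, "week3", side, lm3, d3, rv3, above3, below3, t3, False])
        if not missing9:
            ass_rows.append([pid, "week9", side, lm9, d9, rv9, above9, below9, t9, new_lesion9])

        # surgery: planned from baseline anatomy, performed after treatment
        operated = rng.random() >= config.no_surgery_prob
        if operated:
            planned_level = {0: 1, 1: 2, 2: 3, 3: 4, 4: 6}[level]
            planned_rank = min(3, planned_level)
            approach_p = "open" if level > 0 or rng.random() < 0.5 else "minimally_invasive"
            performed_level, performed_rank, approach_x = planned_level, planned_rank, approach_p
            if improved and rng.random() < 0.6:
                performed_level = max(1, planned_level - 1)
                performed_rank = min(3, performed_level)
            surg_rows.append([pid, "planned", approach_p, planned_rank, planned_level, False, planned_level == 6, False])
            surg_rows.append([pid, "performed", approach_x, performed_rank, performed_level, False, performed_level == 6, False])

        for term, p_any, p_g3 in _AE_PROFILE:
            if rng.random() < p_any:
                grade = 3 if rng.random() < p_g3 else int(rng.integers(1, 3))
                ae_rows.append([pid, term, grade, True])

        sex = "male" if rng.random() < 15 / 21 else "female"
        m_stage = "M1" if rng.random() < 10 / 21 else "M0"
        pat_rows.append(
            [
                pid,
                True,
                True,
                False,
                int(rng.integers(49, 79)),
                float(np.round(np.clip(rng.normal(85, 15), 50, 130), 1)),
                sex,
                int(rng.random() < 0.38),
                m_stage,
                "intermediate" if m_stage == "M1" else "",
                float(np.round(np.clip(rng.normal(1.0, 0.15), 0.6, 1.5), 2)),
                1.2,
                True,
                int(rng.integers(0, 2)),
            ]
        )

    cohort = Cohort(
        patients=pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
        assessments=pd.DataFrame(ass_rows, columns=ASSESSMENT_COLUMNS),
        surgery=pd.DataFrame(surg_rows, columns=SURGERY_COLUMNS),
        ae=pd.DataFrame(ae_rows, columns=AE_COLUMNS),
    )
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# deterministic reference cohort


def reference_cohort() -> Cohort:
    """Deterministic 20-patient synthetic cohort matching printed aggregates.

    Construction targets (all verified by the pipeline tests): baseline
    Mayo distribution 4/3/9/2/2 over levels 0-4; seven improvements — six
    among the sixteen IVC patients and one left-sided renal-vein-only
    patient via the gonadal-vein rule; no worsening; fifteen patients with
    some reduction in summed thrombus length, one with no change, four
    with growth; one patient (P20) with no week-9 scan so the week-3
    fallback path is exercised; seventeen operated patients of whom seven
    had less extensive surgery than planned.
    """
    A = []  # assessments

    def pt(pid, side, rows):
        for tp, lm, d, rv, ab, be, ts, nl in rows:
            A.append([pid, tp, side, lm, d, rv, ab, be, ts, nl])

    RV = TipLandmark.RV_MAIN.name
    RVB = TipLandmark.RV_BRANCHES.name
    RVG = TipLandmark.RV_LATERAL_TO_GONADAL.name
    IVC = TipLandmark.IVC.name
    HEP = TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM.name
    DIA = TipLandmark.IVC_ABOVE_DIAPHRAGM.name
    NA = np.nan

    # -- level 0 (4 patients); P01 improves via the left gonadal rule
    pt("P01", "left", [
        ("baseline", RV, NA, 50.0, 0.0, 0.0, 100.0, False),
        ("week3", RV, NA, 40.0, 0.0, 0.0, 95.0, False),
        ("week9", RVG, NA, 28.0, 0.0, 0.0, 90.0, False),   # -44%
    ])
    pt("P02", "right", [
        ("baseline", RV, NA, 40.0, 0.0, 0.0, 80.0, False),
        ("week3", RV, NA, 36.0, 0.0, 0.0, 78.0, False),
        ("week9", RV, NA, 30.0, 0.0, 0.0, 76.0, False),    # -25%
    ])
    pt("P03", "left", [
        ("baseline", RV, NA, 35.0, 0.0, 0.0, 110.0, False),
        ("week3", RV, NA, 34.0, 0.0, 0.0, 108.0, False),
        ("week9", RV, NA, 30.0, 0.0, 0.0, 105.0, False),   # -14%
    ])
    pt("P04", "right", [
        ("baseline", RV, NA, 45.0, 0.0, 0.0, 90.0, False),
        ("week3", RV, NA, 45.0, 0.0, 0.0, 90.0, False),
        ("week9", RV, NA, 45.0, 0.0, 0.0, 90.0, False),    # no change
    ])
    # -- level 1 (3 patients); P05 improves to level 0
    pt("P05", "right", [
        ("baseline", IVC, 12.0, 40.0, 12.0, 8.0, 120.0, False),
        ("week3", IVC, 8.0, 35.0, 8.0, 6.0, 118.0, False),
        ("week9", RV, NA, 30.0, 0.0, 0.0, 115.0, False),   # -50%
    ])
    pt("P06", "left", [
        ("baseline", IVC, 15.0, 30.0, 15.0, 5.0, 70.0, False),
        ("week3", IVC, 14.0, 29.0, 14.0, 5.0, 70.0, False),
        ("week9", IVC, 13.0, 28.0, 13.0, 4.0, 69.0, False),  # -10%
    ])
    pt("P07", "right", [
        ("baseline", IVC, 10.0, 35.0, 10.0, 0.0, 95.0, False),
        ("week3", IVC, 11.0, 37.0, 11.0, 0.0, 96.0, False),
        ("week9", IVC, 12.0, 40.0, 12.0, 0.0, 97.0, False),  # +15.6% growth
    ])
    # -- level 2 (9 patients); P08, P09, P10 improve to level 1
    pt("P08", "left", [
        ("baseline", IVC, 45.0, 50.0, 45.0, 15.0, 130.0, False),
        ("week3", IVC, 30.0, 40.0, 30.0, 12.0, 120.0, False),
        ("week9", IVC, 15.0, 30.0, 15.0, 9.0, 88.0, False),  # -51%
    ])
    pt("P09", "right", [
        ("baseline", IVC, 60.0, 40.0, 60.0, 20.0, 140.0, False),
        ("week3", IVC, 45.0, 35.0, 45.0, 16.0, 135.0, False),
        ("week9", IVC, 18.0, 28.0, 18.0, 12.0, 130.0, False),  # -51.7%
    ])
    pt("P10", "left", [
        ("baseline", IVC, 30.0, 45.0, 30.0, 10.0, 100.0, False),
        ("week3", IVC, 24.0, 40.0, 24.0, 8.0, 98.0, False),
        ("week9", IVC, 10.0, 35.0, 10.0, 6.0, 96.0, False),  # -40%
    ])
    pt("P11", "right", [
        ("baseline", IVC, 50.0, 40.0, 50.0, 10.0, 85.0, False),
        ("week3", IVC, 47.0, 38.0, 47.0, 10.0, 85.0, False),
        ("week9", IVC, 44.0, 36.0, 44.0, 9.0, 84.0, False),  # -11%
    ])
    pt("P12", "left", [
        ("baseline", IVC, 70.0, 55.0, 70.0, 25.0, 150.0, False),
        ("week3", IVC, 66.0, 52.0, 66.0, 24.0, 148.0, False),
        ("week9", IVC, 62.0, 50.0, 62.0, 22.0, 146.0, False),  # -10.7%
    ])
    pt("P13", "right", [
        ("baseline", IVC, 40.0, 30.0, 40.0, 12.0, 75.0, False),
        ("week3", IVC, 39.0, 29.0, 39.0, 12.0, 75.0, False),
        ("week9", IVC, 38.0, 29.0, 38.0, 11.0, 74.0, False),  # -4.9%
    ])
    pt("P14", "left", [
        ("baseline", IVC, 55.0, 45.0, 55.0, 18.0, 105.0, False),
        ("week3", IVC, 53.0, 44.0, 53.0, 17.0, 104.0, False),
        ("week9", IVC, 52.0, 43.0, 52.0, 17.0, 103.0, False),  # -5.1%
    ])
    pt("P15", "right", [
        ("baseline", IVC, 35.0, 38.0, 35.0, 9.0, 92.0, False),
        ("week3", IVC, 37.0, 40.0, 37.0, 10.0, 93.0, False),
        ("week9", IVC, 40.0, 43.0, 40.0, 11.0, 94.0, False),  # +14.6% growth
    ])
    pt("P16", "left", [
        ("baseline", IVC, 65.0, 48.0, 65.0, 22.0, 125.0, False),
        ("week3", IVC, 67.0, 49.0, 67.0, 23.0, 126.0, True),
        ("week9", IVC, 72.0, 52.0, 72.0, 26.0, 128.0, True),  # +11.1% growth, PD
    ])
    # -- level 3 (2 patients); P17 improves to level 2
    pt("P17", "right", [
        ("baseline", HEP, NA, 55.0, 120.0, 25.0, 160.0, False),
        ("week3", HEP, NA, 50.0, 105.0, 22.0, 150.0, False),
        ("week9", IVC, 70.0, 40.0, 70.0, 16.0, 110.0, False),  # -37%
    ])
    pt("P18", "left", [
        ("baseline", HEP, NA, 45.0, 110.0, 20.0, 135.0, False),
        ("week3", HEP, NA, 44.0, 106.0, 20.0, 134.0, False),
        ("week9", HEP, NA, 42.0, 101.0, 18.0, 132.0, False),  # -8%
    ])
    # -- level 4 (2 patients); P19 improves to level 3
    pt("P19", "right", [
        ("baseline", DIA, NA, 60.0, 180.0, 30.0, 170.0, False),
        ("week3", DIA, NA, 55.0, 160.0, 27.0, 165.0, False),
        ("week9", HEP, NA, 45.0, 130.0, 20.0, 160.0, True),  # -27.8%, new lesion
    ])
    pt("P20", "left", [  # no week-9 scan: week-3 fallback, length growth
        ("baseline", DIA, NA, 55.0, 190.0, 28.0, 155.0, False),
        ("week3", DIA, NA, 60.0, 205.0, 32.0, 158.0, False),  # +8.8% growth
    ])

    assessments = pd.DataFrame(A, columns=ASSESSMENT_COLUMNS)

    S = []

    def surg(pid, planned, performed):
        S.append([pid, "planned", *planned])
        S.append([pid, "performed", *performed])

    # (approach, incision_rank, level_of_control, vvb, hca, pringle)
    surg("P01", ("open", 2, 1, False, False, False), ("open", 1, 1, False, False, False))
    surg("P02", ("open", 1, 1, False, False, False), ("open", 1, 1, False, False, False))
    surg("P03", ("open", 1, 1, False, False, False), ("minimally_invasive", 1, 1, False, False, False))
    surg("P04", ("open", 1, 1, False, False, False), ("open", 1, 1, False, False, False))
    surg("P05", ("open", 2, 2, False, False, False), ("open", 2, 1, False, False, False))
    surg("P06", ("open", 2, 2, False, False, False), ("open", 2, 2, False, False, False))
    surg("P07", ("open", 2, 2, False, False, False), ("open", 2, 2, False, False, False))
    surg("P08", ("open", 2, 3, False, False, False), ("minimally_invasive", 1, 2, False, False, False))
    surg("P09", ("open", 3, 3, False, False, False), ("open", 2, 3, False, False, False))
    surg("P10", ("open", 2, 2, False, False, False), ("open", 2, 1, False, False, False))
    surg("P12", ("open", 3, 3, False, False, False), ("open", 3, 3, False, False, False))
    surg("P13", ("open", 2, 3, False, False, False), ("open", 2, 3, False, False, False))
    surg("P14", ("open", 2, 3, False, False, False), ("open", 2, 3, False, False, False))
    surg("P15", ("open", 2, 3, False, False, False), ("open", 2, 3, False, False, False))
    surg("P16", ("open", 3, 3, False, False, False), ("open", 3, 3, False, False, False))
    surg("P17", ("open", 3, 5, True, False, False), ("open", 3, 3, False, False, False))
    surg("P18", ("open", 3, 4, False, False, False), ("open", 3, 4, False, False, False))
    surgery = pd.DataFrame(S, columns=SURGERY_COLUMNS)

    ae_rows = []
    for pid in [f"P{i:02d}" for i in range(1, 21)]:
        ae_rows.append([pid, "hypertension", 1 + (int(pid[1:]) % 3), True])
    for pid in ("P01", "P05", "P08", "P09", "P12", "P13", "P14", "P15", "P16", "P17", "P18", "P19", "P20"):
        ae_rows.append([pid, "fatigue", 1, True])
    for pid in ("P02", "P03", "P06", "P08", "P10", "P11", "P12", "P14", "P17", "P19"):
        ae_rows.append([pid, "proteinuria", 2 if pid in ("P08", "P17") else 1, True])
    for pid in ("P04", "P07", "P09", "P13"):
        ae_rows.append([pid, "mucositis", 3 if pid == "P09" else 1, True])
    ae = pd.DataFrame(ae_rows, columns=AE_COLUMNS)

    P = []
    sexes = ["male"] * 15 + ["female"] * 5
    for i, pid in enumerate([f"P{i:02d}" for i in range(1, 21)]):
        m_stage = "M1" if i % 2 == 0 and i < 18 else "M0"
        P.append([
            pid, True, True, False,
            49 + i + (i % 3), 70.0 + 2.0 * i, sexes[i], i % 2,
            m_stage, "intermediate" if m_stage == "M1" else "",
            round(0.8 + 0.02 * i, 2), 1.2, True, i % 2,
        ])
    patients = pd.DataFrame(P, columns=PATIENT_COLUMNS)

    cohort = Cohort(patients=patients, assessments=assessments, surgery=surgery, ae=ae)
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# validation and CSV round trip


def validate_cohort(cohort: Cohort) -> None:
    """Check every row against the documented schema; raise on violation."""
    errors: list[str] = []
    a = cohort.assessments
    for col in ASSESSMENT_COLUMNS:
        if col not in a.columns:
            errors.append(f"assessments: missing column {col!r}")
    if not errors:
        for idx, row in a.iterrows():
            where = f"assessments row {idx} (patient {row['patient_id']})"
            if row["timepoint"] not in _TIMEPOINTS:
                errors.append(f"{where}: unknown timepoint {row['timepoint']!r}")
            if row["side"] not in _SIDES:
                errors.append(f"{where}: unknown side {row['side']!r}")
            if row["tip_landmark"] not in _LANDMARKS:
                errors.append(f"{where}: unknown tip_landmark {row['tip_landmark']!r}")
            elif row["tip_landmark"] == TipLandmark.IVC.name and pd.isna(row["tip_distance_mm"]):
                errors.append(f"{where}: IVC landmark requires tip_distance_mm")
            elif (
                row["tip_landmark"] == TipLandmark.RV_LATERAL_TO_GONADAL.name
                and row["side"] != Side.LEFT.value
            ):
                errors.append(f"{where}: RV_LATERAL_TO_GONADAL on a right-sided thrombus")
            for col in ("rv_mm", "ivc_above_mm", "ivc_below_mm", "target_sum_mm"):
                v = row[col]
                if not pd.isna(v) and v < 0:
                    errors.append(f"{where}: negative {col}")
    for col in SURGERY_COLUMNS:
        if col not in cohort.surgery.columns:
            errors.append(f"surgery: missing column {col!r}")
    if "level_of_control" in cohort.surgery.columns:
        for idx, row in cohort.surgery.iterrows():
            if row["phase"] not in ("planned", "performed"):
                errors.append(f"surgery row {idx}: unknown phase {row['phase']!r}")
            if not 1 <= row["level_of_control"] <= 6:
                errors.append(f"surgery row {idx}: level_of_control out of 1..6")
            if row["approach"] not in ("open", "minimally_invasive"):
                errors.append(f"surgery row {idx}: unknown approach {row['approach']!r}")
    if "grade" in cohort.ae.columns:
        for idx, row in cohort.ae.iterrows():
            if not 1 <= row["grade"] <= 5:
                errors.append(f"ae row {idx}: grade outside 1..5")
    if errors:
        raise CohortSchemaError("; ".join(errors))


_BOOL_COLS = {
    "new_lesion",
    "venovenous_bypass",
    "hypothermic_cardiac_arrest",
    "pringle",
    "related",
    "registered",
    "received_dose",
    "central_review_excluded",
    "biopsy_ccrcc",
}


def _frame_to_csv(df: pd.DataFrame) -> str:
    out = df.copy()
    for col in out.columns:
        if col in _BOOL_COLS:
            out[col] = out[col].map({True: "true", False: "false"})
    return out.to_csv(index=False, lineterminator="\n")


def _frame_from_csv(text: str, columns: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(io.StringIO(text), dtype={c: str for c in _BOOL_COLS})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{name}: empty cohort file", stacklevel=3)
        return pd.DataFrame(columns=columns)
    if df.empty and list(df.columns) != columns:
        warnings.warn(f"{name}: empty cohort file", stacklevel=3)
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{name}: missing columns {missing}")
    for col in df.columns:
        if col in _BOOL_COLS:
            bad = ~df[col].isin(["true", "false"]) & df[col].notna()
            if bad.any():
                rows = list(df.index[bad])
                raise CohortSchemaError(f"{name}: non-boolean value in {col!r} at rows {rows}")
            df[col] = df[col].map({"true": True, "false": False})
    if "mskcc_risk" in df.columns:
        df["mskcc_risk"] = df["mskcc_risk"].fillna("")
    return df[columns]


_FILES = {
    "patients": ("patients.csv", PATIENT_COLUMNS),
    "assessments": ("assessments.csv", ASSESSMENT_COLUMNS),
    "surgery": ("surgery.csv", SURGERY_COLUMNS),
    "ae": ("ae.csv", AE_COLUMNS),
}


def write_cohort(cohort: Cohort, directory) -> None:
    """Serialize a cohort to ``<directory>/{patients,assessments,surgery,ae}.csv``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _) in _FILES.items():
        (directory / fname).write_text(_frame_to_csv(getattr(cohort, attr)))


def read_cohort(directory) -> Cohort:
    """Load a cohort written by :func:`write_cohort`; validates every row."""
    from pathlib import Path

    directory = Path(directory)
    frames = {}
    for attr, (fname, columns) in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise CohortSchemaError(f"missing cohort file: {path}")
        frames[attr] = _frame_from_csv(path.read_text(), columns, fname)
    cohort = Cohort(**frames)
    validate_cohort(cohort)
    return cohort
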