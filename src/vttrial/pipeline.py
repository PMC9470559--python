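"""End-to-end trial analysis over a cohort.

Derives the primary endpoint (Mayo-level improvement, with the week-3
fallback when the week-9 scan is missing), applies the two-stage design
decision rule and design-adjusted inference, derives the secondary
endpoints (percent change in thrombus length, the >30% thrombus partial
response, RECIST target-lesion response, planned-vs-performed surgical
change), builds the CONSORT population counts and the adverse-event
table, and serializes everything as a deterministic JSON report.

Denominators are computed from data presence, never hard-coded: the Mayo
and length endpoints run over patients with a usable follow-up scan,
RECIST over patients with week-9 target-lesion data, surgical change over
operated patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, read_cohort
from .design import TwoStageDesign
from .endpoints import (
    ImprovementCall,
    LesionMeasurements,
    RecistCategory,
    Side,
    SurgicalChangeCall,
    SurgicalPlanRecord,
    Timepoint,
    TipLandmark,
    VTTAssessment,
    VTTLengths,
    mayo_improvement,
    recist_classify,
    surgical_change,
    vtt_percent_change,
    vtt_response,
)
from .inference import InferenceResult, TrialOutcome, infer

log = logging.getLogger(__name__)

__all__ = [
    "TrialConfig",
    "TrialReport",
    "derive_primary",
    "derive_secondary",
    "consort_accounting",
    "ae_summary",
    "run_trial_analysis",
    "round_percent",
]


@dataclass(frozen=True)
class TrialConfig:
    """Design and inference configuration for the analysis."""

    design: TwoStageDesign = TwoStageDesign(r1=0, n1=13, r=2, n=20)
    p0: float = 0.05
    conf_level: float = 0.80
    ae_min_fraction: float = 0.10


def round_percent(x: float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals, as percentages are reported."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _assessment_from_row(row: pd.Series) -> VTTAssessment:
    d = row["tip_distance_mm"]
    return VTTAssessment(
        side=Side(row["side"]),
        tip_landmark=TipLandmark[row["tip_landmark"]],
        tip_distance_above_ostium=None if pd.isna(d) else float(d),
        timepoint=Timepoint(row["timepoint"]),
    )


def _lengths_from_row(row: pd.Series) -> VTTLengths:
    return VTTLengths(
        rv_mm=float(row["rv_mm"]),
        ivc_above_mm=float(row["ivc_above_mm"]),
        ivc_below_mm=float(row["ivc_below_mm"]),
    )


def _rows_by_patient(assessments: pd.DataFrame) -> dict[str, dict[str, pd.Series]]:
    out: dict[str, dict[str, pd.Series]] = {}
    for _, row in assessments.iterrows():
        out.setdefault(row["patient_id"], {})[row["timepoint"]] = row
    return out


def _followup_row(rows: dict[str, pd.Series], deviations: list[str], pid: str):
    """Week-9 row, falling back to week 3 when week 9 is missing."""
    if "week9" in rows:
        return rows["week9"]
    if "week3" in rows:
        deviations.append(f"{pid}: no week-9 scan, week-3 scan used")
        return rows["week3"]
    return None


def derive_primary(cohort: Cohort, config: TrialConfig) -> dict:
    """Primary endpoint: Mayo improvement counts, decision rule, inference."""
    deviations: list[str] = []
    calls: dict[str, str] = {}
    non_evaluable: list[str] = []
    by_patient = _rows_by_patient(cohort.assessments)
    for pid in cohort.patient_ids():
        rows = by_patient.get(pid, {})
        if "baseline" not in rows:
            non_evaluable.append(pid)
            deviations.append(f"{pid}: no baseline assessment")
            continue
        follow = _followup_row(rows, deviations, pid)
        if follow is None:
            non_evaluable.append(pid)
            deviations.append(f"{pid}: no follow-up assessment")
            continue
        call = mayo_improvement(_assessment_from_row(rows["baseline"]), _assessment_from_row(follow))
        calls[pid] = call.value
    evaluable = len(calls)
    if evaluable == 0:
        raise ValueError("primary endpoint: no evaluable patients")
    improved = sum(1 for c in calls.values() if c == ImprovementCall.IMPROVED.value)
    worsened = sum(1 for c in calls.values() if c == ImprovementCall.WORSENED.value)
    stable = evaluable - improved - worsened
    design = config.design
    if evaluable != design.n:
        # planned (r1, n1) retained with the attained stage-2 size
        if evaluable <= design.n1:
            raise ValueError(
                f"evaluable count {evaluable} does not exceed stage-1 size {design.n1}; "
                "inference under the planned two-stage rule is undefined"
            )
        deviations.append(
            f"attained sample size {evaluable} differs from planned {design.n}; "
            "inference uses the attained stage-2 size"
        )
        design = TwoStageDesign(r1=design.r1, n1=design.n1, r=design.r, n=evaluable)
    outcome = TrialOutcome(total_responses=improved, stopped_stage1=False) if improved > design.r1 else TrialOutcome(
        total_responses=improved, stopped_stage1=True, stage1_responses=improved
    )
    inference = infer(outcome, design, config.p0, config.conf_level)
    return {
        "evaluable": evaluable,
        "non_evaluable": len(non_evaluable),
        "improved": improved,
        "stable": stable,
        "worsened": worsened,
        "proportion_improved_pct": round_percent(100.0 * improved / evaluable),
        "trial_success": improved > design.r,
        "inference": {
            "estimate_pct": round_percent(100.0 * inference.estimate),
            "umvue_pct": round_percent(100.0 * inference.umvue),
            "ci_lower_pct": round_percent(100.0 * inference.ci_lower),
            "ci_upper_pct": round_percent(100.0 * inference.ci_upper),
            "conf_level": config.conf_level,
            "p_value": float(f"{inference.p_value:.4g}"),
        },
        "calls": calls,
        "deviations": deviations,
    }


def _percent_changes(cohort: Cohort, timepoint: str, fallback: bool, deviations: list[str]):
    """Per-patient percent VTT length change at a timepoint (mm sums)."""
    changes: dict[str, float] = {}
    by_patient = _rows_by_patient(cohort.assessments)
    for pid in cohort.patient_ids():
        rows = by_patient.get(pid, {})
        if "baseline" not in rows:
            continue
        row = rows.get(timepoint)
        if row is None and fallback:
            row = _followup_row(rows, deviations, pid)
        if row is None:
            continue
        baseline = _lengths_from_row(rows["baseline"])
        try:
            changes[pid] = vtt_percent_change(baseline, _lengths_from_row(row))
        except ValueError:
            deviations.append(f"{pid}: zero baseline thrombus length, change undefined")
    return changes


def _median_range(values) -> dict:
    if not values:
        return {"n": 0, "median_pct": None, "min_pct": None, "max_pct": None}
    arr = np.asarray(sorted(values), dtype=float)
    return {
        "n": int(arr.size),
        "median_pct": round_percent(float(np.median(arr))),
        "min_pct": round_percent(float(arr.min())),
        "max_pct": round_percent(float(arr.max())),
    }


def derive_secondary(cohort: Cohort, config: TrialConfig) -> dict:
    """Secondary endpoints: length change, VTT-PR, RECIST, surgical change."""
    deviations: list[str] = []
    week3 = _percent_changes(cohort, "week3", fallback=False, deviations=deviations)
    week9 = _percent_changes(cohort, "week9", fallback=False, deviations=deviations)
    # the length endpoint itself uses the week-3 fallback, like the primary
    week9_fb = _percent_changes(cohort, "week9", fallback=True, deviations=deviations)

    any_reduction = sum(1 for v in week9_fb.values() if v > 0)
    vtt_pr = sum(1 for v in week9.values() if vtt_response(v))

    recist_counts = {c.value: 0 for c in RecistCategory}
    recist_n = 0
    by_patient = _rows_by_patient(cohort.assessments)
    for pid in cohort.patient_ids():
        rows = by_patient.get(pid, {})
        if "baseline" not in rows or "week9" not in rows:
            continue
        sums = {
            tp: LesionMeasurements(
                target_sum_mm=float(rows[tp]["target_sum_mm"]),
                new_lesion=bool(rows[tp]["new_lesion"]),
            )
            for tp in rows
            if not pd.isna(rows[tp]["target_sum_mm"])
        }
        if "baseline" not in sums or "week9" not in sums:
            continue
        nadir_mm = min(m.target_sum_mm for tp, m in sums.items() if tp != "week9")
        cat = recist_classify(sums["baseline"], sums["week9"], LesionMeasurements(nadir_mm))
        recist_counts[cat.value] += 1
        recist_n += 1

    surgical = {c.value: 0 for c in SurgicalChangeCall}
    operated = 0
    by_phase: dict[str, dict[str, pd.Series]] = {}
    for _, row in cohort.surgery.iterrows():
        by_phase.setdefault(row["patient_id"], {})[row["phase"]] = row

    def record(row: pd.Series) -> SurgicalPlanRecord:
        return SurgicalPlanRecord(
            approach=row["approach"],
            incision_rank=int(row["incision_rank"]),
            level_of_control=int(row["level_of_control"]),
            venovenous_bypass=bool(row["venovenous_bypass"]),
            hypothermic_cardiac_arrest=bool(row["hypothermic_cardiac_arrest"]),
            pringle=bool(row["pringle"]),
        )

    for pid in cohort.patient_ids():
        phases = by_phase.get(pid, {})
        if "planned" not in phases or "performed" not in phases:
            continue
        operated += 1
        result = surgical_change(record(phases["planned"]), record(phases["performed"]))
        surgical[result.call.value] += 1

    return {
        "length_change_week3": _median_range(list(week3.values())),
        "length_change_week9": _median_range(list(week9.values())),
        "any_length_reduction": {
            "count": any_reduction,
            "n": len(week9_fb),
            "pct": round_percent(100.0 * any_reduction / len(week9_fb)) if week9_fb else None,
        },
        "vtt_pr": {
            "count": vtt_pr,
            "n": len(week9),
            "pct": round_percent(100.0 * vtt_pr / len(week9)) if week9 else None,
        },
        "recist_week9": {**recist_counts, "n": recist_n},
        "surgical_change": {
            **surgical,
            "n_operated": operated,
            "less_extensive_pct": round_percent(100.0 * surgical["less_extensive"] / operated)
            if operated
            else None,
        },
        "deviations": deviations,
    }


def consort_accounting(patients: pd.DataFrame) -> dict:
    """CONSORT population counts from the registration table.

    ITT is everyone registered; the evaluable and safety populations are
    those who received at least one dose; eligible-and-evaluable removes
    central-review exclusions from the evaluable population.
    """
    itt = int(patients["registered"].sum())
    evaluable = int((patients["registered"] & patients["received_dose"]).sum())
    excluded = int(
        (
            patients["registered"]
            & patients["received_dose"]
            & patients["central_review_excluded"]
        ).sum()
    )
    return {
        "itt": itt,
        "safety": evaluable,
        "evaluable": evaluable,
        "eligible_and_evaluable": evaluable - excluded,
    }


def ae_summary(ae: pd.DataFrame, n_patients: int, min_fraction: float = 0.10) -> pd.DataFrame:
    """Per-term adverse-event table using each patient's maximum grade.

    Returns one row per term with the percentage of patients reporting the
    event at any grade and at grade 3, filtered to terms affecting at
    least ``min_fraction`` of patients.  ``n_patients`` is the safety
    denominator.
    """
    if ae.empty:
        return pd.DataFrame(columns=["term", "any_grade_pct", "grade3_pct"])
    if not ae["grade"].between(1, 5).all():
        bad = ae.loc[~ae["grade"].between(1, 5)]
        raise ValueError(f"adverse-event grades outside 1..5 at rows {list(bad.index)}")
    related = ae[ae["related"]]
    max_grade = related.groupby(["term", "patient_id"])["grade"].max().reset_index()
    rows = []
    for term, grp in max_grade.groupby("term"):
        frac_any = len(grp) / n_patients
        if frac_any < min_fraction:
            continue
        rows.append(
            {
                "term": term,
                "any_grade_pct": round_percent(100.0 * frac_any, 0),
                "grade3_pct": round_percent(100.0 * (grp["grade"] >= 3).sum() / n_patients, 0),
            }
        )
    rows.sort(key=lambda r: (-r["any_grade_pct"], r["term"]))
    return pd.DataFrame(rows, columns=["term", "any_grade_pct", "grade3_pct"])


@dataclass
class TrialReport:
    """Serializable container for the full analysis output."""

    consort: dict
    primary: dict
    secondary: dict
    ae_table: list[dict]
    deviations: list[str]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def run_trial_analysis(cohort: Cohort | str | Path, config: TrialConfig | None = None) -> TrialReport:
    """Full deterministic analysis: endpoints, decision rule, inference, tables.

    ``cohort`` may be an in-memory :class:`Cohort` or a directory written
    by :func:`vttrial.cohort.write_cohort`.
    """
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    config = config or TrialConfig()
    primary = derive_primary(cohort, config)
    secondary = derive_secondary(cohort, config)
    deviations = primary.pop("deviations") + secondary.pop("deviations")
    for d in deviations:
        log.warning("deviation: %s", d)
    ae = ae_summary(cohort.ae, n_patients=len(cohort.patients), min_fraction=config.ae_min_fraction)
    return TrialReport(
        consort=consort_accounting(cohort.patients),
        primary=primary,
        secondary=secondary,
        ae_table=ae.to_dict(orient="records"),
        deviations=sorted(set(deviations)),
    )
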