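"""Endpoint-rule tests: Mayo classification and improvement calls, thrombus
length arithmetic, RECIST v1.1 categories, surgical-approach comparison and
eligibility formulas, with property tests for the documented invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vttrial.endpoints import (
    ImprovementCall,
    LesionMeasurements,
    PatientBaseline,
    RecistCategory,
    Side,
    SurgicalChangeCall,
    SurgicalPlanRecord,
    TipLandmark,
    VTTAssessment,
    VTTLengths,
    classify_mayo,
    cockcroft_gault,
    eligibility_check,
    mayo_improvement,
    recist_classify,
    surgical_change,
    vtt_percent_change,
    vtt_response,
    vtt_sum,
)


def ivc(dist, side=Side.RIGHT):
    return VTTAssessment(side=side, tip_landmark=TipLandmark.IVC, tip_distance_above_ostium=dist)


def landmark(lm, side=Side.RIGHT):
    return VTTAssessment(side=side, tip_landmark=lm)


class TestClassifyMayo:
    @pytest.mark.parametrize(
        "assessment,expected",
        [
            (landmark(TipLandmark.RV_MAIN), 0),
            (landmark(TipLandmark.RV_BRANCHES), 0),
            (landmark(TipLandmark.RV_LATERAL_TO_GONADAL, Side.LEFT), 0),
            (ivc(15.0), 1),
            (ivc(19.9), 1),
            (ivc(20.0), 2),  # the 2 cm boundary belongs to level 2
            (ivc(55.0), 2),
            (landmark(TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM), 3),
            (landmark(TipLandmark.IVC_ABOVE_DIAPHRAGM), 4),
        ],
    )
    def test_levels(self, assessment, expected):
        assert classify_mayo(assessment) == expected

    def test_ivc_requires_tip_distance(self):
        with pytest.raises(ValueError, match="tip_distance"):
            VTTAssessment(side=Side.RIGHT, tip_landmark=TipLandmark.IVC)

    def test_gonadal_landmark_left_only(self):
        with pytest.raises(ValueError, match="left"):
            VTTAssessment(side=Side.RIGHT, tip_landmark=TipLandmark.RV_LATERAL_TO_GONADAL)

    @given(
        st.sampled_from(list(TipLandmark)),
        st.sampled_from(list(TipLandmark)),
        st.floats(0, 300),
        st.floats(0, 300),
    )
    def test_monotone_in_anatomical_extent(self, lm_a, lm_b, d_a, d_b):
        """A tip further craniad never classifies to a lower level."""

        def build(lm, d):
            return VTTAssessment(
                side=Side.LEFT,
                tip_landmark=lm,
                tip_distance_above_ostium=d if lm is TipLandmark.IVC else None,
            )

        a, b = build(lm_a, d_a), build(lm_b, d_b)
        craniad = (lm_a, d_a if lm_a is TipLandmark.IVC else 0.0) <= (
            lm_b,
            d_b if lm_b is TipLandmark.IVC else 0.0,
        )
        if craniad:
            assert classify_mayo(a) <= classify_mayo(b)


class TestMayoImprovement:
    def test_level_reduction_is_improvement(self):
        assert mayo_improvement(ivc(55.0), ivc(15.0)) is ImprovementCall.IMPROVED

    def test_gonadal_rule_left(self):
        base = landmark(TipLandmark.RV_MAIN, Side.LEFT)
        follow = landmark(TipLandmark.RV_LATERAL_TO_GONADAL, Side.LEFT)
        assert mayo_improvement(base, follow) is ImprovementCall.IMPROVED

    def test_gonadal_to_branches_left(self):
        base = landmark(TipLandmark.RV_LATERAL_TO_GONADAL, Side.LEFT)
        follow = landmark(TipLandmark.RV_BRANCHES, Side.LEFT)
        assert mayo_improvement(base, follow) is ImprovementCall.IMPROVED

    def test_right_sided_improvement_needs_branches(self):
        base = landmark(TipLandmark.RV_MAIN, Side.RIGHT)
        follow = landmark(TipLandmark.RV_BRANCHES, Side.RIGHT)
        assert mayo_improvement(base, follow) is ImprovementCall.IMPROVED

    def test_identical_assessments_stable(self):
        assert mayo_improvement(ivc(30.0), ivc(30.0)) is ImprovementCall.STABLE

    def test_extension_into_ivc_worsens_level0(self):
        base = landmark(TipLandmark.RV_MAIN)
        assert mayo_improvement(base, ivc(10.0)) is ImprovementCall.WORSENED

    def test_craniad_move_within_rv_is_stable(self):
        base = landmark(TipLandmark.RV_BRANCHES)
        follow = landmark(TipLandmark.RV_MAIN)
        assert mayo_improvement(base, follow) is ImprovementCall.STABLE

    def test_side_mismatch_rejected(self):
        with pytest.raises(ValueError, match="side"):
            mayo_improvement(ivc(30.0, Side.LEFT), ivc(10.0, Side.RIGHT))

    @given(
        st.sampled_from(
            [
                TipLandmark.IVC,
                TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,
                TipLandmark.IVC_ABOVE_DIAPHRAGM,
            ]
        ),
        st.sampled_from(
            [
                TipLandmark.IVC,
                TipLandmark.IVC_AT_OR_ABOVE_HEPATIC_BELOW_DIAPHRAGM,
                TipLandmark.IVC_ABOVE_DIAPHRAGM,
            ]
        ),
        st.floats(0, 300),
        st.floats(0, 300),
    )
    def test_antisymmetric_above_level_zero(self, lm_a, lm_b, d_a, d_b):
        """Swapping baseline and follow-up flips improved/worsened for
        IVC-level thrombi (the level-0 sub-level rules are intentionally
        one-directional and are excluded)."""

        def build(lm, d):
            return VTTAssessment(
                side=Side.RIGHT,
                tip_landmark=lm,
                tip_distance_above_ostium=d if lm is TipLandmark.IVC else None,
            )

        a, b = build(lm_a, d_a), build(lm_b, d_b)
        forward, backward = mayo_improvement(a, b), mayo_improvement(b, a)
        flip = {
            ImprovementCall.IMPROVED: ImprovementCall.WORSENED,
            ImprovementCall.WORSENED: ImprovementCall.IMPROVED,
            ImprovementCall.STABLE: ImprovementCall.STABLE,
        }
        assert backward is flip[forward]


class TestLengths:
    @pytest.mark.parametrize(
        "lengths,expected",
        [(VTTLengths(10, 0, 0), 10), (VTTLengths(10, 25, 5), 40)],
    )
    def test_vtt_sum(self, lengths, expected):
        assert vtt_sum(lengths) == expected

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            VTTLengths(-1, 0, 0)

    @pytest.mark.parametrize(
        "sum0,sumT,expected",
        [((40, 0, 0), (20, 0, 0), 50.0), ((10, 20, 10), (10, 20, 10), 0.0), ((40, 0, 0), (0, 0, 0), 100.0)],
    )
    def test_percent_change(self, sum0, sumT, expected):
        assert vtt_percent_change(VTTLengths(*sum0), VTTLengths(*sumT)) == pytest.approx(expected)

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            vtt_percent_change(VTTLengths(0, 0, 0), VTTLengths(5, 0, 0))

    @given(
        st.floats(0.1, 500),
        st.floats(0, 500),
        st.floats(0, 500),
        st.floats(0, 500),
        st.floats(0.001, 1000),
    )
    def test_scale_invariance(self, rv0, ab0, rvT, abT, c):
        base, follow = VTTLengths(rv0, ab0, 0), VTTLengths(rvT, abT, 0)
        scaled = vtt_percent_change(
            VTTLengths(rv0 * c, ab0 * c, 0), VTTLengths(rvT * c, abT * c, 0)
        )
        assert scaled == pytest.approx(vtt_percent_change(base, follow), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("pct,expected", [(51.0, True), (30.0, False), (-20.0, False)])
    def test_vtt_response_strict_threshold(self, pct, expected):
        assert vtt_response(pct) is expected


class TestRecist:
    def test_pr_at_30_percent_decrease(self):
        assert (
            recist_classify(
                LesionMeasurements(100), LesionMeasurements(70), LesionMeasurements(70)
            )
            is RecistCategory.PR
        )

    def test_pd_from_nadir_growth(self):
        assert (
            recist_classify(
                LesionMeasurements(100), LesionMeasurements(61), LesionMeasurements(50)
            )
            is RecistCategory.PD
        )

    def test_stable_disease(self):
        assert (
            recist_classify(
                LesionMeasurements(100), LesionMeasurements(95), LesionMeasurements(95)
            )
            is RecistCategory.SD
        )

    def test_cr_requires_zero_sum(self):
        assert (
            recist_classify(
                LesionMeasurements(100), LesionMeasurements(0), LesionMeasurements(0)
            )
            is RecistCategory.CR
        )

    @given(st.floats(0, 200), st.floats(0, 200), st.floats(0, 200))
    def test_new_lesion_always_pd(self, b, c, nd):
        result = recist_classify(
            LesionMeasurements(b),
            LesionMeasurements(c, new_lesion=True),
            LesionMeasurements(min(nd, b)),
        )
        assert result is RecistCategory.PD


def plan(approach="open", rank=2, level=3):
    return SurgicalPlanRecord(approach=approach, incision_rank=rank, level_of_control=level)


class TestSurgicalChange:
    def test_supradiaphragmatic_downstage(self):
        result = surgical_change(plan(level=6), plan(level=3))
        assert result.call is SurgicalChangeCall.LESS_EXTENSIVE
        assert result.lower_level_of_control

    def test_milked_into_rv(self):
        result = surgical_change(plan(level=2), plan(level=1))
        assert result.call is SurgicalChangeCall.LESS_EXTENSIVE

    def test_open_to_minimally_invasive(self):
        result = surgical_change(plan("open"), plan("minimally_invasive"))
        assert result.call is SurgicalChangeCall.LESS_EXTENSIVE
        assert result.open_to_minimally_invasive

    def test_more_extensive(self):
        result = surgical_change(plan(level=2), plan(level=4))
        assert result.call is SurgicalChangeCall.MORE_EXTENSIVE

    @given(
        st.sampled_from(["open", "minimally_invasive"]),
        st.integers(0, 5),
        st.integers(1, 6),
    )
    def test_identity_is_unchanged(self, approach, rank, level):
        record = plan(approach, rank, level)
        assert surgical_change(record, record).call is SurgicalChangeCall.UNCHANGED

    def test_level_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            plan(level=7)


class TestEligibility:
    def test_cockcroft_gault_example(self):
        assert cockcroft_gault(70, 80, "male", 1.0) == pytest.approx(77.78, abs=0.01)

    def test_female_factor(self):
        m = cockcroft_gault(60, 70, "male", 1.1)
        f = cockcroft_gault(60, 70, "female", 1.1)
        assert f / m == pytest.approx(0.85)

    @given(st.floats(20, 100), st.floats(40, 150), st.floats(0.3, 5))
    def test_creatinine_homogeneity(self, age, weight, cr):
        assert cockcroft_gault(age, weight, "male", 2 * cr) == pytest.approx(
            cockcroft_gault(age, weight, "male", cr) / 2
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cockcroft_gault(0, 80, "male", 1.0)

    def _complete(self, **overrides):
        base = dict(
            age=65,
            weight=80,
            sex="male",
            ecog=0,
            urinalysis_protein_plus=0,
            serum_creatinine=1.0,
            creatinine_uln=1.2,
            biopsy_ccrcc=True,
            m_stage="M0",
        )
        base.update(overrides)
        return PatientBaseline(**base)

    def test_all_normal_eligible(self):
        result = eligibility_check(self._complete())
        assert result.eligible and not result.violations

    def test_m1_poor_risk_ineligible(self):
        result = eligibility_check(self._complete(m_stage="M1", mskcc_risk="poor"))
        assert not result.eligible
        assert "mskcc_not_poor_if_m1" in result.violations

    def test_both_renal_criteria_failing(self):
        # creatinine 2 x ULN and Cockcroft-Gault below 30 mL/min
        result = eligibility_check(self._complete(age=90, weight=45, serum_creatinine=2.4))
        assert not result.eligible
        assert "renal_function_adequate" in result.violations

    def test_single_renal_criterion_suffices(self):
        # high creatinine but preserved calculated clearance
        result = eligibility_check(self._complete(age=40, weight=110, serum_creatinine=1.9))
        assert result.eligible

    def test_missing_fields_indeterminate_not_failed(self):
        result = eligibility_check(PatientBaseline(age=70, ecog=1))
        assert result.eligible
        assert "proteinuria_below_threshold" in result.indeterminate
        assert "renal_function_adequate" in result.indeterminate
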