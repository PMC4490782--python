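import numpy as np
import pandas as pd
import pytest

from claimsignal.claims_model import StudyConfig, ValidationError
from claimsignal.cohort import (
    assign_untreated_index,
    build_indexed,
    build_person_weeks,
    compute_baseline,
    find_eligible,
)
from claimsignal.exposure import incident_courses
from conftest import make_bundle

CFG = StudyConfig()


def indexed_frame(*rows):
    return pd.DataFrame(rows, columns=["subject_id", "arm", "index_day"])


class TestFindEligible:
    def test_age_rule(self):
        b = make_bundle(
            medical=[(1, 100, "D01", "outpatient"), (2, 100, "D01", "outpatient")],
            enrollment=[(1, 0, 36), (2, 0, 36)],
            subjects=[(1, 1954, "F"), (2, 1930, "M")],  # subject 1 is 48.8 at claim
        )
        out = find_eligible(b, CFG)
        assert list(out.subject_id) == [2]

    def test_first_dementia_day_recorded(self):
        b = make_bundle(
            medical=[(1, 300, "D02", "outpatient"), (1, 120, "D01", "inpatient")],
            enrollment=[(1, 0, 36)],
        )
        out = find_eligible(b, CFG)
        assert out.iloc[0].first_dementia_day == 120

    def test_comorbidity_only_codes_do_not_qualify(self):
        b = make_bundle(
            medical=[(1, 100, "C01", "outpatient")], enrollment=[(1, 0, 36)]
        )
        assert len(find_eligible(b, CFG)) == 0


class TestUntreatedIndex:
    def test_first_visit_with_observed_baseline_wins(self):
        b = make_bundle(
            medical=[(1, 100, "D01", "outpatient"), (1, 250, "D01", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        assert assign_untreated_index(1, b, CFG) == 250

    def test_inpatient_only_dementia_claims_give_no_index(self):
        b = make_bundle(
            medical=[(1, 250, "D01", "inpatient"), (1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        assert assign_untreated_index(1, b, CFG) is None

    def test_visit_with_empty_baseline_skipped(self):
        # day-200 visit has no claim in its baseline; day-350 visit qualifies
        # because the day-200 dementia visit falls in its baseline
        b = make_bundle(
            medical=[(1, 200, "D01", "outpatient"), (1, 350, "D01", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        assert assign_untreated_index(1, b, CFG) == 350

    def test_enrollment_gap_in_baseline_disqualifies(self):
        b = make_bundle(
            medical=[(1, 100, "C00", "outpatient"), (1, 250, "D01", "outpatient")],
            enrollment=[(1, 0, 3), (1, 5, 36)],  # month 4 = days 120-149 missing
        )
        assert assign_untreated_index(1, b, CFG) is None


class TestBuildIndexed:
    def test_arms_disjoint_and_prevalent_in_neither(self):
        b = make_bundle(
            pharmacy=[(1, 200, 30, "ACHEI"), (3, 50, 30, "ACHEI")],
            medical=[
                (1, 100, "D01", "outpatient"),
                (2, 250, "D01", "outpatient"), (2, 100, "C00", "outpatient"),
                (3, 250, "D01", "outpatient"), (3, 100, "C00", "outpatient"),
            ],
            enrollment=[(1, 0, 36), (2, 0, 36), (3, 0, 36)],
        )
        courses = incident_courses(b, CFG)
        out = build_indexed(b, find_eligible(b, CFG), courses, CFG)
        assert out.set_index("subject_id").arm.to_dict() == {1: "treated", 2: "untreated"}
        # subject 3: prevalent user, excluded from both arms
        assert 3 not in set(out.subject_id)

    def test_excluded_class_user_not_untreated(self):
        b = make_bundle(
            pharmacy=[(2, 300, 30, "MEMANTINE")],
            medical=[(2, 250, "D01", "outpatient"), (2, 100, "C00", "outpatient")],
            enrollment=[(2, 0, 36)],
        )
        out = build_indexed(b, find_eligible(b, CFG), incident_courses(b, CFG), CFG)
        assert len(out) == 0


class TestComputeBaseline:
    def test_empty_baseline_all_zero(self):
        b = make_bundle(
            medical=[(1, 250, "D01", "outpatient")], enrollment=[(1, 0, 36)],
            subjects=[(1, 1930, "M")],
        )
        out = compute_baseline(b, indexed_frame((1, "untreated", 250)), CFG)
        row = out.iloc[0]
        assert row.comorbidity_count == 0 and row.n_clinic_visits == 0
        assert row.statin == 0 and row.female == 0
        assert row.age == pytest.approx(2003 - 1930 - 0.5 + 250 / 365.25)

    def test_distinct_comorbidity_groups_counted(self):
        b = make_bundle(
            medical=[
                (1, 100, "C01", "outpatient"),
                (1, 110, "C01", "outpatient"),
                (1, 120, "C02", "outpatient"),
            ],
            enrollment=[(1, 0, 36)],
        )
        out = compute_baseline(b, indexed_frame((1, "untreated", 250)), CFG)
        assert out.iloc[0].comorbidity_count == 2

    def test_baseline_is_index_exclusive(self):
        # statin dispensed on the index day itself does not flag
        b = make_bundle(
            pharmacy=[(1, 250, 90, "STATIN")],
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        out = compute_baseline(b, indexed_frame((1, "untreated", 250)), CFG)
        assert out.iloc[0].statin == 0
        b2 = make_bundle(
            pharmacy=[(1, 249, 90, "STATIN")],
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        out2 = compute_baseline(b2, indexed_frame((1, "untreated", 250)), CFG)
        assert out2.iloc[0].statin == 1

    def test_baseline_outcome_flag(self):
        b = make_bundle(
            medical=[(1, 200, "G01", "outpatient")], enrollment=[(1, 0, 36)]
        )
        out = compute_baseline(b, indexed_frame((1, "untreated", 250)), CFG)
        assert out.iloc[0].baseline_gastrointestinal == 1
        assert out.iloc[0].baseline_hepatic == 0

    def test_duplicate_index_rejected(self):
        b = make_bundle(medical=[(1, 100, "C00", "outpatient")], enrollment=[(1, 0, 36)])
        with pytest.raises(ValidationError, match="overlapping"):
            compute_baseline(
                b, indexed_frame((1, "untreated", 250), (1, "treated", 300)), CFG
            )


class TestPersonWeeks:
    def test_death_censors_with_reason(self):
        b = make_bundle(
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
            death=[(1, 250 + 73)],  # week 10 of follow-up
        )
        pw, cen = build_person_weeks(
            indexed_frame((1, "untreated", 250)), b, pd.DataFrame(), CFG, ["death"]
        )
        assert cen.iloc[0].censor_reason == "death"
        assert cen.iloc[0].censor_week == 10
        assert pw.week.max() == 10
        assert pw.loc[pw.week == 10, "epstart_death"].iloc[0] == 1

    def test_temporary_gap_suspends_at_risk_but_not_follow_up(self):
        # months 10-11 (days 300-359) unenrolled, re-enrolled afterwards
        b = make_bundle(
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 9), (1, 12, 36)],
        )
        pw, cen = build_person_weeks(
            indexed_frame((1, "untreated", 250)), b, pd.DataFrame(), CFG, []
        )
        assert cen.iloc[0].censor_reason == "study_end"
        gap_weeks = pw[(pw.week >= 8) & (pw.week <= 14)]
        assert not gap_weeks.at_risk.all()
        assert pw[pw.week > 16].at_risk.all()

    def test_terminal_disenrollment_censors(self):
        b = make_bundle(
            medical=[(1, 100, "C00", "outpatient")], enrollment=[(1, 0, 12)]
        )
        pw, cen = build_person_weeks(
            indexed_frame((1, "untreated", 250)), b, pd.DataFrame(), CFG, []
        )
        assert cen.iloc[0].censor_reason == "disenrollment"
        assert cen.iloc[0].censor_day == 13 * 30 - 1

    def test_as_treated_censors_at_course_end(self):
        b = make_bundle(
            pharmacy=[(1, 250, 30, "ACHEI")],
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        courses = incident_courses(b, CFG)
        pw, cen = build_person_weeks(
            indexed_frame((1, "treated", 250)), b, courses, CFG, []
        )
        assert cen.iloc[0].censor_reason == "course_end"
        assert cen.iloc[0].censor_day == 250 + 29 + 60
        assert pw.exposed.all()

    def test_full_followup_mode_keeps_treated_past_course_end(self):
        cfg = StudyConfig(follow_up_mode="full_followup")
        b = make_bundle(
            pharmacy=[(1, 250, 30, "ACHEI")],
            medical=[(1, 100, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        courses = incident_courses(b, cfg)
        pw, cen = build_person_weeks(
            indexed_frame((1, "treated", 250)), b, courses, cfg, []
        )
        assert cen.iloc[0].censor_reason == "study_end"
        # exposed only while the course era is active (ends day 339, week 12)
        assert pw.loc[pw.week <= 11, "exposed"].all()
        assert not pw.loc[pw.week >= 14, "exposed"].any()

    def test_person_time_additivity_against_day_counter(self, sim_small, config):
        _, bundle, _ = sim_small
        courses = incident_courses(bundle, config)
        from claimsignal.cohort import find_eligible as fe

        indexed = build_indexed(bundle, fe(bundle, config), courses, config)
        pw, cen = build_person_weeks(indexed, bundle, courses, config, [])
        # brute-force day-level counter for a handful of subjects
        spans = bundle.enrollment.groupby("subject_id")
        for _, row in cen.head(8).iterrows():
            months = set()
            for _, sp in bundle.enrollment[bundle.enrollment.subject_id == row.subject_id].iterrows():
                months.update(range(sp.start_month, sp.end_month + 1))
            weeks = 0
            for w in range(row.censor_week + 1):
                a = row.index_day + 7 * w
                bday = min(a + 6, row.censor_day)
                if all(d // 30 in months for d in range(a, bday + 1)):
                    weeks += 1
            got = pw[(pw.subject_id == row.subject_id) & pw.at_risk]
            assert len(got) == weeks

    def test_arm_exclusivity_preserved(self):
        b = make_bundle(medical=[(1, 100, "C00", "outpatient")], enrollment=[(1, 0, 36)])
        with pytest.raises(ValidationError, match="overlapping"):
            build_person_weeks(
                indexed_frame((1, "untreated", 250), (1, "treated", 260)),
                b, pd.DataFrame(), CFG, [],
            )
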