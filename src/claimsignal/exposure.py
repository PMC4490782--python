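"""Drug-supply timelines, course segmentation, and incident-course selection.

A *supply timeline* turns dispensing claims into disjoint intervals of days on
which the subject is inferred to possess the drug.  Overlapping fills are
stockpiled: each dispensing contributes ``days_supply`` days starting at the
dispensing day or the day after the previous supply ran out, whichever is
later.  A *course* is a maximal run of supply not interrupted by a gap of
``course_gap_days`` or more, and persists ``course_tail_days`` past its last
supplied day.  The *incident* course is the first one preceded by a fully
observed, fully enrolled, drug-free washout containing at least one medical
claim — the new-user design's guard against prevalent-user bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _util
from .claims_model import ClaimsBundle, StudyConfig, day_to_week, month_of_day


@dataclass(frozen=True)
class SupplyTimeline:
    subject_id: object
    drug_class: str
    intervals: tuple  # ((first_day, last_day), ...) inclusive, disjoint, sorted

    def total_supplied_days(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)

    def overlaps(self, lo: int, hi: int) -> bool:
        """Any supplied day within [lo, hi]?"""
        return any(a <= hi and b >= lo for a, b in self.intervals)


@dataclass(frozen=True)
class DrugCourse:
    subject_id: object
    start_day: int
    start_week: int
    last_supplied_day: int
    end_day: int
    is_incident: bool = False


def build_supply_timeline(
    dispensings: pd.DataFrame,
    subject_id=None,
    drug_class: str | None = None,
) -> SupplyTimeline:
    """Reconstruct the supplied-day intervals for one subject and drug class.

    Dispensings need columns ``dispense_day`` and ``days_supply``; order does
    not matter.  Each fill begins at ``max(dispense_day, previous supply end
    + 1)`` so overlapping fills extend supply end-to-end (no cap).
    """
    if subject_id is None and len(dispensings):
        subject_id = dispensings["subject_id"].iloc[0]
    if drug_class is None and len(dispensings) and "drug_class" in dispensings:
        drug_class = dispensings["drug_class"].iloc[0]
    days = dispensings["dispense_day"].to_numpy()
    supply = dispensings["days_supply"].to_numpy()
    order = np.argsort(days, kind="stable")
    intervals: list = []
    prev_end = None
    for d, s in zip(days[order], supply[order]):
        start = int(d) if prev_end is None else max(int(d), prev_end + 1)
        end = start + int(s) - 1
        if intervals and start <= intervals[-1][1] + 1:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
        prev_end = end if prev_end is None else max(prev_end, end)
    return SupplyTimeline(
        subject_id=subject_id,
        drug_class=drug_class or "",
        intervals=tuple(tuple(iv) for iv in intervals),
    )


def segment_courses(
    timeline: SupplyTimeline,
    gap_days: int = 60,
    tail_days: int = 60,
    cap_day: int | None = None,
    week_days: int = 7,
) -> list:
    """Split a supply timeline into courses at zero-supply runs >= gap_days.

    ``end_day`` is the last supplied day of the course plus ``tail_days``,
    optionally truncated at ``cap_day`` (death, terminal disenrollment, or
    study end).
    """
    courses: list = []
    run: list = []
    for a, b in timeline.intervals:
        if run and a - run[-1][1] - 1 >= gap_days:
            courses.append(run)
            run = []
        run.append((a, b))
    if run:
        courses.append(run)
    out = []
    for run in courses:
        start = run[0][0]
        last = run[-1][1]
        end = last + tail_days
        if cap_day is not None:
            end = min(end, cap_day)
        out.append(
            DrugCourse(
                subject_id=timeline.subject_id,
                start_day=start,
                start_week=day_to_week(start, 0, week_days),
                last_supplied_day=last,
                end_day=max(end, start),
            )
        )
    return out


def select_incident_course(
    courses,
    excluded_timelines,
    enrolled_months,
    medical_claim_days,
    config: StudyConfig,
):
    """Return the first course qualifying as incident, or None.

    A course qualifies when its preceding ``washout_days`` window lies fully
    inside the study period, every overlapping month is enrolled, no supplied
    day of any excluded drug class falls in it, and it contains at least one
    medical claim.

    Parameters
    ----------
    courses : list of DrugCourse for the exposure class, in order
    excluded_timelines : iterable of SupplyTimeline for all excluded classes
    enrolled_months : set-like of enrolled month indices for the subject
    medical_claim_days : sorted array of the subject's medical-claim days
    """
    claim_days = np.asarray(medical_claim_days)
    for course in courses:
        lo = course.start_day - config.washout_days
        hi = course.start_day - 1
        if lo < config.study_start_day or hi > config.study_end_day:
            continue
        months = range(
            month_of_day(lo, config.month_length_days),
            month_of_day(hi, config.month_length_days) + 1,
        )
        if not all(m in enrolled_months for m in months):
            continue
        if any(t.overlaps(lo, hi) for t in excluded_timelines):
            continue
        n_claims = np.searchsorted(claim_days, hi, side="right") - np.searchsorted(
            claim_days, lo, side="left"
        )
        if n_claims < 1:
            continue
        return replace(course, is_incident=True)
    return None


def weekly_exposure(course: DrugCourse, timeline: SupplyTimeline, anchor_day: int):
    """Per-week supply coverage of a course on the anchor's weekly grid.

    Returns ``(weeks, covered, proportion)`` where ``weeks`` runs from the
    course's start week to its final supplied week (relative to
    ``anchor_day``), ``covered[w]`` is True iff at least one supplied day
    falls in that week, and ``proportion`` is the covered fraction.
    """
    in_course = [
        (max(a, course.start_day), min(b, course.last_supplied_day))
        for a, b in timeline.intervals
        if a <= course.last_supplied_day and b >= course.start_day
    ]
    if not in_course:
        raise ValueError("course inconsistent with timeline: no supplied days")
    w0 = day_to_week(course.start_day, anchor_day)
    w1 = day_to_week(course.last_supplied_day, anchor_day)
    weeks = np.arange(w0, w1 + 1)
    covered = np.zeros(len(weeks), dtype=bool)
    for a, b in in_course:
        covered[day_to_week(a, anchor_day) - w0 : day_to_week(b, anchor_day) - w0 + 1] = True
    return weeks, covered, covered.mean()


def incident_courses(bundle: ClaimsBundle, config: StudyConfig) -> pd.DataFrame:
    """Reconstruct exposure-class courses for every dispensed subject and flag
    the incident one.

    Course ends are truncated at death, terminal disenrollment, or study end.
    Returns one row per course: ``subject_id, start_day, start_week,
    last_supplied_day, end_day, is_incident``.
    """
    ph = bundle.pharmacy
    exp = ph[ph["drug_class"] == config.exposure_class]
    cols = ["subject_id", "start_day", "start_week", "last_supplied_day", "end_day", "is_incident"]
    if len(exp) == 0:
        return pd.DataFrame(columns=cols)

    index = _util.SubjectIndex(bundle.subjects["subject_id"])
    cum = _util.enrollment_cumulative(bundle.enrollment, index, config.n_months)
    last_day = _util.last_enrolled_day(
        bundle.enrollment, index, config.month_length_days, config.study_end_day
    )
    death_day = pd.Series(
        bundle.death["death_day"].to_numpy(), index=bundle.death["subject_id"]
    )
    claims_by_subject = {
        s: np.sort(g["service_day"].to_numpy())
        for s, g in bundle.medical.groupby("subject_id")
    }
    excl = ph[ph["drug_class"].isin(config.excluded_classes)]
    excl_groups = {k: g for k, g in excl.groupby(["subject_id", "drug_class"])}

    rows = []
    for subject, fills in exp.groupby("subject_id"):
        code = int(index.code([subject])[0])
        timeline = build_supply_timeline(fills, subject, config.exposure_class)
        cap = int(
            min(
                death_day.get(subject, np.iinfo(np.int64).max),
                last_day[code] if last_day[code] >= 0 else config.study_end_day,
                config.study_end_day,
            )
        )
        courses = segment_courses(
            timeline,
            config.course_gap_days,
            config.course_tail_days,
            cap_day=cap,
            week_days=config.week_length_days,
        )
        excluded_timelines = [
            build_supply_timeline(excl_groups[(subject, c)], subject, c)
            for c in config.excluded_classes
            if (subject, c) in excl_groups
        ]
        enrolled = {
            m
            for m in range(config.n_months)
            if cum[code, m + 1] - cum[code, m] == 1
        }
        incident = select_incident_course(
            courses,
            excluded_timelines,
            enrolled,
            claims_by_subject.get(subject, np.array([], dtype=np.int64)),
            config,
        )
        for c in courses:
            is_inc = incident is not None and c.start_day == incident.start_day
            rows.append(
                (subject, c.start_day, c.start_week, c.last_supplied_day, c.end_day, is_inc)
            )
    return pd.DataFrame(rows, columns=cols)
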