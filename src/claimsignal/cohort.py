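"""Cohort construction: eligibility, index dates, baseline covariates, and
the weekly person-time table.

The treated arm is the incident new-user cohort: follow-up starts at the
first dispensing of the incident course.  The untreated arm is indexed at the
first dementia-related *outpatient* visit that allows a fully observed,
fully enrolled 180-day baseline containing at least one medical claim — an
indicated population engaging the health-care system, without a dispensing
to anchor time zero.  Subjects with any anti-dementia dispensing who do not
qualify as incident users (prevalent users) belong to neither arm.

Person-time is discretized into 1-week bins anchored at each subject's index
day.  Weeks in temporary enrollment gaps carry no person-time but do not end
follow-up; only death, a terminal disenrollment (never re-established), the
study end, or — in as-treated mode — the end of the treated course censors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _util
from .claims_model import DEATH, ClaimsBundle, StudyConfig, ValidationError

CENSOR_PRIORITY = ("death", "disenrollment", "course_end", "study_end")


def find_eligible(bundle: ClaimsBundle, config: StudyConfig) -> pd.DataFrame:
    """Subjects with a dementia-group primary diagnosis at or above the
    minimum age; returns ``subject_id, first_dementia_day``.

    Age at a claim uses the mid-year convention: someone born in year B is
    ``(study_start_year - B) - 0.5 + day/365.25`` years old on study day
    ``day``.
    """
    dem_codes = bundle.code_map.codes_for_role("dementia")
    claims = bundle.medical[bundle.medical["primary_dx"].isin(dem_codes)]
    claims = claims.merge(bundle.subjects[["subject_id", "birth_year"]], on="subject_id")
    age = (
        (config.study_start_year - claims["birth_year"])
        - 0.5
        + claims["service_day"] / 365.25
    )
    claims = claims[age >= config.min_age]
    out = (
        claims.groupby("subject_id", as_index=False)["service_day"]
        .min()
        .rename(columns={"service_day": "first_dementia_day"})
    )
    return out


def _medical_keys(bundle, index: _util.SubjectIndex, mask=None):
    med = bundle.medical if mask is None else bundle.medical[mask]
    return _util.sorted_event_keys(index, med["subject_id"], med["service_day"])


def assign_untreated_indices(
    bundle: ClaimsBundle,
    candidates: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Index day for each untreated candidate, or no row if none qualifies.

    The index is the earliest outpatient dementia claim whose preceding
    ``washout_days`` form a baseline fully inside the study period, fully
    enrolled, and containing at least one medical claim.
    """
    index = _util.SubjectIndex(bundle.subjects["subject_id"])
    cum = _util.enrollment_cumulative(bundle.enrollment, index, config.n_months)
    all_keys = _medical_keys(bundle, index)

    dem_codes = bundle.code_map.codes_for_role("dementia")
    med = bundle.medical
    visits = med[
        med["primary_dx"].isin(dem_codes)
        & (med["setting"] == "outpatient")
        & med["subject_id"].isin(candidates["subject_id"])
    ]
    if len(visits) == 0:
        return pd.DataFrame(columns=["subject_id", "index_day"])
    day = visits["service_day"].to_numpy()
    codes = index.code(visits["subject_id"]).astype(int)
    lo = day - config.washout_days
    ok = lo >= config.study_start_day
    m1 = lo // config.month_length_days
    m2 = (day - 1) // config.month_length_days
    ok &= _util.fully_enrolled(cum, codes, m1, m2)
    ok &= _util.window_counts(all_keys, codes, lo, day - 1) >= 1
    q = visits.loc[ok, ["subject_id", "service_day"]]
    return (
        q.groupby("subject_id", as_index=False)["service_day"]
        .min()
        .rename(columns={"service_day": "index_day"})
    )


def assign_untreated_index(subject_id, bundle, config):
    """Single-subject convenience wrapper; returns index day or None."""
    out = assign_untreated_indices(
        bundle, pd.DataFrame({"subject_id": [subject_id]}), config
    )
    return int(out["index_day"].iloc[0]) if len(out) else None


def build_indexed(
    bundle: ClaimsBundle,
    eligible: pd.DataFrame,
    courses: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Assign arms and index days.

    Treated: eligible subjects with an incident exposure course (index at
    course start).  Untreated: eligible subjects with no dispensing of any
    excluded anti-dementia class and a qualifying dementia outpatient visit.
    Prevalent users fall in neither arm.
    """
    elig_ids = set(eligible["subject_id"])
    incident = courses[courses["is_incident"]] if len(courses) else courses
    treated = incident[incident["subject_id"].isin(elig_ids)] if len(incident) else incident
    treated_ids = set(treated["subject_id"]) if len(treated) else set()

    excluded_users = set(
        bundle.pharmacy.loc[
            bundle.pharmacy["drug_class"].isin(config.excluded_classes), "subject_id"
        ]
    )
    cand = eligible[~eligible["subject_id"].isin(excluded_users)]
    untreated = assign_untreated_indices(bundle, cand, config)

    both = treated_ids & set(untreated["subject_id"])
    if both:
        raise ValidationError(f"subjects assigned to both arms: {sorted(both)[:5]}")
    frames = []
    if len(treated):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": treated["subject_id"].to_numpy(),
                    "arm": "treated",
                    "index_day": treated["start_day"].to_numpy(),
                }
            )
        )
    if len(untreated):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": untreated["subject_id"].to_numpy(),
                    "arm": "untreated",
                    "index_day": untreated["index_day"].to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["subject_id", "arm", "index_day"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("subject_id", kind="mergesort").reset_index(drop=True)


def compute_baseline(
    bundle: ClaimsBundle, indexed: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Baseline covariates over the index-exclusive window
    ``[index_day - washout_days, index_day - 1]`` for every indexed subject.

    Columns: demographics (age, female), distinct-comorbidity-group count,
    distinct-drug-class count (rx_risk_proxy), utilization counts by setting,
    hospice/nursing-home/statin flags, per-class drug flags (``drug_<CLASS>``),
    per-comorbidity-group diagnosis flags (``dx_<group>``), and
    ``baseline_<outcome>`` flags for prior episodes of each outcome.
    """
    if indexed["subject_id"].duplicated().any():
        raise ValidationError("overlapping index assignments for one subject")
    out = indexed.reset_index(drop=True).copy()
    n = len(out)
    index = _util.SubjectIndex(bundle.subjects["subject_id"])
    codes = index.code(out["subject_id"]).astype(int)
    idx_day = out["index_day"].to_numpy()
    lo = idx_day - config.washout_days
    hi = idx_day - 1

    subj_attrs = bundle.subjects.set_index("subject_id")
    by = subj_attrs["birth_year"].reindex(out["subject_id"]).to_numpy()
    out["age"] = (config.study_start_year - by) - 0.5 + idx_day / 365.25
    out["female"] = (
        subj_attrs["sex"].reindex(out["subject_id"]).to_numpy() == "F"
    ).astype(int)

    med = bundle.medical
    for name, setting in (
        ("n_clinic_visits", "outpatient"),
        ("n_hospitalizations", "inpatient"),
        ("n_ed_visits", "emergency"),
    ):
        keys = _medical_keys(bundle, index, med["setting"] == setting)
        out[name] = _util.window_counts(keys, codes, lo, hi)
    for name, setting in (("hospice", "hospice"), ("nursing_home", "nursing_home")):
        keys = _medical_keys(bundle, index, med["setting"] == setting)
        out[name] = (_util.window_counts(keys, codes, lo, hi) >= 1).astype(int)

    # window bounds per subject, for claim-level joins
    win = pd.DataFrame({"subject_id": out["subject_id"], "_lo": lo, "_hi": hi})

    com_map = bundle.code_map.code_to_label("comorbidity")
    cm = med[["subject_id", "service_day", "primary_dx"]].merge(win, on="subject_id")
    cm = cm[(cm["service_day"] >= cm["_lo"]) & (cm["service_day"] <= cm["_hi"])]
    cm["group"] = cm["primary_dx"].map(com_map)
    cg = cm.dropna(subset=["group"]).drop_duplicates(["subject_id", "group"])
    counts = cg.groupby("subject_id").size()
    out["comorbidity_count"] = counts.reindex(out["subject_id"], fill_value=0).to_numpy()
    for g in bundle.code_map.labels("comorbidity"):
        flagged = set(cg.loc[cg["group"] == g, "subject_id"])
        out[f"dx_{g}"] = out["subject_id"].isin(flagged).astype(int)

    for g in config.outcome_groups:
        codes_g = bundle.code_map.codes(g)
        hit = cm[cm["primary_dx"].isin(codes_g)]
        out[f"baseline_{g}"] = out["subject_id"].isin(set(hit["subject_id"])).astype(int)

    ph = bundle.pharmacy[["subject_id", "dispense_day", "drug_class"]].merge(
        win, on="subject_id"
    )
    ph = ph[(ph["dispense_day"] >= ph["_lo"]) & (ph["dispense_day"] <= ph["_hi"])]
    pc = ph.drop_duplicates(["subject_id", "drug_class"])
    out["rx_risk_proxy"] = (
        pc.groupby("subject_id").size().reindex(out["subject_id"], fill_value=0).to_numpy()
    )
    for cls in config.drug_classes:
        users = set(pc.loc[pc["drug_class"] == cls, "subject_id"])
        out[f"drug_{cls}"] = out["subject_id"].isin(users).astype(int)
    out["statin"] = out["drug_STATIN"] if "drug_STATIN" in out else 0
    return out


def build_person_weeks(
    indexed: pd.DataFrame,
    bundle: ClaimsBundle,
    courses: pd.DataFrame,
    config: StudyConfig,
    groups,
    events: pd.DataFrame | None = None,
    episodes: pd.DataFrame | None = None,
):
    """Weekly person-time table with censoring.

    Returns ``(person_weeks, censor)``.  ``person_weeks`` has one row per
    subject-week from the index week to the censor week with ``at_risk``
    (False during enrollment-gap weeks), ``exposed``, and per-group
    ``event_<g>`` / ``epstart_<g>`` indicator columns; for the ``death``
    pseudo-group the indicator fires in the censor week when the censor
    reason is death.  ``censor`` has one row per subject with the censor day,
    week, and reason.
    """
    if indexed["subject_id"].duplicated().any():
        raise ValidationError("overlapping index assignments for one subject")
    idx = indexed.reset_index(drop=True)
    n = len(idx)
    sindex = _util.SubjectIndex(bundle.subjects["subject_id"])
    codes = sindex.code(idx["subject_id"]).astype(int)
    index_day = idx["index_day"].to_numpy()
    arm_treated = (idx["arm"] == "treated").to_numpy()
    wk_len = config.week_length_days

    BIG = np.int64(1 << 40)
    death_map = bundle.death.set_index("subject_id")["death_day"]
    death_day = death_map.reindex(idx["subject_id"]).fillna(BIG).to_numpy(dtype=np.int64)
    last_day = _util.last_enrolled_day(
        bundle.enrollment, sindex, config.month_length_days, config.study_end_day
    )[codes]
    term_day = np.where(last_day < config.study_end_day, last_day, BIG)

    course_end = np.full(n, BIG, dtype=np.int64)
    if config.follow_up_mode == "as_treated" and len(courses):
        inc = courses[courses["is_incident"]].set_index("subject_id")["end_day"]
        ce = inc.reindex(idx["subject_id"]).to_numpy()
        course_end = np.where(arm_treated & ~np.isnan(ce), np.nan_to_num(ce, nan=BIG), BIG).astype(np.int64)

    study_end = np.full(n, config.study_end_day, dtype=np.int64)
    cand = np.stack([death_day, term_day, course_end, study_end])
    censor_day = cand.min(axis=0)
    reason_order = np.array(["death", "disenrollment", "course_end", "study_end"])
    reason = reason_order[np.argmax(cand == censor_day[None, :], axis=0)]
    censor_day = np.maximum(censor_day, index_day)  # guard: degenerate follow-up
    censor_week = (censor_day - index_day) // wk_len

    n_weeks = censor_week + 1
    total = int(n_weeks.sum())
    row_start = np.concatenate([[0], np.cumsum(n_weeks)[:-1]])
    subj_row = np.repeat(np.arange(n), n_weeks)
    week = np.arange(total) - row_start[subj_row]

    a = index_day[subj_row] + week * wk_len
    b = np.minimum(a + wk_len - 1, censor_day[subj_row])
    cum = _util.enrollment_cumulative(bundle.enrollment, sindex, config.n_months)
    at_risk = _util.fully_enrolled(
        cum, codes[subj_row], a // config.month_length_days, b // config.month_length_days
    )

    if config.follow_up_mode == "as_treated":
        exposed = arm_treated[subj_row]
    else:
        inc_end = np.where(course_end < BIG, course_end, -1)
        if len(courses):
            inc = courses[courses["is_incident"]].set_index("subject_id")["end_day"]
            ce = inc.reindex(idx["subject_id"]).fillna(-1).to_numpy(dtype=np.int64)
        else:
            ce = np.full(n, -1, dtype=np.int64)
        exposed = arm_treated[subj_row] & (a <= ce[subj_row])

    pw = pd.DataFrame(
        {
            "subject_id": idx["subject_id"].to_numpy()[subj_row],
            "week": week,
            "at_risk": at_risk,
            "exposed": exposed,
        }
    )

    def _mark(df: pd.DataFrame, day_col: str, col: str):
        flags = np.zeros(total, dtype=np.int64)
        if df is not None and len(df):
            pos = pd.Series(np.arange(n), index=idx["subject_id"])
            r = pos.reindex(df["subject_id"]).to_numpy()
            keep = ~np.isnan(r)
            r = r[keep].astype(int)
            day = df[day_col].to_numpy()[keep]
            w = (day - index_day[r]) // wk_len
            inside = (w >= 0) & (w <= censor_week[r]) & (day <= censor_day[r])
            flat = row_start[r[inside]] + w[inside]
            np.add.at(flags, flat, 1)
        pw[col] = flags
        return flags

    for g in groups:
        if g == DEATH:
            flags = np.zeros(total, dtype=np.int64)
            is_death = reason == "death"
            flat = row_start + censor_week
            flags[flat[is_death]] = 1
            pw[f"event_{DEATH}"] = flags
            pw[f"epstart_{DEATH}"] = flags
            continue
        sub_e = events[events["group_label"] == g] if events is not None else None
        _mark(sub_e, "service_day", f"event_{g}")
        sub_p = episodes[episodes["group_label"] == g] if episodes is not None else None
        _mark(sub_p, "start_day", f"epstart_{g}")

    # a recorded event implies presence; force those weeks at risk
    flag_cols = [c for c in pw.columns if c.startswith(("event_", "epstart_"))]
    if flag_cols:
        pw["at_risk"] = pw["at_risk"] | (pw[flag_cols].to_numpy().sum(axis=1) > 0)

    censor = pd.DataFrame(
        {
            "subject_id": idx["subject_id"],
            "arm": idx["arm"],
            "index_day": index_day,
            "censor_day": censor_day,
            "censor_week": censor_week,
            "censor_reason": reason,
        }
    )
    return pw, censor
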