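"""Synthetic administrative-claims generator with known ground truth.

The simulator emulates the structure of state Medicaid fee-for-service data
for an older dementia-diagnosed population over a three-year study window:
monthly enrollment churn, pharmacy dispensings with days-supply, diagnosis-
coded visits across care settings, vital-records death dates, and treatment
assignment confounded by indication.

The confounding mechanism is a latent gamma frailty with mean 1.  Frailty
raises the number of chronic conditions, the probability of hospice care and
of death, and lowers the probability of statin use and of starting the study
drug — so untreated subjects are frailer than treated ones and a crude
comparison makes treatment look protective against death.  Outcome and death
processes are weekly Bernoulli hazards on a 1-week grid, multiplied by a
per-outcome exposure hazard ratio while a drug course (including its 60-day
tail) is active, and optionally by an extra acute multiplier during the first
exposed weeks.

Latent outcome events emit an index claim plus a geometric burst of 0-3
follow-up claims at 7-21-day offsets, so downstream episode clustering is
exercised; claims are only emitted while the subject is alive and enrolled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import (
    OUTCOME_GROUPS,
    ClaimsBundle,
    StudyConfig,
    ValidationError,
    default_code_map,
    normalize_enrollment,
)

PRESETS = ("null_all", "gi_effect", "frailty_death", "acute_transient")

_CONDITION_GROUPS = (
    "diabetes",
    "hypertension",
    "heart_failure",
    "renal",
    "pulmonary",
    "depression",
    "thyroid",
    "arthritis",
    "electrolyte",
    "vascular",
)
_CONDITION_BASE_P = np.array(
    [0.20, 0.25, 0.12, 0.06, 0.15, 0.18, 0.12, 0.15, 0.08, 0.10]
)
_DRUG_USER_CLASSES = (
    "ANTIDEP",
    "ANTIPSYCH",
    "ANXIO",
    "ANTICONV",
    "NARC",
    "SEDATIVE",
    "STEROID",
    "NSAID",
    "GASTROPROT",
)
_DRUG_USER_BASE = np.array([0.55, 0.35, 0.30, 0.22, 0.42, 0.15, 0.10, 0.35, 0.32])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class OutcomeModel:
    """Weekly hazard model for one outcome group."""

    h0: float  # baseline weekly hazard at age 77, one comorbidity, frailty 1
    hr: float = 1.0  # exposure hazard ratio while a course is active
    beta_age10: float = 0.10  # log-HR per 10 years of age
    beta_comorb: float = 0.15  # log-HR per chronic condition
    frailty_power: float = 0.0  # hazard multiplied by frailty**power


@dataclass
class DeathModel:
    h0: float = 0.0045
    hr: float = 1.0
    beta_age10: float = 0.35
    frailty_power: float = 1.0


@dataclass
class TreatmentModel:
    """Logit of treatment on observed covariates and latent frailty."""

    intercept: float = -1.9
    beta_age10: float = -0.15
    beta_comorb: float = -0.30
    beta_statin: float = 0.7
    beta_hospice: float = -1.8
    beta_frailty: float = -0.15  # on (frailty - 1); negative = frail less treated


def _default_outcomes() -> dict:
    return {
        "gastrointestinal": OutcomeModel(h0=0.0050),
        "psychological": OutcomeModel(h0=0.0090, beta_age10=0.0),
        "respiratory": OutcomeModel(h0=0.0055, beta_age10=0.20),
        "hematological": OutcomeModel(h0=0.0040, beta_age10=0.15),
        "hepatic": OutcomeModel(h0=0.0008),
    }


@dataclass
class ScenarioSpec:
    """Complete parameterization of one simulated study population."""

    n_subjects: int = 4000
    seed: int = 0
    frailty_shape: float = 2.0  # Gamma(shape, 1/shape): mean 1, var 1/shape
    outcomes: dict = field(default_factory=_default_outcomes)
    death: DeathModel = field(default_factory=DeathModel)
    treatment: TreatmentModel = field(default_factory=TreatmentModel)
    acute_multiplier: float = 1.0  # extra outcome-hazard factor, first exposed weeks
    acute_weeks: int = 6
    refill_stop_prob: float = 0.12  # per-refill probability of stopping therapy
    days_supply: int = 30
    monthly_gap_prob: float = 0.01  # i.i.d. per-month disenrollment probability
    prevalent_fraction: float = 0.06  # treated with an extra early fill
    memantine_fraction: float = 0.02
    treatment_start_lo: int = 240
    treatment_start_hi: int = 600
    dementia_visit_weekly_prob: float = 0.10
    clinic_logit: float = 0.0  # weekly clinic-visit prob = sigmoid(logit + slope*(f-1))
    clinic_frailty_slope: float = 0.35

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.frailty_shape <= 0:
            raise ValidationError("frailty_shape must be positive")
        for g, m in self.outcomes.items():
            if not (0 <= m.h0 < 1):
                raise ValidationError(f"{g}: weekly hazard h0 must be in [0, 1)")
            if m.hr <= 0:
                raise ValidationError(f"{g}: hazard ratio must be positive")
            if m.h0 * m.hr * max(self.acute_multiplier, 1.0) >= 1:
                raise ValidationError(f"{g}: exposed weekly hazard >= 1 is degenerate")
        if not (0 <= self.death.h0 < 1) or self.death.hr <= 0:
            raise ValidationError("death: invalid weekly hazard or hazard ratio")
        for name in ("refill_stop_prob", "monthly_gap_prob", "prevalent_fraction",
                     "memantine_fraction", "dementia_visit_weekly_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be a probability")
        if self.refill_stop_prob == 0:
            raise ValidationError("refill_stop_prob must be > 0")


def preset(name: str, n_subjects: int = 4000, seed: int = 0) -> ScenarioSpec:
    """Named study scenarios mirroring the reaction classes under test.

    - ``null_all``: every exposure hazard ratio (including death) is 1.
    - ``gi_effect``: gastrointestinal HR 2.0, all other HRs 1.
    - ``frailty_death``: death HR 1 with strong frailty-treatment and
      frailty-death links, so the crude death comparison looks protective.
    - ``acute_transient``: all HRs 1, but outcome hazards are tripled during
      the first 6 exposed weeks only.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available presets: {list(PRESETS)}")
    spec = ScenarioSpec(n_subjects=n_subjects, seed=seed)
    if name == "gi_effect":
        spec.outcomes["gastrointestinal"].hr = 2.0
    elif name == "frailty_death":
        spec.treatment.beta_comorb = -0.35
        spec.treatment.beta_hospice = -2.0
        spec.treatment.beta_statin = 0.8
        spec.treatment.beta_frailty = -0.05
        spec.death.h0 = 0.0035
        spec.death.frailty_power = 1.3
        spec.treatment_start_lo = 190
        spec.treatment_start_hi = 330
    elif name == "acute_transient":
        spec.acute_multiplier = 3.0
    return spec


@dataclass
class GroundTruth:
    """Latent state behind one simulated bundle."""

    subjects: pd.DataFrame  # frailty, treatment, exposure era, death
    events: pd.DataFrame  # latent outcome event weeks and whether claimed


def simulate_bundle(
    spec: ScenarioSpec, config: StudyConfig | None = None
) -> tuple[ClaimsBundle, GroundTruth]:
    """Simulate one claims bundle plus its ground truth; deterministic in
    ``spec.seed``."""
    cfg = config if config is not None else StudyConfig()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_weeks = cfg.n_weeks
    n_months = cfg.n_months
    end_day = cfg.study_end_day
    code_map = default_code_map()

    # --- subject-level latent state -------------------------------------
    birth_year = cfg.study_start_year - rng.integers(50, 93, n)
    age = (cfg.study_start_year - birth_year).astype(float)
    female = rng.random(n) < 0.72
    frailty = rng.gamma(spec.frailty_shape, 1.0 / spec.frailty_shape, n)
    fm1 = frailty - 1.0

    cond_logit = np.log(_CONDITION_BASE_P / (1 - _CONDITION_BASE_P))
    conditions = rng.random((n, len(_CONDITION_GROUPS))) < _sigmoid(
        cond_logit[None, :] + 0.9 * fm1[:, None]
    )
    n_conditions = conditions.sum(axis=1)
    statin = rng.random(n) < _sigmoid(-1.2 - 0.7 * fm1)
    hospice_user = rng.random(n) < _sigmoid(-3.6 + 1.8 * fm1)
    nursing_user = rng.random(n) < _sigmoid(-2.0 + 0.8 * fm1)
    drug_logit = np.log(_DRUG_USER_BASE / (1 - _DRUG_USER_BASE))
    drug_users = rng.random((n, len(_DRUG_USER_CLASSES))) < _sigmoid(
        drug_logit[None, :] + 0.6 * fm1[:, None]
    )

    enrolled = rng.random((n, n_months)) >= spec.monthly_gap_prob

    t = spec.treatment
    z = (
        t.intercept
        + t.beta_age10 * (age - 77.0) / 10.0
        + t.beta_comorb * n_conditions
        + t.beta_statin * statin
        + t.beta_hospice * hospice_user
        + t.beta_frailty * fm1
    )
    treated = rng.random(n) < _sigmoid(z)
    t_start = rng.integers(spec.treatment_start_lo, spec.treatment_start_hi + 1, n)
    prevalent = treated & (rng.random(n) < spec.prevalent_fraction)
    prev_day = rng.integers(0, 121, n)
    memantine = rng.random(n) < spec.memantine_fraction
    mem_day = rng.integers(0, 901, n)

    # --- dispensing histories -------------------------------------------
    n_fills = rng.geometric(spec.refill_stop_prob, n)  # intended fills, >= 1
    tr_idx = np.flatnonzero(treated)
    fill_rows = np.zeros(0, dtype=np.int64)
    fill_days = np.zeros(0, dtype=np.int64)
    if len(tr_idx):
        kmax = int(n_fills[tr_idx].max())
        K = np.arange(kmax)
        days = t_start[tr_idx, None] + spec.days_supply * K[None, :]
        ok = (K[None, :] < n_fills[tr_idx, None]) & (days <= end_day)
        month = np.clip(days // cfg.month_length_days, 0, n_months - 1)
        ok &= enrolled[tr_idx[:, None], month]
        ok = np.logical_and.accumulate(ok, axis=1)  # persistency: stop at first miss
        r, c = np.nonzero(ok)
        fill_rows = tr_idx[r]
        fill_days = days[r, c]
    started = np.zeros(n, dtype=bool)
    started[np.unique(fill_rows)] = True
    treated &= started  # never-dispensed assignments contribute no exposure

    last_fill = np.full(n, -1, dtype=np.int64)
    if len(fill_rows):
        s = pd.Series(fill_days).groupby(fill_rows).max()
        last_fill[s.index.to_numpy()] = s.to_numpy()
    supply_end = np.where(treated, last_fill + spec.days_supply - 1, -1)
    exposure_end = np.where(
        treated, np.minimum(supply_end + cfg.course_tail_days, end_day), -1
    )

    # --- exposure grid ---------------------------------------------------
    week_idx = np.arange(n_weeks)
    w_start = np.where(treated, t_start // 7, n_weeks + 1)
    w_end = np.where(treated, exposure_end // 7, -1)
    exposed = (week_idx[None, :] >= w_start[:, None]) & (
        week_idx[None, :] <= w_end[:, None]
    )
    if np.any(prevalent & treated):
        pe = np.minimum(prev_day + spec.days_supply - 1 + cfg.course_tail_days, end_day)
        pmask = (prevalent & treated)[:, None] & (
            (week_idx[None, :] >= (prev_day // 7)[:, None])
            & (week_idx[None, :] <= (pe // 7)[:, None])
        )
        exposed |= pmask
    acute = exposed & (week_idx[None, :] < (w_start + spec.acute_weeks)[:, None])

    # --- death -----------------------------------------------------------
    d = spec.death
    death_base = d.h0 * np.exp(d.beta_age10 * (age - 77.0) / 10.0) * frailty**d.frailty_power
    death_h = np.clip(death_base[:, None] * np.where(exposed, d.hr, 1.0), 0, 0.97)
    death_draw = rng.random((n, n_weeks)) < death_h
    death_week = np.where(death_draw.any(axis=1), death_draw.argmax(axis=1), n_weeks)
    death_day = np.minimum(death_week * 7 + rng.integers(0, 7, n), end_day)
    death_day = np.where(death_week >= n_weeks, end_day + 10_000, death_day)

    # dispensing requires being alive: drop post-death fills, then rebuild the
    # exposure era (post-death exposure never affected any hazard draw)
    if len(fill_rows):
        keep = fill_days <= death_day[fill_rows]
        fill_rows, fill_days = fill_rows[keep], fill_days[keep]
    started = np.zeros(n, dtype=bool)
    started[np.unique(fill_rows)] = True
    treated &= started
    last_fill = np.full(n, -1, dtype=np.int64)
    if len(fill_rows):
        s = pd.Series(fill_days).groupby(fill_rows).max()
        last_fill[s.index.to_numpy()] = s.to_numpy()
    supply_end = np.where(treated, last_fill + spec.days_supply - 1, -1)
    exposure_end = np.where(
        treated, np.minimum(supply_end + cfg.course_tail_days, end_day), -1
    )
    w_start = np.where(treated, t_start // 7, n_weeks + 1)
    w_end = np.where(treated, exposure_end // 7, -1)
    exposed = (week_idx[None, :] >= w_start[:, None]) & (
        week_idx[None, :] <= w_end[:, None]
    )
    if np.any(prevalent & treated):
        pe = np.minimum(prev_day + spec.days_supply - 1 + cfg.course_tail_days, end_day)
        exposed |= (prevalent & treated)[:, None] & (
            (week_idx[None, :] >= (prev_day // 7)[:, None])
            & (week_idx[None, :] <= (pe // 7)[:, None])
        )
    acute = exposed & (week_idx[None, :] < (w_start + spec.acute_weeks)[:, None])

    def _month(dayv):
        return np.clip(np.asarray(dayv) // cfg.month_length_days, 0, n_months - 1)

    def _observable(subj, day):
        return (day <= end_day) & (day <= death_day[subj]) & enrolled[subj, _month(day)]

    # --- latent outcome events and their claims -------------------------
    med_subj: list = []
    med_day: list = []
    med_dx: list = []
    med_setting: list = []
    truth_records: list = []

    alive = week_idx[None, :] <= death_week[:, None]
    groups_sorted = sorted(spec.outcomes)
    for g in groups_sorted:
        m = spec.outcomes[g]
        base = (
            m.h0
            * np.exp(
                m.beta_age10 * (age - 77.0) / 10.0 + m.beta_comorb * (n_conditions - 1)
            )
            * frailty**m.frailty_power
        )
        mult = np.where(exposed, m.hr, 1.0) * np.where(acute, spec.acute_multiplier, 1.0)
        h = np.clip(base[:, None] * mult, 0, 0.97)
        hits = (rng.random((n, n_weeks)) < h) & alive
        subj, wk = np.nonzero(hits)
        day = wk * 7 + rng.integers(0, 7, len(wk))
        day = np.minimum(day, death_day[subj])
        claimed = _observable(subj, day)
        codes = np.array(sorted(code_map.codes(g)))
        # index claim
        isubj, iday = subj[claimed], day[claimed]
        med_subj.append(isubj)
        med_day.append(iday)
        med_dx.append(codes[rng.integers(0, len(codes), len(isubj))])
        med_setting.append(
            rng.choice(["outpatient", "inpatient", "emergency"], len(isubj), p=[0.7, 0.15, 0.15])
        )
        # follow-up burst: 0-3 extra claims, Geometric(0.5) truncated
        burst = rng.choice(4, size=len(isubj), p=[8 / 15, 4 / 15, 2 / 15, 1 / 15])
        bs = np.repeat(isubj, burst)
        bd = np.repeat(iday, burst) + rng.integers(7, 22, int(burst.sum()))
        keep = _observable(bs, bd)
        med_subj.append(bs[keep])
        med_day.append(bd[keep])
        med_dx.append(codes[rng.integers(0, len(codes), int(keep.sum()))])
        med_setting.append(np.full(int(keep.sum()), "outpatient"))
        truth_records.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "group_label": g,
                    "week": wk,
                    "day": day,
                    "claimed": claimed,
                }
            )
        )

    # --- background medical claims --------------------------------------
    dem_codes = np.array(sorted(code_map.codes("dementia")))
    cond_codes = np.array([f"C{i + 1:02d}" for i in range(len(_CONDITION_GROUPS))])

    def _weekly_process(p_week, setting_choices, setting_p, dx_fn):
        p = np.broadcast_to(np.asarray(p_week)[:, None], (n, n_weeks))
        hits = (rng.random((n, n_weeks)) < p) & alive
        subj, wk = np.nonzero(hits)
        day = np.minimum(wk * 7 + rng.integers(0, 7, len(wk)), death_day[subj])
        keep = _observable(subj, day)
        subj, day = subj[keep], day[keep]
        med_subj.append(subj)
        med_day.append(day)
        med_dx.append(dx_fn(subj))
        if len(setting_choices) == 1:
            med_setting.append(np.full(len(subj), setting_choices[0]))
        else:
            med_setting.append(rng.choice(setting_choices, len(subj), p=setting_p))

    # dementia-diagnosis visits (chronic disease management)
    _weekly_process(
        np.full(n, spec.dementia_visit_weekly_prob),
        ["outpatient", "inpatient", "nursing_home"],
        [0.85, 0.05, 0.10],
        lambda subj: dem_codes[rng.integers(0, len(dem_codes), len(subj))],
    )

    # visits code one of the subject's own chronic conditions 70% of the time
    cond_order = np.argsort(~conditions, axis=1, kind="stable")
    cond_count = conditions.sum(axis=1)

    def _condition_dx(subj):
        c = cond_count[subj]
        u = rng.random(len(subj))
        j = np.minimum((u * np.maximum(c, 1)).astype(int), np.maximum(c - 1, 0))
        slot = cond_order[subj, j]
        use = (c > 0) & (rng.random(len(subj)) < 0.7)
        return np.where(use, cond_codes[slot], "C00")

    # routine clinic visits
    p_clinic = _sigmoid(spec.clinic_logit + spec.clinic_frailty_slope * fm1)
    _weekly_process(p_clinic, ["outpatient"], None, _condition_dx)
    # emergency-department visits and hospitalizations
    _weekly_process(np.clip(0.004 * frailty, 0, 0.5), ["emergency"], None, _condition_dx)
    _weekly_process(
        np.clip(0.007 * np.sqrt(frailty), 0, 0.5), ["inpatient"], None, _condition_dx
    )
    # hospice and nursing-home service claims
    _weekly_process(
        np.where(hospice_user, 0.5, 0.0), ["hospice"], None,
        lambda subj: np.full(len(subj), "C00"),
    )
    _weekly_process(
        np.where(nursing_user, 0.3, 0.0), ["nursing_home"], None,
        lambda subj: np.full(len(subj), "C00"),
    )

    medical = pd.DataFrame(
        {
            "subject_id": np.concatenate(med_subj) if med_subj else np.array([], int),
            "service_day": np.concatenate(med_day) if med_day else np.array([], int),
            "primary_dx": np.concatenate(med_dx) if med_dx else np.array([], str),
            "setting": np.concatenate(med_setting) if med_setting else np.array([], str),
        }
    ).sort_values(["subject_id", "service_day", "primary_dx", "setting"], kind="mergesort")

    # --- pharmacy claims --------------------------------------------------
    ph_subj = [fill_rows]
    ph_day = [fill_days]
    ph_supply = [np.full(len(fill_rows), spec.days_supply)]
    ph_class = [np.full(len(fill_rows), "ACHEI")]

    pv = np.flatnonzero(prevalent & treated)
    pv = pv[_observable(pv, prev_day[pv])]
    ph_subj.append(pv)
    ph_day.append(prev_day[pv])
    ph_supply.append(np.full(len(pv), spec.days_supply))
    ph_class.append(np.full(len(pv), "ACHEI"))

    mm = np.flatnonzero(memantine)
    for off in (0, spec.days_supply):
        dayv = mem_day[mm] + off
        keep = _observable(mm, dayv)
        ph_subj.append(mm[keep])
        ph_day.append(dayv[keep])
        ph_supply.append(np.full(int(keep.sum()), spec.days_supply))
        ph_class.append(np.full(int(keep.sum()), "MEMANTINE"))

    def _maintenance_fills(users_mask, cls):
        users = np.flatnonzero(users_mask)
        if not len(users):
            return
        offset = rng.integers(0, 90, len(users))
        kmax = end_day // 90 + 1
        days = offset[:, None] + 90 * np.arange(kmax)[None, :]
        subj = np.repeat(users, kmax)
        days = days.ravel()
        keep = _observable(subj, days)
        ph_subj.append(subj[keep])
        ph_day.append(days[keep])
        ph_supply.append(np.full(int(keep.sum()), 90))
        ph_class.append(np.full(int(keep.sum()), cls))

    _maintenance_fills(statin, "STATIN")
    for j, cls in enumerate(_DRUG_USER_CLASSES):
        _maintenance_fills(drug_users[:, j], cls)

    pharmacy = pd.DataFrame(
        {
            "subject_id": np.concatenate(ph_subj),
            "dispense_day": np.concatenate(ph_day),
            "days_supply": np.concatenate(ph_supply),
            "drug_class": np.concatenate(ph_class),
        }
    ).sort_values(["subject_id", "dispense_day", "drug_class"], kind="mergesort")

    # --- enrollment spans, deaths, subjects -------------------------------
    padded = np.zeros((n, n_months + 2), dtype=bool)
    padded[:, 1:-1] = enrolled
    starts = np.nonzero(~padded[:, :-1] & padded[:, 1:])
    ends = np.nonzero(padded[:, :-1] & ~padded[:, 1:])
    enrollment = pd.DataFrame(
        {
            "subject_id": starts[0],
            "start_month": starts[1],
            "end_month": ends[1] - 1,
        }
    )
    enrollment = enrollment.merge(
        pd.DataFrame(
            {"subject_id": np.arange(n), "birth_year": birth_year,
             "sex": np.where(female, "F", "M")}
        ),
        on="subject_id",
    )
    enrollment = normalize_enrollment(enrollment)

    died = death_week < n_weeks
    death = pd.DataFrame(
        {"subject_id": np.flatnonzero(died), "death_day": death_day[died]}
    )
    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "birth_year": birth_year,
            "sex": np.where(female, "F", "M"),
        }
    )
    bundle = ClaimsBundle(
        pharmacy=pharmacy.reset_index(drop=True),
        medical=medical.reset_index(drop=True),
        enrollment=enrollment.reset_index(drop=True),
        death=death.reset_index(drop=True),
        subjects=subjects,
        code_map=code_map,
    )
    truth_subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "frailty": frailty,
            "n_conditions": n_conditions,
            "statin": statin,
            "hospice": hospice_user,
            "nursing_home": nursing_user,
            "treated": treated,
            "prevalent": prevalent & treated,
            "treatment_start_day": np.where(treated, t_start, -1),
            "last_supplied_day": supply_end,
            "exposure_end_day": exposure_end,
            "death_week": np.where(died, death_week, -1),
            "death_day": np.where(died, death_day, -1),
        }
    )
    truth_events = (
        pd.concat(truth_records, ignore_index=True)
        if truth_records
        else pd.DataFrame(columns=["subject_id", "group_label", "week", "day", "claimed"])
    )
    return bundle, GroundTruth(subjects=truth_subjects, events=truth_events)


def check_consistency(bundle: ClaimsBundle, truth: GroundTruth) -> None:
    """Structural agreement between a bundle and its ground truth.

    Raises AssertionError on: a claimed latent event with no matching claim,
    a treated subject without exposure dispensings, a death record
    disagreeing with the latent death day, or claims after death.
    """
    ev = truth.events[truth.events["claimed"]]
    if len(ev):
        med = bundle.medical.copy()
        roles = bundle.code_map
        label = {}
        for g in roles.labels("outcome"):
            for c in roles.codes(g):
                label[c] = g
        med["group_label"] = med["primary_dx"].map(label)
        med = med.dropna(subset=["group_label"])
        key_claims = set(zip(med["subject_id"], med["group_label"], med["service_day"]))
        missing = [
            t
            for t in zip(ev["subject_id"], ev["group_label"], ev["day"])
            if t not in key_claims
        ]
        assert not missing, f"{len(missing)} claimed latent events lack claims"
    tr = truth.subjects[truth.subjects["treated"]]
    achei = set(bundle.pharmacy.loc[bundle.pharmacy["drug_class"] == "ACHEI", "subject_id"])
    assert set(tr["subject_id"]) <= achei, "treated subject without ACHEI dispensing"
    dd = truth.subjects.set_index("subject_id")["death_day"]
    rec = bundle.death.set_index("subject_id")["death_day"]
    assert rec.index.isin(dd[dd >= 0].index).all()
    assert (rec == dd.loc[rec.index]).all(), "death record disagrees with truth"
    after = bundle.medical["service_day"] > bundle.medical["subject_id"].map(dd).where(
        lambda s: s >= 0, np.inf
    )
    assert not after.any(), "medical claim after death"
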