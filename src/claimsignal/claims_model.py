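"""Claims data model, code-group mapping, study configuration, and tabular IO.

All dates are integer day offsets from ``study_start_day`` (day 0); calendar
dates in source files must be converted on read.  Weeks are half-open 7-day
bins anchored per use (``day_to_week``), so week 0 of a subject's follow-up is
the week containing the index day.  Enrollment is tracked in fixed-length
months (default 30 days) unless the input supplies explicit month indices.

The bundle of four claims tables (pharmacy dispensings, medical claims,
enrollment spans, death records) plus a diagnosis code-group map is the single
input object consumed by every downstream stage.  Demographic attributes
(birth year, sex) travel on the enrollment file, as they do in real
eligibility extracts, and are normalized into a subjects table on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SETTINGS = ("outpatient", "inpatient", "emergency", "hospice", "nursing_home")
ROLES = ("dementia", "outcome", "comorbidity")

#: outcome groups analysed by default, mirroring the targeted-outcome taxonomy
OUTCOME_GROUPS = (
    "gastrointestinal",
    "psychological",
    "respiratory",
    "hematological",
    "hepatic",
)
DEATH = "death"

#: default drug-class vocabulary for pharmacy claims
DRUG_CLASSES = (
    "ACHEI",
    "MEMANTINE",
    "STATIN",
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

PHARMACY_SCHEMA = ("subject_id", "dispense_day", "days_supply", "drug_class")
MEDICAL_SCHEMA = ("subject_id", "service_day", "primary_dx", "setting")
ENROLLMENT_SCHEMA = ("subject_id", "start_month", "end_month", "birth_year", "sex")
DEATH_SCHEMA = ("subject_id", "death_day")
CODEMAP_SCHEMA = ("code", "group_label", "role")

REPORT_SECTIONS = ("baseline", "balance", "incidence", "hazards", "crossover")


class SchemaError(ValueError):
    """A delimited input is missing required columns."""


class ValidationError(ValueError):
    """Rows violate a data-model invariant."""


def day_to_week(day, anchor_day=0, week_days: int = 7):
    """Map a day offset to its week index relative to ``anchor_day``.

    Week ``w`` contains days ``[anchor_day + week_days*w,
    anchor_day + week_days*(w+1) - 1]``; week 0 starts at the anchor and
    negative days map to negative weeks (floor-division convention).  Works
    elementwise on arrays.
    """
    return (np.asarray(day) - anchor_day) // week_days if isinstance(day, np.ndarray) else (day - anchor_day) // week_days


def month_of_day(day, month_days: int = 30):
    """Fixed-length calendar: the month index containing ``day``."""
    return np.asarray(day) // month_days if isinstance(day, np.ndarray) else day // month_days


# ---------------------------------------------------------------------------
# code-group map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeGroupMap:
    """Mapping from diagnosis codes to labelled groups with a role each.

    Roles partition the groups by purpose: ``dementia`` groups define cohort
    eligibility, ``outcome`` groups drive event detection from the primary
    diagnosis, and ``comorbidity`` groups feed baseline covariates.  Dementia
    and outcome groups may not share codes; a code may legitimately appear in
    both an outcome group and a comorbidity group.
    """

    groups: Mapping[str, frozenset]
    roles: Mapping[str, str]

    def __post_init__(self):
        for label, role in self.roles.items():
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r} for group {label!r}")
            if label not in self.groups:
                raise ValidationError(f"role given for unknown group {label!r}")
        if set(self.groups) != set(self.roles):
            raise ValidationError("groups and roles must cover the same labels")
        dem = self.codes_for_role("dementia")
        out = self.codes_for_role("outcome")
        overlap = dem & out
        if overlap:
            raise ValidationError(
                f"codes shared between dementia and outcome groups: {sorted(overlap)}"
            )

    def labels(self, role: str | None = None) -> tuple:
        if role is None:
            return tuple(sorted(self.groups))
        return tuple(sorted(g for g, r in self.roles.items() if r == role))

    def codes(self, label: str) -> frozenset:
        if label not in self.groups:
            raise KeyError(
                f"unknown group {label!r}; configured groups: {sorted(self.groups)}"
            )
        return self.groups[label]

    def codes_for_role(self, role: str) -> frozenset:
        out: set = set()
        for g in self.labels(role):
            out |= self.groups[g]
        return frozenset(out)

    def code_to_label(self, role: str) -> dict:
        """code -> group label for one role (first label wins on overlap)."""
        table: dict = {}
        for g in self.labels(role):
            for c in self.groups[g]:
                table.setdefault(c, g)
        return table

    def frame(self) -> pd.DataFrame:
        rows = [
            (code, label, self.roles[label])
            for label in sorted(self.groups)
            for code in sorted(self.groups[label])
        ]
        return pd.DataFrame(rows, columns=list(CODEMAP_SCHEMA))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CodeGroupMap":
        _require_columns(df, CODEMAP_SCHEMA, "code map")
        groups: dict = {}
        roles: dict = {}
        for label, sub in df.groupby("group_label"):
            role_vals = set(sub["role"])
            if len(role_vals) != 1:
                raise ValidationError(f"group {label!r} has conflicting roles {role_vals}")
            roles[str(label)] = role_vals.pop()
            groups[str(label)] = frozenset(str(c) for c in sub["code"])
        return cls(groups=groups, roles=roles)

    @classmethod
    def read_csv(cls, path) -> "CodeGroupMap":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def write_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)


def default_code_map() -> CodeGroupMap:
    """Toy code-group map with the same group labels as the study taxonomy.

    Stands in for licensed diagnosis groupers (which are not distributable);
    codes are synthetic but structurally faithful: dementia groups, five
    targeted outcome groups, and comorbidity groups used for baseline
    covariates.
    """
    groups = {
        "dementia": frozenset({"D01", "D02", "D03", "D04", "D05"}),
        "gastrointestinal": frozenset({"G01", "G02", "G03", "G04", "G05", "G06"}),
        "hematological": frozenset({"H01", "H02", "H03", "H04"}),
        "hepatic": frozenset({"L01"}),
        "psychological": frozenset({"P01", "P02", "P03", "P04"}),
        "respiratory": frozenset({"R01"}),
        "general": frozenset({"C00"}),
        "diabetes": frozenset({"C01"}),
        "hypertension": frozenset({"C02"}),
        "heart_failure": frozenset({"C03"}),
        "renal": frozenset({"C04"}),
        "pulmonary": frozenset({"C05"}),
        "depression": frozenset({"C06"}),
        "thyroid": frozenset({"C07"}),
        "arthritis": frozenset({"C08"}),
        "electrolyte": frozenset({"C09"}),
        "vascular": frozenset({"C10"}),
    }
    roles = {label: "comorbidity" for label in groups}
    roles["dementia"] = "dementia"
    for g in OUTCOME_GROUPS:
        roles[g] = "outcome"
    return CodeGroupMap(groups=groups, roles=roles)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------


def default_covariates(
    outcome_groups: Sequence[str] = OUTCOME_GROUPS,
    drug_flag_classes: Sequence[str] = (
        "ANTIDEP",
        "ANTIPSYCH",
        "ANXIO",
        "ANTICONV",
        "NARC",
        "SEDATIVE",
        "STEROID",
        "NSAID",
        "GASTROPROT",
    ),
) -> dict:
    """Per-outcome propensity covariate lists (demographics, comorbidity,
    utilization, drug-class flags, and the outcome's own baseline-episode
    flag as a risk factor)."""
    common = [
        "age",
        "female",
        "comorbidity_count",
        "rx_risk_proxy",
        "n_clinic_visits",
        "n_hospitalizations",
        "n_ed_visits",
        "hospice",
        "nursing_home",
        "statin",
    ] + [f"drug_{c}" for c in drug_flag_classes]
    lists = {g: common + [f"baseline_{g}"] for g in outcome_groups}
    lists[DEATH] = list(common)
    return lists


@dataclass
class StudyConfig:
    """Protocol constants for one study run.

    Durations are in days unless the name says otherwise.  ``washout_days`` is
    the drug-free pre-index window required for an incident course;
    ``course_gap_days`` is the supply gap that terminates a course and
    ``course_tail_days`` extends the course past its last supplied day;
    ``episode_gap_days`` separates episodes of care; the case-crossover
    windows are ``window_weeks`` long.
    """

    washout_days: int = 180
    course_gap_days: int = 60
    course_tail_days: int = 60
    episode_gap_days: int = 28
    window_weeks: int = 6
    week_length_days: int = 7
    month_length_days: int = 30
    min_age: int = 50
    study_start_day: int = 0
    study_end_day: int = 1094
    study_start_year: int = 2003
    exposure_class: str = "ACHEI"
    excluded_classes: tuple = ("ACHEI", "MEMANTINE")
    drug_classes: tuple = DRUG_CLASSES
    outcome_groups: tuple = OUTCOME_GROUPS
    covariates: dict = field(default_factory=default_covariates)
    # key prognostic covariates entering the Mahalanobis metric with the
    # logit propensity; the remaining covariates are balanced by the score
    key_covariates: dict = field(
        default_factory=lambda: {
            g: ["age", "comorbidity_count", "n_clinic_visits"]
            for g in (*OUTCOME_GROUPS, DEATH)
        }
    )
    exact_match: dict = field(
        default_factory=lambda: {
            **{g: [f"baseline_{g}"] for g in OUTCOME_GROUPS},
            DEATH: ["hospice"],
        }
    )
    band_match: dict = field(default_factory=lambda: {DEATH: {"age": 5.0}})
    adjust_covariates: dict = field(default_factory=dict)
    caliper_sd: float = 0.2
    follow_up_mode: str = "as_treated"
    comorbidity_dx_position: str = "primary"
    ridge_fallback: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "washout_days",
            "course_gap_days",
            "course_tail_days",
            "episode_gap_days",
            "window_weeks",
            "week_length_days",
            "month_length_days",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.study_end_day <= self.study_start_day:
            raise ValidationError("study_end_day must exceed study_start_day")
        if self.follow_up_mode not in ("as_treated", "full_followup"):
            raise ValidationError(f"unknown follow_up_mode {self.follow_up_mode!r}")
        if self.caliper_sd <= 0:
            raise ValidationError("caliper_sd must be positive")
        self.excluded_classes = tuple(self.excluded_classes)
        self.drug_classes = tuple(self.drug_classes)
        self.outcome_groups = tuple(self.outcome_groups)

    @property
    def n_months(self) -> int:
        return self.study_end_day // self.month_length_days + 1

    @property
    def n_weeks(self) -> int:
        return self.study_end_day // self.week_length_days + 1

    def analyses(self) -> tuple:
        """Outcome labels analysed: the clinical groups plus death."""
        return (*self.outcome_groups, DEATH)

    def validate_covariates(self, available: Iterable[str]) -> None:
        avail = set(available)
        for g, names in self.covariates.items():
            missing = [n for n in names if n not in avail]
            if missing:
                raise ValidationError(
                    f"covariates for outcome {g!r} not computable: {missing}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "StudyConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown study-config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle + readers/writers
# ---------------------------------------------------------------------------


@dataclass
class ClaimsBundle:
    """The four claims tables, subject attributes, and the code-group map."""

    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    enrollment: pd.DataFrame
    death: pd.DataFrame
    subjects: pd.DataFrame
    code_map: CodeGroupMap

    def equals(self, other: "ClaimsBundle") -> bool:
        def same(a, b):
            a = a.reset_index(drop=True)
            b = b.reset_index(drop=True)
            return a.shape == b.shape and bool((a == b).all().all())

        return (
            same(self.pharmacy, other.pharmacy)
            and same(self.medical, other.medical)
            and same(self.enrollment[list(ENROLLMENT_SCHEMA[:3])], other.enrollment[list(ENROLLMENT_SCHEMA[:3])])
            and same(self.death, other.death)
            and same(self.subjects, other.subjects)
            and self.code_map.frame().equals(other.code_map.frame())
        )


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _offending(mask: pd.Series, limit: int = 10) -> str:
    rows = list(np.flatnonzero(np.asarray(mask))[:limit])
    return f"rows {rows}" + ("..." if int(np.asarray(mask).sum()) > limit else "")


def normalize_enrollment(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or adjacent enrollment spans per subject.

    Idempotent; output spans are sorted, disjoint, and separated by at least
    one gap month.
    """
    _require_columns(enrollment, ENROLLMENT_SCHEMA[:3], "enrollment")
    if len(enrollment) == 0:
        return enrollment.reset_index(drop=True)
    bad = enrollment["start_month"] > enrollment["end_month"]
    if bad.any():
        raise ValidationError(f"enrollment: start_month > end_month at {_offending(bad)}")
    df = enrollment.sort_values(["subject_id", "start_month", "end_month"], kind="mergesort")
    same_subject = df["subject_id"].eq(df["subject_id"].shift())
    run_max_end = df.groupby("subject_id")["end_month"].cummax().shift()
    new_span = ~(same_subject & (df["start_month"] <= run_max_end + 1))
    span_id = new_span.cumsum()
    agg = {"subject_id": "first", "start_month": "min", "end_month": "max"}
    for extra in df.columns:
        if extra not in agg:
            agg[extra] = "first"
    out = df.groupby(span_id, sort=True).agg(agg)
    return out.reset_index(drop=True)[list(df.columns)]


def validate_bundle(bundle: ClaimsBundle, config: StudyConfig | None = None) -> None:
    """Check every type invariant; raise ValidationError naming offending rows."""
    ph, md, en, dt = bundle.pharmacy, bundle.medical, bundle.enrollment, bundle.death
    _require_columns(ph, PHARMACY_SCHEMA, "pharmacy")
    _require_columns(md, MEDICAL_SCHEMA, "medical")
    _require_columns(en, ENROLLMENT_SCHEMA[:3], "enrollment")
    _require_columns(dt, DEATH_SCHEMA, "death")

    if len(ph):
        bad = ph["days_supply"] < 1
        if bad.any():
            raise ValidationError(f"pharmacy: days_supply < 1 at {_offending(bad)}")
        if config is not None:
            bad = ~ph["drug_class"].isin(config.drug_classes)
            if bad.any():
                raise ValidationError(
                    f"pharmacy: drug_class outside vocabulary at {_offending(bad)}"
                )
            bad = (ph["dispense_day"] < config.study_start_day) | (
                ph["dispense_day"] > config.study_end_day
            )
            if bad.any():
                raise ValidationError(
                    f"pharmacy: dispense_day outside study period at {_offending(bad)}"
                )
    if len(md):
        bad = ~md["setting"].isin(SETTINGS)
        if bad.any():
            raise ValidationError(f"medical: unknown setting at {_offending(bad)}")
        bad = md["primary_dx"].astype(str).str.len() == 0
        if bad.any():
            raise ValidationError(f"medical: empty primary_dx at {_offending(bad)}")
        known = frozenset().union(*bundle.code_map.groups.values())
        bad = ~md["primary_dx"].astype(str).isin(known)
        if bad.any():
            raise ValidationError(
                f"medical: primary_dx not in code map at {_offending(bad)}"
            )
        if config is not None:
            bad = (md["service_day"] < config.study_start_day) | (
                md["service_day"] > config.study_end_day
            )
            if bad.any():
                raise ValidationError(
                    f"medical: service_day outside study period at {_offending(bad)}"
                )
    if len(dt):
        if dt["subject_id"].duplicated().any():
            raise ValidationError("death: more than one record per subject")
        if config is not None:
            bad = dt["death_day"] < config.study_start_day
            if bad.any():
                raise ValidationError(
                    f"death: death_day before study start at {_offending(bad)}"
                )
    if len(en):
        bad = en["start_month"] > en["end_month"]
        if bad.any():
            raise ValidationError(
                f"enrollment: start_month > end_month at {_offending(bad)}"
            )


def read_claims_bundle(
    pharmacy_path,
    medical_path,
    enrollment_path,
    death_path,
    code_map_path,
    config: StudyConfig | None = None,
) -> ClaimsBundle:
    """Read and validate the four claims tables plus the code-group map.

    Enrollment spans are normalized (overlapping/adjacent spans merged) and a
    subjects table is derived from the demographic columns of the enrollment
    file.
    """
    ph = pd.read_csv(pharmacy_path, dtype={"subject_id": np.int64})
    md = pd.read_csv(medical_path, dtype={"subject_id": np.int64, "primary_dx": str})
    en = pd.read_csv(enrollment_path, dtype={"subject_id": np.int64})
    dt = pd.read_csv(death_path, dtype={"subject_id": np.int64})
    cmap = CodeGroupMap.read_csv(code_map_path)
    _require_columns(en, ENROLLMENT_SCHEMA, "enrollment")
    en = normalize_enrollment(en)
    subjects = (
        en[["subject_id", "birth_year", "sex"]]
        .drop_duplicates("subject_id")
        .sort_values("subject_id")
        .reset_index(drop=True)
    )
    bad = ~subjects["sex"].isin(("F", "M"))
    if bad.any():
        raise ValidationError(f"enrollment: sex must be F or M at {_offending(bad)}")
    bundle = ClaimsBundle(
        pharmacy=ph.reset_index(drop=True),
        medical=md.reset_index(drop=True),
        enrollment=en,
        death=dt.reset_index(drop=True),
        subjects=subjects,
        code_map=cmap,
    )
    validate_bundle(bundle, config)
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, outdir) -> dict:
    """Write the bundle as five CSV files; returns the path of each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pharmacy": outdir / "pharmacy.csv",
        "medical": outdir / "medical.csv",
        "enrollment": outdir / "enrollment.csv",
        "death": outdir / "death.csv",
        "code_map": outdir / "code_map.csv",
    }
    bundle.pharmacy.to_csv(paths["pharmacy"], index=False)
    bundle.medical.to_csv(paths["medical"], index=False)
    enr = bundle.enrollment
    if "birth_year" not in enr.columns:
        enr = enr.merge(bundle.subjects, on="subject_id", how="left")
    enr.to_csv(paths["enrollment"], index=False)
    bundle.death.to_csv(paths["death"], index=False)
    bundle.code_map.write_csv(paths["code_map"])
    return paths


def read_bundle_dir(bundle_dir, config: StudyConfig | None = None) -> ClaimsBundle:
    d = Path(bundle_dir)
    return read_claims_bundle(
        d / "pharmacy.csv",
        d / "medical.csv",
        d / "enrollment.csv",
        d / "death.csv",
        d / "code_map.csv",
        config=config,
    )


def write_report_tables(
    results: Mapping[str, pd.DataFrame],
    outdir,
    required: Sequence[str] = REPORT_SECTIONS,
) -> dict:
    """Render the analysis result tables as CSV files with deterministic
    column order; a missing section raises an error naming the absent
    analysis."""
    missing = [s for s in required if s not in results]
    if missing:
        raise ValidationError(f"missing report sections: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for section in required:
        df = results[section]
        path = outdir / f"{section}.csv"
        df.to_csv(path, index=False)
        paths[section] = path
    return paths
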