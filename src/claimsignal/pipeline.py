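"""End-to-end orchestration: bundle -> courses -> cohort -> episodes ->
matching -> estimation -> crossover, with a run manifest.

The stages log row counts after every filter so cohort attrition (eligible
-> dementia-diagnosed -> incident users / untreated) can be reconstructed
from the log alone.  A single configuration file governs a run; identical
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, exposure, inference, matching, outcomes
from .claims_model import (
    DEATH,
    ClaimsBundle,
    StudyConfig,
    ValidationError,
    read_bundle_dir,
    write_claims_bundle,
    write_report_tables,
)
from .synthetic_claims import preset, simulate_bundle

log = logging.getLogger("claimsignal")


@dataclass
class AnalysisResults:
    config: StudyConfig
    courses: pd.DataFrame
    indexed: pd.DataFrame
    baseline: pd.DataFrame
    censor: pd.DataFrame
    incidence: pd.DataFrame
    hazards: pd.DataFrame
    balance: pd.DataFrame
    crossover: pd.DataFrame
    matched: dict = field(default_factory=dict)

    def report_frames(self) -> dict:
        base_cols = [
            "age", "female", "comorbidity_count", "rx_risk_proxy",
            "n_clinic_visits", "n_hospitalizations", "n_ed_visits",
            "hospice", "nursing_home", "statin",
        ]
        rows = []
        for arm, sub in self.baseline.groupby("arm"):
            for c in base_cols:
                if c in sub:
                    rows.append((c, arm, float(sub[c].mean()), float(sub[c].std(ddof=1))))
        baseline_tbl = pd.DataFrame(rows, columns=["variable", "arm", "mean", "sd"])
        return {
            "baseline": baseline_tbl,
            "balance": self.balance,
            "incidence": self.incidence,
            "hazards": self.hazards,
            "crossover": self.crossover,
        }


def run_analysis(
    bundle: ClaimsBundle,
    config: StudyConfig,
    groups=None,
    do_crude: bool = True,
    do_matched: bool = True,
    do_incidence: bool = True,
    do_crossover: bool = True,
) -> AnalysisResults:
    """Run the full observational pipeline on one bundle.

    ``groups`` selects the analysed outcomes (default: all configured
    clinical groups plus death); restricting it is the supported way to
    speed up replicate studies.
    """
    groups = list(groups if groups is not None else config.analyses())
    clinical = [g for g in groups if g != DEATH]

    courses = exposure.incident_courses(bundle, config)
    log.info("courses: %d reconstructed, %d incident",
             len(courses), int(courses["is_incident"].sum()) if len(courses) else 0)
    eligible = cohort.find_eligible(bundle, config)
    log.info("eligible dementia subjects: %d", len(eligible))
    indexed = cohort.build_indexed(bundle, eligible, courses, config)
    n_t = int((indexed["arm"] == "treated").sum())
    log.info("indexed: %d treated, %d untreated", n_t, len(indexed) - n_t)
    baseline = cohort.compute_baseline(bundle, indexed, config)
    config.validate_covariates(baseline.columns)

    ev_frames = [outcomes.detect_events(bundle, g) for g in clinical]
    events = (
        pd.concat(ev_frames, ignore_index=True)
        if ev_frames
        else pd.DataFrame(columns=outcomes.EVENT_COLUMNS)
    )
    episodes = outcomes.cluster_episodes(events, config.episode_gap_days)
    log.info("events: %d claims in %d episodes", len(events), len(episodes))
    pw, censor = cohort.build_person_weeks(
        indexed, bundle, courses, config, groups, events, episodes
    )

    hazard_rows = []
    incidence_rows = []
    balance_frames = []
    matched_cohorts = {}
    treated_flags = (baseline["arm"] == "treated").to_numpy()
    for g in groups:
        if do_crude:
            try:
                hr = inference.fit_stratified_cox(pw, g, pairs=None, analysis="crude")
                hazard_rows.append(hr)
            except inference.InferenceError as exc:
                log.warning("crude %s: %s", g, exc)
        if do_matched:
            model = matching.fit_propensity(
                baseline, treated_flags, config.covariates[g], g,
                ridge_fallback=config.ridge_fallback,
            )
            mc = matching.mahalanobis_match(
                baseline,
                treated_flags,
                model,
                key_covariates=config.key_covariates.get(g, ()),
                exact_vars=config.exact_match.get(g, ()),
                band_vars=config.band_match.get(g),
                caliper_sd=config.caliper_sd,
            )
            matched_cohorts[g] = mc
            log.info("matched %s: %d pairs, %d treated unmatched",
                     g, len(mc.pairs), mc.n_unmatched_treated)
            bal = matching.balance(mc, baseline, config.covariates[g])
            bal.insert(0, "outcome", g)
            balance_frames.append(bal)
            adjust = None
            if config.adjust_covariates.get(g):
                adjust = baseline.set_index("subject_id")[config.adjust_covariates[g]]
            try:
                hr = inference.fit_stratified_cox(
                    pw, g, pairs=mc.stratum_map(), adjust=adjust, analysis="matched"
                )
                hazard_rows.append(hr)
            except inference.InferenceError as exc:
                log.warning("matched %s: %s", g, exc)
        if do_incidence:
            for arm, subset in (
                ("treated", None),
                ("untreated", None),
                ("matched_untreated", matched_cohorts[g].pairs["untreated_id"]
                 if g in matched_cohorts else None),
            ):
                if arm == "matched_untreated" and subset is None:
                    continue
                try:
                    res = inference.compute_incidence(
                        pw, censor, g, arm.replace("matched_", ""), subset,
                        config.week_length_days,
                    )
                    res.arm = arm
                    incidence_rows.append(res)
                except inference.InferenceError as exc:
                    log.warning("incidence %s/%s: %s", g, arm, exc)

    crossover_rows = []
    if do_crossover and clinical:
        windows = inference.build_windows(bundle, courses, config, clinical)
        for g in clinical:
            for contrast in inference.CONTRASTS:
                try:
                    crossover_rows.append(inference.crossover_or(windows, g, contrast))
                except inference.InferenceError as exc:
                    log.warning("crossover %s/%s: %s", g, contrast, exc)

    hazards = pd.DataFrame([dataclasses.asdict(h) for h in hazard_rows]).drop(
        columns=["coefficients"], errors="ignore"
    )
    incidence = pd.DataFrame([dataclasses.asdict(r) for r in incidence_rows])
    balance_tbl = (
        pd.concat(balance_frames, ignore_index=True)
        if balance_frames
        else pd.DataFrame(columns=["outcome", "covariate", "treated_mean",
                                   "untreated_mean", "p_value", "smd"])
    )
    crossover = pd.DataFrame([dataclasses.asdict(r) for r in crossover_rows])
    return AnalysisResults(
        config=config,
        courses=courses,
        indexed=indexed,
        baseline=baseline,
        censor=censor,
        incidence=incidence,
        hazards=hazards,
        balance=balance_tbl,
        crossover=crossover,
        matched=matched_cohorts,
    )


# ---------------------------------------------------------------------------
# config-file driven runs
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list
    outputs: list

    def to_text(self) -> str:
        lines = [
            f"claimsignal {self.version}",
            f"config_hash: {self.config_hash}",
            f"seed: {self.seed}",
            "stages:",
        ]
        lines += [f"  - {name}: {count} rows" for name, count in self.stages]
        lines += ["outputs:"] + [f"  - {p}" for p in self.outputs]
        return "\n".join(lines) + "\n"


def load_run_config(path) -> tuple[StudyConfig, dict]:
    """Parse a pipeline YAML file: a ``study:`` section of StudyConfig
    overrides plus either ``simulate: {preset, n_subjects}`` or
    ``input: {bundle_dir}``."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    study = StudyConfig(**(data.get("study") or {}))
    source = {k: data[k] for k in ("simulate", "input") if k in data}
    if len(source) != 1:
        raise ValidationError("config must name exactly one of 'simulate' or 'input'")
    return study, source


def run_pipeline(config_path, outdir) -> RunManifest:
    """Execute the full pipeline from one configuration file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config, source = load_run_config(config_path)
    for g in config.outcome_groups:
        if g not in config.covariates:
            raise ValidationError(f"no covariate list configured for outcome {g!r}")

    if "simulate" in source:
        sim = source["simulate"]
        spec = preset(
            sim.get("preset", "null_all"),
            n_subjects=int(sim.get("n_subjects", 4000)),
            seed=int(sim.get("seed", config.seed)),
        )
        bundle, _ = simulate_bundle(spec, config)
        write_claims_bundle(bundle, outdir / "bundle")
        log.info("simulated bundle: %d subjects", spec.n_subjects)
    else:
        bundle = read_bundle_dir(source["input"]["bundle_dir"], config)

    results = run_analysis(bundle, config)
    results.courses.to_csv(outdir / "courses.csv", index=False)
    results.indexed.to_csv(outdir / "cohort.csv", index=False)
    results.censor.to_csv(outdir / "censor.csv", index=False)
    paths = write_report_tables(results.report_frames(), outdir)
    stages = [
        ("courses", len(results.courses)),
        ("indexed", len(results.indexed)),
        ("baseline", len(results.baseline)),
        ("hazards", len(results.hazards)),
        ("incidence", len(results.incidence)),
        ("crossover", len(results.crossover)),
    ]
    outputs = sorted(
        str(p.relative_to(outdir))
        for p in list(paths.values())
        + [outdir / "courses.csv", outdir / "cohort.csv", outdir / "censor.csv"]
    )
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        stages=stages,
        outputs=outputs,
    )
    (outdir / "manifest.txt").write_text(manifest.to_text())
    return manifest
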