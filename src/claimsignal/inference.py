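"""Effect estimation: incidence densities, pair-stratified recurrent-event
Cox models, and case-crossover odds ratios.

The cohort contrast is estimated with a Cox proportional-hazards model on
the weekly counting-process table: episode starts are recurrent events, each
matched pair is a stratum (the crude analysis is the same fit with a single
stratum), ties are handled with the Breslow approximation — natural here
because person-time is discrete — and the variance is a robust sandwich
clustered on subject.  The partial likelihood involves only risk sets at
event times, so the solver collapses the person-week table to those risk
sets and runs Newton iterations on the collapsed arrays; this keeps
replicate-scale simulation studies cheap without changing the estimand.

The case-crossover design compares, within treated subjects, event odds in
the first and second 6-week treatment windows against a pre-treatment
referent window anchored at the week after the most recent baseline clinic
visit.  With one binary observation per window the conditional-likelihood
odds ratio is the discordant-pair ratio n10/n01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _util
from .claims_model import DEATH, ClaimsBundle, StudyConfig

DAYS_PER_YEAR = 365.25


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# incidence density
# ---------------------------------------------------------------------------


@dataclass
class IncidenceResult:
    group_label: str
    arm: str
    n_episodes: int
    person_years: float
    density: float  # per 100 person-years
    ci_low: float
    ci_high: float


def incidence_density(
    n_episodes: int,
    at_risk_weeks: float,
    group_label: str = "",
    arm: str = "",
    week_days: int = 7,
) -> IncidenceResult:
    """Episodes per 100 person-years with a normal-approximation CI.

    Zero events fall back to the exact Poisson upper bound
    (3.69 events / person-time).
    """
    if at_risk_weeks <= 0:
        raise InferenceError("zero person-time")
    py = at_risk_weeks * week_days / DAYS_PER_YEAR
    density = 100.0 * n_episodes / py
    if n_episodes == 0:
        lo, hi = 0.0, 3.69 * 100.0 / py
    else:
        half = 1.96 * density / np.sqrt(n_episodes)
        lo, hi = max(density - half, 0.0), density + half
    return IncidenceResult(
        group_label=group_label,
        arm=arm,
        n_episodes=int(n_episodes),
        person_years=float(py),
        density=float(density),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def compute_incidence(
    pw: pd.DataFrame,
    censor: pd.DataFrame,
    group: str,
    arm: str,
    subject_subset=None,
    week_days: int = 7,
) -> IncidenceResult:
    """Incidence density for one arm (optionally restricted to a subject
    subset, e.g. the matched untreated cohort)."""
    ids = censor.loc[censor["arm"] == arm, "subject_id"]
    if subject_subset is not None:
        ids = ids[ids.isin(set(subject_subset))]
    sub = pw[pw["subject_id"].isin(set(ids)) & pw["at_risk"]]
    n_ev = int(sub[f"epstart_{group}"].sum())
    return incidence_density(n_ev, float(len(sub)), group, arm, week_days)


# ---------------------------------------------------------------------------
# stratified recurrent-event Cox
# ---------------------------------------------------------------------------


@dataclass
class HazardResult:
    group_label: str
    analysis: str  # crude | matched
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    n_subjects: int
    log_hr: float = np.nan
    se: float = np.nan
    monotone: bool = False
    coefficients: dict = field(default_factory=dict)


def fit_stratified_cox(
    pw: pd.DataFrame,
    group: str,
    pairs: pd.Series | None = None,
    exposure_col: str = "exposed",
    adjust: pd.DataFrame | None = None,
    analysis: str | None = None,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> HazardResult:
    """Breslow partial-likelihood fit on the weekly counting-process table.

    Parameters
    ----------
    pw : person-week table with ``at_risk``, the exposure column, and an
        ``epstart_<group>`` event column.
    pairs : optional Series mapping subject_id -> stratum (pair id).  When
        given, the analysis is restricted to mapped subjects and stratified;
        otherwise a single stratum is used (crude analysis).
    adjust : optional per-subject frame (indexed by subject_id) of extra
        covariates entering the linear predictor alongside exposure.

    A monotone likelihood (all events on one arm within every informative
    risk set) is flagged and reported with an infinite confidence bound.
    """
    event_col = f"epstart_{group}"
    rows = pw[pw["at_risk"]]
    if pairs is not None:
        pairs = pairs[~pairs.index.duplicated()]
        rows = rows[rows["subject_id"].isin(set(pairs.index))]
        stratum = pairs.reindex(rows["subject_id"]).to_numpy()
    else:
        stratum = np.zeros(len(rows), dtype=np.int64)
    if len(rows) == 0 or rows[event_col].sum() == 0:
        raise InferenceError(f"no events for {group!r}")

    subj, subj_ids = pd.factorize(rows["subject_id"], sort=False)
    week = rows["week"].to_numpy()
    d_events = rows[event_col].to_numpy(dtype=np.int64)
    cols = [exposure_col]
    X = [rows[exposure_col].to_numpy(dtype=float)]
    if adjust is not None:
        for c in adjust.columns:
            X.append(adjust[c].reindex(rows["subject_id"]).to_numpy(dtype=float))
            cols.append(c)
    X = np.column_stack(X)
    p = X.shape[1]

    WK = np.int64(1 << 20)
    key = np.asarray(stratum, dtype=np.int64) * WK + week
    ev_keys = np.unique(key[d_events > 0])
    pos = np.searchsorted(ev_keys, key)
    pos_valid = pos < len(ev_keys)
    in_rs = np.zeros(len(rows), dtype=bool)
    in_rs[pos_valid] = ev_keys[pos[pos_valid]] == key[pos_valid]

    k_idx = pos[in_rs]  # risk-set index per collapsed row
    Xr = X[in_rs]
    subj_r = subj[in_rs]
    dr = d_events[in_rs]
    K = len(ev_keys)
    d_k = np.zeros(K)
    np.add.at(d_k, k_idx, dr)
    sum_x_events = (Xr * dr[:, None]).sum(axis=0)
    n_events = int(dr.sum())

    beta = np.zeros(p)
    converged = False
    hess = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(Xr @ beta, -500, 500)
        w = np.exp(eta)
        S0 = np.zeros(K)
        np.add.at(S0, k_idx, w)
        S1 = np.zeros((K, p))
        S2 = np.zeros((K, p, p))
        wX = w[:, None] * Xr
        for a in range(p):
            np.add.at(S1[:, a], k_idx, wX[:, a])
            for b in range(a, p):
                np.add.at(S2[:, a, b], k_idx, wX[:, a] * Xr[:, b])
                if b > a:
                    S2[:, b, a] = S2[:, a, b]
        xbar = S1 / S0[:, None]
        grad = sum_x_events - (d_k[:, None] * xbar).sum(axis=0)
        hess = -(
            d_k[:, None, None]
            * (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta - step
        if np.abs(beta_new).max() > 20:
            beta = np.clip(beta_new, -20, 20)
            break
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    monotone = (not converged) or abs(beta[0]) > 8
    info = -hess
    # robust sandwich: clusters are matched pairs when stratified (a pair's
    # member contributions are dependent; the pair nests the subject's
    # recurrent events), otherwise subjects
    if pairs is not None:
        cl, _ = pd.factorize(stratum[in_rs], sort=False)
    else:
        cl = subj_r
    n_clusters = int(cl.max()) + 1 if len(cl) else 0
    se = np.nan
    cov = np.full((p, p), np.nan)
    if not monotone:
        eta = np.clip(Xr @ beta, -500, 500)
        w = np.exp(eta)
        S0 = np.zeros(K)
        np.add.at(S0, k_idx, w)
        S1 = np.zeros((K, p))
        for a in range(p):
            np.add.at(S1[:, a], k_idx, w * Xr[:, a])
        xbar = S1 / S0[:, None]
        resid_rows = (dr[:, None] - (d_k[k_idx] * w / S0[k_idx])[:, None]) * (
            Xr - xbar[k_idx]
        )
        U = np.zeros((n_clusters, p))
        np.add.at(U, cl, resid_rows)
        try:
            Hinv = np.linalg.inv(info)
            cov = Hinv @ (U.T @ U) @ Hinv
            se = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            monotone = True

    log_hr = float(beta[0])
    if monotone or not np.isfinite(se) or se == 0:
        hr = float(np.exp(log_hr))
        lo, hi = (0.0, np.inf)
        pval = np.nan
        monotone = True
    else:
        hr = float(np.exp(log_hr))
        lo = float(np.exp(log_hr - 1.96 * se))
        hi = float(np.exp(log_hr + 1.96 * se))
        pval = float(2 * stats.norm.sf(abs(log_hr) / se))
    return HazardResult(
        group_label=group,
        analysis=analysis or ("matched" if pairs is not None else "crude"),
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        p_value=pval,
        n_events=n_events,
        n_subjects=int(len(subj_ids)),
        log_hr=log_hr,
        se=se,
        monotone=monotone,
        coefficients=dict(zip(cols, beta)),
    )


# ---------------------------------------------------------------------------
# case-crossover windows and odds ratios
# ---------------------------------------------------------------------------

WINDOWS = ("pre", "w1", "w2")
CONTRASTS = {"w1_vs_pre": "w1", "w2_vs_pre": "w2"}


def build_windows(
    bundle: ClaimsBundle,
    courses: pd.DataFrame,
    config: StudyConfig,
    groups=None,
) -> pd.DataFrame:
    """Three 6-week windows per incident user with per-group event flags.

    ``w1`` starts at the first-dispensing week (week 0), ``w2`` immediately
    after; the pre-treatment window starts the week after the latest baseline
    clinic visit that lets it end before week 0.  A window is eligible only
    when it is fully observed: inside the study period, fully enrolled, and
    the subject survives through its last week.  At most one event per
    window counts.
    """
    groups = list(groups if groups is not None else config.outcome_groups)
    inc = courses[courses["is_incident"]].reset_index(drop=True)
    cols = ["subject_id", "window", "start_week", "end_week", "eligible"] + [
        f"event_{g}" for g in groups
    ]
    if len(inc) == 0:
        return pd.DataFrame(columns=cols)
    W = config.window_weeks
    wk = config.week_length_days
    index = _util.SubjectIndex(bundle.subjects["subject_id"])
    cum = _util.enrollment_cumulative(bundle.enrollment, index, config.n_months)
    death = bundle.death.set_index("subject_id")["death_day"]

    anchor = inc["start_day"].to_numpy()
    codes = index.code(inc["subject_id"]).astype(int)
    n = len(inc)
    death_day = death.reindex(inc["subject_id"]).fillna(np.int64(1 << 40)).to_numpy(np.int64)

    med = bundle.medical
    clinic = med[med["setting"] == "outpatient"][["subject_id", "service_day"]]
    clinic = clinic.merge(
        pd.DataFrame({"subject_id": inc["subject_id"], "_anchor": anchor}),
        on="subject_id",
    )
    rel_week = (clinic["service_day"] - clinic["_anchor"]) // wk
    in_baseline = (clinic["service_day"] >= clinic["_anchor"] - config.washout_days) & (
        rel_week <= -(W + 1)
    )
    latest = (
        clinic[in_baseline]
        .assign(_w=rel_week[in_baseline])
        .groupby("subject_id")["_w"]
        .max()
    )
    pre_start = latest.reindex(inc["subject_id"]).to_numpy() + 1  # NaN if no visit

    group_keys = {
        g: _util.sorted_event_keys(
            index,
            med.loc[med["primary_dx"].isin(bundle.code_map.codes(g)), "subject_id"],
            med.loc[med["primary_dx"].isin(bundle.code_map.codes(g)), "service_day"],
        )
        for g in groups
    }

    frames = []
    for name, start in (("pre", pre_start), ("w1", np.zeros(n)), ("w2", np.full(n, W))):
        has = ~np.isnan(start)
        s = np.where(has, start, 0).astype(np.int64)
        e = s + W - 1
        day_lo = anchor + s * wk
        day_hi = anchor + e * wk + wk - 1
        eligible = (
            has
            & (day_lo >= config.study_start_day)
            & (day_hi <= config.study_end_day)
            & (death_day > day_hi)
            & _util.fully_enrolled(
                cum, codes, day_lo // config.month_length_days,
                day_hi // config.month_length_days,
            )
        )
        frame = pd.DataFrame(
            {
                "subject_id": inc["subject_id"],
                "window": name,
                "start_week": np.where(has, s, np.nan),
                "end_week": np.where(has, e, np.nan),
                "eligible": eligible,
            }
        )
        for g in groups:
            cnt = _util.window_counts(group_keys[g], codes, day_lo, day_hi)
            frame[f"event_{g}"] = np.where(eligible, np.minimum(cnt, 1), 0)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[cols]


@dataclass
class CrossoverResult:
    group_label: str
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n10: int  # event in treatment window only
    n01: int  # event in pre window only
    n11: int
    n00: int
    n_pairs: int
    degenerate: bool = False


def crossover_or(windows: pd.DataFrame, group: str, contrast: str) -> CrossoverResult:
    """Conditional-likelihood odds ratio for one window contrast.

    Restricted to subjects eligible for both windows of the contrast; the
    1:1 paired-binary estimate is n10/n01 with a Wald CI on the log scale.
    An empty discordant cell makes the OR degenerate; it is then reported
    with a one-sided exact (Clopper-Pearson) bound and a warning.
    """
    if contrast not in CONTRASTS:
        raise InferenceError(f"unknown contrast {contrast!r}; use {list(CONTRASTS)}")
    tw = CONTRASTS[contrast]
    pre = windows[(windows["window"] == "pre") & windows["eligible"]]
    trt = windows[(windows["window"] == tw) & windows["eligible"]]
    m = pre[["subject_id", f"event_{group}"]].merge(
        trt[["subject_id", f"event_{group}"]],
        on="subject_id",
        suffixes=("_pre", "_trt"),
    )
    if len(m) == 0:
        raise InferenceError("no subject eligible for both windows")
    ep = m[f"event_{group}_pre"].to_numpy(dtype=bool)
    et = m[f"event_{group}_trt"].to_numpy(dtype=bool)
    n10 = int((et & ~ep).sum())
    n01 = int((~et & ep).sum())
    n11 = int((et & ep).sum())
    n00 = int((~et & ~ep).sum())
    md = n10 + n01
    alpha = 0.05

    if md == 0:
        warnings.warn(f"{group}/{contrast}: all subjects concordant; OR undefined")
        return CrossoverResult(group, contrast, np.nan, np.nan, np.nan, np.nan,
                               n10, n01, n11, n00, len(m), degenerate=True)
    if n10 == 0 or n01 == 0:
        warnings.warn(
            f"{group}/{contrast}: empty discordant cell (n10={n10}, n01={n01}); "
            "reporting one-sided exact bound"
        )
        pval = float(min(1.0, 2 * 0.5**md))
        if n10 == 0:
            pu = 1 - (alpha / 2) ** (1 / md)
            return CrossoverResult(group, contrast, 0.0, 0.0, pu / (1 - pu), pval,
                                   n10, n01, n11, n00, len(m), degenerate=True)
        pl = (alpha / 2) ** (1 / md)
        return CrossoverResult(group, contrast, np.inf, pl / (1 - pl), np.inf, pval,
                               n10, n01, n11, n00, len(m), degenerate=True)
    or_ = n10 / n01
    se = np.sqrt(1 / n10 + 1 / n01)
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    pval = float(2 * stats.norm.sf(abs(np.log(or_)) / se))
    return CrossoverResult(group, contrast, float(or_), lo, hi, pval,
                           n10, n01, n11, n00, len(m))
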