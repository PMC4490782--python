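import subprocess

import numpy as np
import pandas as pd
import pytest

from claimsignal.claims_model import StudyConfig
from claimsignal.exposure import incident_courses
from claimsignal.inference import (
    InferenceError,
    build_windows,
    crossover_or,
    fit_stratified_cox,
    incidence_density,
)
from conftest import make_bundle

CFG = StudyConfig()


def pair_data(rng, n_pairs=60, hr=2.0, het=0.3):
    rows = []
    for k in range(n_pairs):
        h = 0.02 * np.exp(rng.normal(0, het))
        for sid, ex, length, hz in (
            (2 * k, 1, int(rng.integers(20, 40)), hr * h),
            (2 * k + 1, 0, int(rng.integers(30, 70)), h),
        ):
            ev = rng.random(length) < hz
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "stratum": k,
                        "week": np.arange(length),
                        "at_risk": True,
                        "exposed": ex,
                        "epstart_x": ev.astype(int),
                    }
                )
            )
    pw = pd.concat(rows, ignore_index=True)
    pairs = pd.Series(pw.stratum.values, index=pw.subject_id.values)
    return pw, pairs[~pairs.index.duplicated()]


class TestIncidenceDensity:
    def test_rate_arithmetic(self):
        weeks = 50.0 * 365.25 / 7  # exactly 50 person-years
        r = incidence_density(10, weeks)
        assert r.density == pytest.approx(20.0)

    def test_zero_events_exact_poisson_upper_bound(self):
        weeks = 100.0 * 365.25 / 7
        r = incidence_density(0, weeks)
        assert r.density == 0.0
        assert (r.ci_low, r.ci_high) == (0.0, pytest.approx(3.69, abs=1e-9))

    def test_published_scale_reproduced(self):
        # 78 episodes over 282.6 person-years -> 27.6 per 100 PY
        weeks = 282.6 * 365.25 / 7
        r = incidence_density(78, weeks)
        assert r.density == pytest.approx(27.6, abs=0.05)

    def test_invariant_to_splitting_follow_up(self):
        a = incidence_density(7, 800.0)
        b = incidence_density(7, 500.0 + 300.0)
        assert a.density == b.density

    def test_zero_person_time_rejected(self):
        with pytest.raises(InferenceError, match="person-time"):
            incidence_density(3, 0.0)


class TestStratifiedCox:
    def test_matches_r_coxph_breslow_with_robust_se(self, tmp_path):
        pw, pairs = pair_data(np.random.default_rng(7), n_pairs=40)
        mine = fit_stratified_cox(pw, "x", pairs)
        d = pw.copy()
        d["stratum_id"] = d.subject_id.map(pairs)
        d["stop"] = d.week + 1
        csv = tmp_path / "cox.csv"
        d.to_csv(csv, index=False)
        out = subprocess.run(
            ["Rscript", "-e", f"""
library(survival)
d <- read.csv('{csv}')
f <- coxph(Surv(week, stop, epstart_x) ~ exposed + strata(stratum_id)
           + cluster(stratum_id), data=d, ties='breslow')
cat(sprintf('%.8f %.8f', coef(f), summary(f)$coefficients[1,'robust se']))
"""],
            capture_output=True, text=True, check=True,
        )
        beta_r, se_r = map(float, out.stdout.split())
        assert mine.log_hr == pytest.approx(beta_r, abs=1e-6)
        assert mine.se == pytest.approx(se_r, rel=1e-4)

    def test_single_stratum_equals_pairs_collapsed_to_one(self):
        pw, pairs = pair_data(np.random.default_rng(3), n_pairs=30)
        crude = fit_stratified_cox(pw, "x", pairs=None)
        one = fit_stratified_cox(pw, "x", pairs=(pairs * 0))
        assert one.log_hr == pytest.approx(crude.log_hr, abs=1e-9)

    def test_wald_interval_contains_point_estimate(self):
        pw, pairs = pair_data(np.random.default_rng(5))
        r = fit_stratified_cox(pw, "x", pairs)
        assert r.ci_low < r.hazard_ratio < r.ci_high
        assert r.hazard_ratio > 0

    def test_monotone_likelihood_flagged(self):
        # one pair: treated event week 3, untreated censored week 10
        rows = []
        for sid, ex, length in ((0, 1, 4), (1, 0, 11)):
            ev = np.zeros(length, int)
            if ex:
                ev[3] = 1
            rows.append(pd.DataFrame({"subject_id": sid, "stratum": 0,
                                      "week": np.arange(length), "at_risk": True,
                                      "exposed": ex, "epstart_x": ev}))
        pw = pd.concat(rows, ignore_index=True)
        pairs = pd.Series([0, 0], index=[0, 1])
        r = fit_stratified_cox(pw, "x", pairs)
        assert r.monotone
        assert np.isinf(r.ci_high) or r.ci_high == 0.0

    def test_no_events_rejected(self):
        pw, pairs = pair_data(np.random.default_rng(1), n_pairs=4)
        pw["epstart_x"] = 0
        with pytest.raises(InferenceError, match="no events"):
            fit_stratified_cox(pw, "x", pairs)

    def test_covariate_adjustment_runs_within_strata(self):
        pw, pairs = pair_data(np.random.default_rng(9), n_pairs=50)
        adjust = pd.DataFrame(
            {"z": np.random.default_rng(0).normal(size=pairs.size)},
            index=pairs.index,
        )
        r = fit_stratified_cox(pw, "x", pairs, adjust=adjust)
        assert "z" in r.coefficients and np.isfinite(r.coefficients["z"])


class TestBuildWindows:
    def bundle_with_course(self, extra_medical=(), death=None):
        med = [(1, d, c, s) for d, c, s in extra_medical]
        med.append((1, 50, "C00", "outpatient"))
        return make_bundle(
            pharmacy=[(1, 280, 30, "ACHEI"), (1, 310, 30, "ACHEI")],
            medical=med,
            enrollment=[(1, 0, 36)],
            death=death,
        )

    def test_pre_window_anchored_after_latest_qualifying_visit(self):
        # clinic visits at relative weeks -20 and -9 -> pre window -8..-3
        b = self.bundle_with_course(
            extra_medical=[(280 - 140, "C00", "outpatient"), (280 - 63, "C00", "outpatient")]
        )
        w = build_windows(b, incident_courses(b, CFG), CFG, ["gastrointestinal"])
        pre = w[w.window == "pre"].iloc[0]
        assert (pre.start_week, pre.end_week) == (-8, -3)
        assert pre.eligible

    def test_visit_too_close_to_index_skipped_for_earlier_anchor(self):
        # the week -4 visit cannot anchor a pre window ending before week 0;
        # the earlier week -19 visit is used instead
        b = make_bundle(
            pharmacy=[(1, 280, 30, "ACHEI")],
            medical=[(1, 280 - 28, "C00", "outpatient"),
                     (1, 280 - 133, "C00", "outpatient"),
                     (1, 110, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        w = build_windows(b, incident_courses(b, CFG), CFG, ["gastrointestinal"])
        pre = w[w.window == "pre"].iloc[0]
        assert (pre.start_week, pre.end_week) == (-18, -13)

    def test_no_qualifying_baseline_visit_gives_no_pre_window(self):
        b = make_bundle(
            pharmacy=[(1, 280, 30, "ACHEI")],
            medical=[(1, 280 - 28, "C00", "outpatient"), (1, 50, "C00", "outpatient")],
            enrollment=[(1, 0, 36)],
        )
        w = build_windows(b, incident_courses(b, CFG), CFG, ["gastrointestinal"])
        pre = w[w.window == "pre"].iloc[0]
        assert not pre.eligible

    def test_death_in_week_eight_invalidates_second_window(self):
        b = self.bundle_with_course(
            extra_medical=[(130, "C00", "outpatient")], death=[(1, 280 + 60)]
        )
        w = build_windows(b, incident_courses(b, CFG), CFG, ["gastrointestinal"]).set_index("window")
        assert w.loc["pre"].eligible and w.loc["w1"].eligible
        assert not w.loc["w2"].eligible

    def test_event_capped_at_one_per_window(self):
        b = self.bundle_with_course(
            extra_medical=[(130, "C00", "outpatient"),
                           (285, "G01", "outpatient"), (300, "G02", "outpatient")]
        )
        w = build_windows(b, incident_courses(b, CFG), CFG, ["gastrointestinal"]).set_index("window")
        assert w.loc["w1"].event_gastrointestinal == 1


class TestCrossoverOR:
    def windows_from_counts(self, n10, n01, n11=0, n00=0):
        rows = []
        sid = 0
        for (et, ep), count in (((1, 0), n10), ((0, 1), n01), ((1, 1), n11), ((0, 0), n00)):
            for _ in range(count):
                rows.append((sid, "pre", -8, -3, True, ep))
                rows.append((sid, "w1", 0, 5, True, et))
                sid += 1
        return pd.DataFrame(
            rows, columns=["subject_id", "window", "start_week", "end_week",
                           "eligible", "event_gastrointestinal"]
        )

    def test_discordant_pair_closed_form(self):
        w = self.windows_from_counts(4, 2, n00=4)
        r = crossover_or(w, "gastrointestinal", "w1_vs_pre")
        assert r.odds_ratio == pytest.approx(2.0)
        assert (r.n10, r.n01) == (4, 2)

    def test_symmetric_discordance_gives_exactly_one(self):
        r = crossover_or(self.windows_from_counts(5, 5), "gastrointestinal", "w1_vs_pre")
        assert r.odds_ratio == 1.0

    def test_all_concordant_warns_and_is_degenerate(self):
        with pytest.warns(UserWarning, match="concordant"):
            r = crossover_or(
                self.windows_from_counts(0, 0, n11=3, n00=5),
                "gastrointestinal", "w1_vs_pre",
            )
        assert r.degenerate and np.isnan(r.odds_ratio)

    def test_empty_cell_reports_one_sided_bound(self):
        with pytest.warns(UserWarning, match="discordant"):
            r = crossover_or(self.windows_from_counts(3, 0), "gastrointestinal", "w1_vs_pre")
        assert r.degenerate and np.isinf(r.odds_ratio) and np.isfinite(r.ci_low)

    def test_matches_conditional_logistic_fit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        w = self.windows_from_counts(7, 3, n11=2, n00=6)
        r = crossover_or(w, "gastrointestinal", "w1_vs_pre")
        pre = w[w.window == "pre"].set_index("subject_id").event_gastrointestinal
        trt = w[w.window == "w1"].set_index("subject_id").event_gastrointestinal
        y = np.column_stack([trt.sort_index(), pre.sort_index()]).ravel()
        x = np.tile([1.0, 0.0], len(pre))
        g = np.repeat(np.arange(len(pre)), 2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ConditionalLogit(y, x.reshape(-1, 1), groups=g).fit(
                disp=0, method="newton"
            )
        assert np.log(r.odds_ratio) == pytest.approx(fit.params[0], abs=1e-6)

    def test_unknown_contrast_rejected(self):
        with pytest.raises(InferenceError, match="contrast"):
            crossover_or(self.windows_from_counts(1, 1), "gastrointestinal", "w3_vs_pre")
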