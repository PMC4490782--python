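"""Per-outcome propensity models, Mahalanobis metric matching within a
propensity caliper, and covariate-balance diagnostics.

Because risk factors as well as confounders enter each propensity model, one
model and one matched cohort is built per study outcome.  Matching is 1:1
greedy nearest-neighbour without replacement: candidates must fall within a
caliper on the logit propensity (default 0.2 standard deviations) and agree
exactly on designated key prognostic covariates (or within a band, e.g.
baseline age within +-5 years for the death analysis); among admissible
candidates the one at the smallest Mahalanobis distance over (logit score,
key covariates) wins, with pooled within-arm covariance and a deterministic
tie-break on the smaller untreated identifier.  Treated subjects are
processed hardest-to-match first (descending logit score).

Balance tables report Welch t-tests for continuous covariates, uncorrected
Pearson chi-square tests for binary ones, and the standardized mean
difference (mean difference over the pooled-variance scale).  These are
diagnostics, not inference; no multiplicity adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class MatchingError(ValueError):
    pass


@dataclass
class PropensityModel:
    outcome_label: str
    covariates: list
    params: pd.Series
    score: np.ndarray  # P(treated | X), original row order
    logit_score: np.ndarray
    subject_id: np.ndarray


@dataclass
class MatchedCohort:
    outcome_label: str
    pairs: pd.DataFrame  # pair_id, treated_id, untreated_id, distance
    caliper: float
    exact_vars: tuple
    band_vars: dict
    n_unmatched_treated: int

    @property
    def subject_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.pairs["treated_id"].to_numpy(), self.pairs["untreated_id"].to_numpy()]
        )

    def stratum_map(self) -> pd.Series:
        """subject_id -> pair_id for stratified analyses."""
        s = pd.concat(
            [
                pd.Series(self.pairs["pair_id"].to_numpy(), index=self.pairs["treated_id"]),
                pd.Series(self.pairs["pair_id"].to_numpy(), index=self.pairs["untreated_id"]),
            ]
        )
        s.index.name = "subject_id"
        return s


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def fit_propensity(
    baseline: pd.DataFrame,
    treated,
    covariates,
    outcome_label: str = "",
    ridge_fallback: bool = False,
) -> PropensityModel:
    """Maximum-likelihood logistic regression of treatment on baseline
    covariates, with intercept; continuous covariates are standardized
    internally and coefficients reported on the standardized scale.

    Perfect separation raises a MatchingError recommending covariate review
    (or set ``ridge_fallback`` to fall back to an L2-penalized fit).
    """
    y = np.asarray(treated, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise MatchingError("both arms must be non-empty to fit a propensity model")
    missing = [c for c in covariates if c not in baseline.columns]
    if missing:
        raise MatchingError(f"covariates not present in baseline table: {missing}")
    X = baseline[list(covariates)].astype(float).copy()
    for c in covariates:
        if not _is_binary(X[c]):
            sd = X[c].std(ddof=1)
            X[c] = (X[c] - X[c].mean()) / (sd if sd > 0 else 1.0)
    Xd = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        converged = res.mle_retvals.get("converged", True)
        params = res.params
    except Exception:
        converged = False
        params = None
    if params is None or not converged or np.abs(np.asarray(params)).max() > 15:
        if not ridge_fallback:
            raise MatchingError(
                f"propensity model for {outcome_label!r} did not converge "
                "(possible perfect separation); review covariates or enable "
                "the ridge fallback"
            )
        # weak L2 penalty: bounds separated coefficients, barely shrinks the rest
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=10.0, max_iter=2000)
        lr.fit(X.to_numpy(), y)
        params = pd.Series(
            np.concatenate([[lr.intercept_[0]], lr.coef_[0]]), index=Xd.columns
        )
    eta = np.asarray(Xd @ params, dtype=float)
    eta = np.clip(eta, -30, 30)
    score = 1.0 / (1.0 + np.exp(-eta))
    return PropensityModel(
        outcome_label=outcome_label,
        covariates=list(covariates),
        params=pd.Series(np.asarray(params), index=Xd.columns),
        score=score,
        logit_score=eta,
        subject_id=baseline["subject_id"].to_numpy(),
    )


def mahalanobis_match(
    baseline: pd.DataFrame,
    treated,
    model: PropensityModel,
    key_covariates=(),
    exact_vars=(),
    band_vars=None,
    caliper_sd: float = 0.2,
    metric: str = "pooled",
) -> MatchedCohort:
    """1:1 greedy Mahalanobis matching within a logit-propensity caliper.

    ``band_vars`` maps a covariate name to a half-width; candidates must lie
    within that absolute difference (banded matching, e.g. age +-5 years).
    ``metric="pooled"`` uses the pooled within-arm covariance (classic
    Mahalanobis, for small key sets); ``metric="diagonal"`` standardizes each
    feature independently, which is preferable when the key set is large or
    nearly collinear.
    """
    band_vars = dict(band_vars or {})
    treated = np.asarray(treated, dtype=bool)
    ids = baseline["subject_id"].to_numpy()
    logit = model.logit_score
    feats = [logit]
    for c in key_covariates:
        feats.append(baseline[c].to_numpy(dtype=float))
    Z = np.column_stack(feats)

    t_mask, u_mask = treated, ~treated
    nt, nu = int(t_mask.sum()), int(u_mask.sum())
    if nt == 0 or nu == 0:
        raise MatchingError("both arms must be non-empty for matching")
    cov_t = np.cov(Z[t_mask], rowvar=False, ddof=1) if nt > 1 else np.zeros((Z.shape[1],) * 2)
    cov_u = np.cov(Z[u_mask], rowvar=False, ddof=1) if nu > 1 else np.zeros((Z.shape[1],) * 2)
    cov_t = np.atleast_2d(cov_t)
    cov_u = np.atleast_2d(cov_u)
    pooled = ((nt - 1) * cov_t + (nu - 1) * cov_u) / max(nt + nu - 2, 1)
    if metric == "diagonal":
        pooled = np.diag(np.maximum(np.diag(pooled), 1e-12))
    elif metric != "pooled":
        raise MatchingError(f"unknown metric {metric!r}; use 'pooled' or 'diagonal'")
    pooled = pooled + 1e-12 * np.eye(pooled.shape[0])
    try:
        L = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        names = ["logit_score", *key_covariates]
        w, v = np.linalg.eigh(pooled)
        worst = names[int(np.argmax(np.abs(v[:, 0])))]
        raise MatchingError(
            f"singular matching covariance; near-collinear covariate: {worst}"
        )

    caliper = caliper_sd * float(np.std(logit, ddof=1))
    exact = baseline[list(exact_vars)].to_numpy(dtype=float) if exact_vars else None
    bands = {c: (baseline[c].to_numpy(dtype=float), w) for c, w in band_vars.items()}

    u_idx = np.flatnonzero(u_mask)
    u_ids = ids[u_idx]
    u_order = np.argsort(u_ids, kind="stable")  # tie-break: smaller untreated id
    u_idx = u_idx[u_order]
    u_ids = u_ids[u_order]
    Wu = np.linalg.solve(L, Z[u_idx].T).T
    u_logit = logit[u_idx]
    available = np.ones(len(u_idx), dtype=bool)

    t_idx = np.flatnonzero(t_mask)
    order = np.lexsort((ids[t_idx], -logit[t_idx]))  # descending score, id tiebreak
    t_idx = t_idx[order]

    pairs = []
    for k, ti in enumerate(t_idx):
        ok = available & (np.abs(u_logit - logit[ti]) <= caliper)
        if exact is not None and ok.any():
            ok &= (exact[u_idx] == exact[ti]).all(axis=1)
        for c, (vals, wdt) in bands.items():
            if not ok.any():
                break
            ok &= np.abs(vals[u_idx] - vals[ti]) <= wdt
        if not ok.any():
            continue
        wt = np.linalg.solve(L, Z[ti])
        cand = np.flatnonzero(ok)
        dist = np.sqrt(((Wu[cand] - wt) ** 2).sum(axis=1))
        j = cand[int(np.argmin(dist))]  # u sorted by id, argmin returns first min
        available[j] = False
        pairs.append((ids[ti], u_ids[j], float(dist[int(np.argmin(dist))])))
    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "untreated_id", "distance"])
    pairs_df.insert(0, "pair_id", np.arange(len(pairs_df)))
    return MatchedCohort(
        outcome_label=model.outcome_label,
        pairs=pairs_df,
        caliper=caliper,
        exact_vars=tuple(exact_vars),
        band_vars=band_vars,
        n_unmatched_treated=nt - len(pairs_df),
    )


def balance(
    matched: MatchedCohort, baseline: pd.DataFrame, covariates
) -> pd.DataFrame:
    """Covariate balance across matched arms.

    Welch t-test for continuous covariates, uncorrected Pearson chi-square
    for binary ones; SMD = (mean_t - mean_u) / sqrt((var_t + var_u)/2).
    Zero variance in both arms yields p = 1 and SMD = 0.
    """
    if len(matched.pairs) < 2:
        raise MatchingError("balance requires at least two matched pairs")
    b = baseline.set_index("subject_id")
    xt = b.loc[matched.pairs["treated_id"]]
    xu = b.loc[matched.pairs["untreated_id"]]
    rows = []
    for c in covariates:
        a = xt[c].to_numpy(dtype=float)
        u = xu[c].to_numpy(dtype=float)
        mt, mu = a.mean(), u.mean()
        vt, vu = a.var(ddof=1), u.var(ddof=1)
        if vt == 0 and vu == 0:
            p, smd = (1.0, 0.0) if mt == mu else (0.0, np.inf)
        elif _is_binary(b[c]):
            table = np.array(
                [[a.sum(), len(a) - a.sum()], [u.sum(), len(u) - u.sum()]]
            )
            if (table.sum(axis=0) == 0).any():
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            smd = (mt - mu) / np.sqrt((vt + vu) / 2)
        else:
            _, p = stats.ttest_ind(a, u, equal_var=False)
            smd = (mt - mu) / np.sqrt((vt + vu) / 2)
        rows.append((c, mt, mu, float(p), float(smd)))
    return pd.DataFrame(
        rows, columns=["covariate", "treated_mean", "untreated_mean", "p_value", "smd"]
    )
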