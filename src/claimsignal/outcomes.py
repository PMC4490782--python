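"""Outcome-event detection and episode-of-care clustering.

Events are medical claims whose *primary* diagnosis falls in an outcome
group's code set.  Claims for one condition cluster tightly in time (the
index visit plus immediate follow-up), so the unit outcome is an *episode of
care*: a new episode starts only when an event is separated from the previous
event claim by at least ``episode_gap_days`` (default 28 days, i.e. a 4-week
claim-free gap).  The gap is measured in days between consecutive claim
dates — not on the discretized weekly grid — and from the previous claim, so
an episode extends indefinitely under sustained claims.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .claims_model import ClaimsBundle, CodeGroupMap, day_to_week

EVENT_COLUMNS = ["subject_id", "group_label", "service_day"]
EPISODE_COLUMNS = ["subject_id", "group_label", "start_day", "n_claims", "last_claim_day"]


def detect_events(
    bundle_or_medical, group: str, code_map: CodeGroupMap | None = None
) -> pd.DataFrame:
    """One event per medical claim whose primary_dx is in the group's codes.

    Same-day duplicate claims are kept (episode clustering absorbs them).
    Returns rows sorted by subject then day.
    """
    if isinstance(bundle_or_medical, ClaimsBundle):
        medical = bundle_or_medical.medical
        code_map = bundle_or_medical.code_map
    else:
        medical = bundle_or_medical
        if code_map is None:
            raise ValueError("code_map required when passing a medical frame")
    if group not in code_map.labels("outcome"):
        raise KeyError(
            f"{group!r} is not an outcome group; configured outcome groups: "
            f"{list(code_map.labels('outcome'))}"
        )
    hit = medical["primary_dx"].isin(code_map.codes(group))
    events = medical.loc[hit, ["subject_id", "service_day"]].copy()
    events.insert(1, "group_label", group)
    return events.sort_values(["subject_id", "service_day"], kind="mergesort").reset_index(
        drop=True
    )


def cluster_episodes(events: pd.DataFrame, episode_gap_days: int = 28) -> pd.DataFrame:
    """Cluster events into episodes of care per subject (and group).

    An event starts a new episode iff its day is at least
    ``episode_gap_days`` after the previous event claim of the same subject
    and group.  Handles multiple subjects/groups at once; episodes never
    bridge subjects.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    cols = ["subject_id", "service_day"]
    by = ["subject_id"]
    if "group_label" in events.columns:
        by = ["subject_id", "group_label"]
        cols = by + ["service_day"]
    df = events[cols].sort_values(cols, kind="mergesort").reset_index(drop=True)
    same = np.ones(len(df), dtype=bool)
    for c in by:
        same &= df[c].eq(df[c].shift()).to_numpy()
    gap = df["service_day"].diff().to_numpy()
    new_episode = ~same | (gap >= episode_gap_days)
    ep_id = np.cumsum(new_episode)
    out = df.groupby(ep_id).agg(
        subject_id=("subject_id", "first"),
        start_day=("service_day", "first"),
        n_claims=("service_day", "size"),
        last_claim_day=("service_day", "last"),
    )
    if "group_label" in events.columns:
        out.insert(1, "group_label", df.groupby(ep_id)["group_label"].first())
    else:
        out.insert(1, "group_label", "")
    return out.reset_index(drop=True)[EPISODE_COLUMNS]


def episode_starts_to_weeks(
    episodes: pd.DataFrame, anchor_day: int, n_weeks: int, week_days: int = 7
):
    """Per-week episode-start indicators on a subject's follow-up grid.

    Episodes starting before week 0 (baseline) or at/after ``n_weeks`` are
    dropped; the dropped count is returned so callers can log it.
    """
    indicators = np.zeros(n_weeks, dtype=np.int64)
    if len(episodes) == 0:
        return indicators, 0
    weeks = day_to_week(episodes["start_day"].to_numpy(), anchor_day, week_days)
    inside = (weeks >= 0) & (weeks < n_weeks)
    np.add.at(indicators, weeks[inside], 1)
    return indicators, int((~inside).sum())
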