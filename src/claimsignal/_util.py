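"""Internal vectorized helpers shared by the pipeline stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

# day offsets are < 2**20; keys pack (subject_code, day) into one int64
_DAY_SPAN = 1 << 21


def pack_keys(codes: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Pack (subject code, day) pairs into sortable int64 keys.

    Days may be negative down to -_DAY_SPAN/2; an offset keeps keys ordered.
    """
    return codes.astype(np.int64) * _DAY_SPAN + (np.asarray(days, dtype=np.int64) + _DAY_SPAN // 4)


def window_counts(
    sorted_keys: np.ndarray,
    codes: np.ndarray,
    lo_day: np.ndarray,
    hi_day: np.ndarray,
) -> np.ndarray:
    """Count events with day in [lo_day, hi_day] per query, given a sorted
    packed key array for one event stream."""
    lo = pack_keys(codes, np.asarray(lo_day))
    hi = pack_keys(codes, np.asarray(hi_day) + 1)
    return np.searchsorted(sorted_keys, hi) - np.searchsorted(sorted_keys, lo)


class SubjectIndex:
    """Stable subject-id <-> dense integer code mapping for one bundle."""

    def __init__(self, subject_ids: pd.Series | np.ndarray):
        ids = pd.Index(pd.unique(pd.Series(subject_ids))).sort_values()
        self.ids = np.asarray(ids)
        self._lookup = pd.Series(np.arange(len(ids)), index=ids)

    def __len__(self) -> int:
        return len(self.ids)

    def code(self, subject_ids) -> np.ndarray:
        return self._lookup.reindex(np.asarray(subject_ids)).to_numpy()


def enrollment_cumulative(
    enrollment: pd.DataFrame, index: SubjectIndex, n_months: int
) -> np.ndarray:
    """Cumulative enrolled-month counts: ``cum[s, m]`` = enrolled months < m.

    Months [m1, m2] are fully enrolled iff ``cum[s, m2+1] - cum[s, m1] ==
    m2 - m1 + 1``.  Spans beyond the study period are clipped.
    """
    M = np.zeros((len(index), n_months), dtype=bool)
    if len(enrollment):
        codes = index.code(enrollment["subject_id"])
        start = np.clip(enrollment["start_month"].to_numpy(), 0, n_months)
        end = np.clip(enrollment["end_month"].to_numpy() + 1, 0, n_months)
        keep = (end > start) & (codes >= 0)
        codes, start, end = codes[keep].astype(int), start[keep], end[keep]
        lengths = end - start
        subj = np.repeat(codes, lengths)
        month = np.concatenate([np.arange(s, e) for s, e in zip(start, end)]) if len(start) else np.array([], int)
        M[subj, month] = True
    cum = np.zeros((len(index), n_months + 1), dtype=np.int32)
    np.cumsum(M, axis=1, out=cum[:, 1:])
    return cum


def fully_enrolled(
    cum: np.ndarray, codes: np.ndarray, m1: np.ndarray, m2: np.ndarray
) -> np.ndarray:
    """Vectorized check that months m1..m2 (inclusive) are all enrolled."""
    n_months = cum.shape[1] - 1
    m1 = np.asarray(m1)
    m2 = np.asarray(m2)
    valid = (m1 >= 0) & (m2 < n_months) & (m2 >= m1)
    m1c = np.clip(m1, 0, n_months - 1)
    m2c = np.clip(m2, 0, n_months - 1)
    count = cum[codes, m2c + 1] - cum[codes, m1c]
    return valid & (count == (m2c - m1c + 1))


def last_enrolled_day(
    enrollment: pd.DataFrame, index: SubjectIndex, month_days: int, study_end_day: int
) -> np.ndarray:
    """Last day of each subject's final enrolled month, clipped to study end;
    subjects with no spans get -1."""
    out = np.full(len(index), -1, dtype=np.int64)
    if len(enrollment):
        last = enrollment.groupby("subject_id")["end_month"].max()
        codes = index.code(last.index)
        day = (last.to_numpy() + 1) * month_days - 1
        out[codes.astype(int)] = np.minimum(day, study_end_day)
    return out


def sorted_event_keys(index: SubjectIndex, subject_ids, days) -> np.ndarray:
    keys = pack_keys(index.code(subject_ids), np.asarray(days))
    return np.sort(keys)
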