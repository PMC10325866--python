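"""Behavioural activity quantification and its repeated-measures analysis.

Activity/inactivity is co-registered during acquisition as marker
intervals.  Per 10-min epoch the pipeline reports the time spent active,
inactive, and their ratio; handling/artifact/sleep-suspect intervals are
excluded from both sums.  Unmarked time counts as inactive (activity is
what gets flagged).

The treatment effect on inactivity is tested with the same mixed
repeated-measures ANOVA machinery as the qEEG metrics, but with the
baseline retained as a fourth within-subject level (behaviour is not
baseline-normalised).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import Recording
from . import stats as _stats

__all__ = ["ActivitySummary", "activity_ratio", "behavior_anova", "activity_share_table"]

_EXCLUDED = ("handling", "artifact", "sleep_suspect")


@dataclass(frozen=True)
class ActivitySummary:
    subject_id: str
    epoch: str
    active_s: float
    inactive_s: float

    @property
    def ratio(self) -> float:
        total = self.active_s + self.inactive_s
        return self.active_s / total if total > 0 else 0.0


def _union_length(intervals, window):
    """Total length of the union of intervals clipped to ``window``."""
    t0, t1 = window
    clipped = sorted(
        (max(a, t0), min(b, t1)) for a, b in intervals if min(b, t1) > max(a, t0)
    )
    total, cursor = 0.0, t0
    for a, b in clipped:
        a = max(a, cursor)
        if b > a:
            total += b - a
            cursor = b
    return total


def _union_intervals(intervals, window):
    t0, t1 = window
    clipped = sorted(
        (max(a, t0), min(b, t1)) for a, b in intervals if min(b, t1) > max(a, t0)
    )
    merged = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _subtract(intervals, cuts):
    """Set difference of interval unions (both already merged/sorted)."""
    out = []
    for a, b in intervals:
        pieces = [(a, b)]
        for c, d in cuts:
            nxt = []
            for p, q in pieces:
                if d <= p or c >= q:
                    nxt.append((p, q))
                    continue
                if c > p:
                    nxt.append((p, c))
                if d < q:
                    nxt.append((d, q))
            pieces = nxt
        out.extend(pieces)
    return out


def activity_ratio(markers, window, subject_id: str = "", epoch: str = "") -> ActivitySummary:
    """Active and inactive totals within an epoch window.

    Handling/artifact/sleep-suspect intervals are excluded from both
    sums; of the remaining time, marked-active seconds count as active
    and everything else as inactive.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("epoch window must have positive length")
    excluded = _union_intervals(
        [(m.start, m.end) for m in markers if m.label in _EXCLUDED], window
    )
    active_iv = _union_intervals(
        [(m.start, m.end) for m in markers if m.label == "active"], window
    )
    active_clean = _subtract(active_iv, excluded)
    active_s = sum(b - a for a, b in active_clean)
    excluded_s = _union_length(excluded, window)
    inactive_s = (t1 - t0) - excluded_s - active_s
    return ActivitySummary(subject_id, epoch, float(active_s), float(inactive_s))


def summarize_recording(recording: Recording, manifest, subject_id=None) -> pd.DataFrame:
    """ActivitySummary rows for every epoch of one recording."""
    if subject_id is None:
        subject_id = recording.subject_id
    rows = []
    for name, window in manifest.epoch_windows(recording.admin_time).items():
        s = activity_ratio(recording.markers, window, subject_id, name)
        rows.append({
            "subject": s.subject_id, "epoch": s.epoch,
            "active_s": s.active_s, "inactive_s": s.inactive_s, "ratio": s.ratio,
        })
    return pd.DataFrame(rows)


def behavior_anova(summaries: pd.DataFrame, groups: dict,
                   response: str = "inactive_s", epoch_order=None):
    """Mixed RM-ANOVA on per-epoch inactivity durations.

    ``groups`` maps subject id -> treatment group.  All epochs including
    the baseline enter as within-subject levels.
    """
    df = summaries.copy()
    df["group"] = df["subject"].map(groups)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "subject"].unique()
        raise ValueError(f"no treatment group for subjects: {list(missing)}")
    if epoch_order is None:
        epoch_order = list(dict.fromkeys(df["epoch"]))
    design = df.rename(columns={"epoch": "time", response: "value"})[
        ["subject", "group", "time", "value"]
    ]
    design["time"] = pd.Categorical(design["time"], categories=epoch_order, ordered=True)
    return _stats.rm_anova(design)


def activity_share_table(summaries: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Group x epoch mean active/inactive shares (pie-chart values; sum to 1)."""
    df = summaries.copy()
    df["group"] = df["subject"].map(groups)
    df["active_share"] = df["ratio"]
    df["inactive_share"] = 1.0 - df["ratio"]
    out = (
        df.groupby(["group", "epoch"], sort=True)[["active_share", "inactive_share"]]
        .mean()
        .reset_index()
    )
    return out
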