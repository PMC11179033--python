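"""Data-harmonization and exclusion rules for the raw study streams.

Three rules, applied in order and each fully logged:

1.  Onset harmonization — study day 1 is the first calendar day on which the
    participant responded to any cognitive or mood prompt; earlier
    passive-only days are removed and day indices rebased.
2.  Non-wear flagging — a day with fewer than 100 recorded steps, or with no
    heart-rate record, is flagged as non-wear and excluded from activity and
    heart-rate analyses (flagged, never deleted).
3.  Sparse-hour filtering — pooled across participants and days, clock-hour
    bins with fewer than 25 assessments are excluded per stream (d-prime and
    mood separately).

All exclusions are conservative: records are flagged or moved to a dropped
pile with counts reported, so records_in = records_kept + records_dropped
holds for every rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .nback import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CleaningReport:
    onset_dates: dict[str, date] = field(default_factory=dict)
    dropped_pre_onset: dict[str, int] = field(default_factory=dict)
    participants_excluded: list[str] = field(default_factory=list)
    nonwear_days: int = 0
    wear_days: int = 0
    sparse_hours: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "onset_dates": {k: str(v) for k, v in self.onset_dates.items()},
            "dropped_pre_onset": dict(self.dropped_pre_onset),
            "participants_excluded": list(self.participants_excluded),
            "nonwear_days": self.nonwear_days,
            "wear_days": self.wear_days,
            "sparse_hours": self.sparse_hours,
        }


def harmonize_onset(raw: StudyDataset, report: CleaningReport | None = None) -> StudyDataset:
    """Rebase each participant's day index to their first response day.

    The onset date is the earliest calendar date with any cognitive or mood
    response; earlier (passive-only) daily records are dropped, and a
    participant with no responses at all is excluded with a warning.
    """
    report = report if report is not None else CleaningReport()
    ds = raw.copy()
    first_resp: dict[str, date] = {}
    for stream, col in ((ds.sessions, "timestamp"), (ds.moods, "timestamp")):
        if len(stream) == 0:
            continue
        dates = pd.to_datetime(stream[col]).dt.date
        for pid, d in dates.groupby(stream["participant_id"]).min().items():
            if pid not in first_resp or d < first_resp[pid]:
                first_resp[pid] = d

    all_pids = set(ds.dailies["participant_id"]) | set(
        ds.sessions["participant_id"]
    ) | set(ds.moods["participant_id"])
    for pid in sorted(all_pids - set(first_resp)):
        logger.warning(
            "participant %s has passive data only and is excluded", pid
        )
        report.participants_excluded.append(pid)

    report.onset_dates = dict(first_resp)
    ds.onset_dates = dict(first_resp)

    def _rebase(df: pd.DataFrame, datecol: str) -> pd.DataFrame:
        if len(df) == 0:
            return df
        keep = df["participant_id"].isin(first_resp)
        df = df[keep].copy()
        onset = df["participant_id"].map(first_resp)
        d = pd.to_datetime(df[datecol]).dt.date
        df["day_index"] = (
            pd.to_datetime(d) - pd.to_datetime(onset)
        ).dt.days + 1
        return df

    ds.sessions = _rebase(ds.sessions, "timestamp")
    ds.moods = _rebase(ds.moods, "timestamp")
    dailies = _rebase(ds.dailies, "date")
    pre = dailies["day_index"] < 1
    for pid, n in dailies.loc[pre, "participant_id"].value_counts().items():
        report.dropped_pre_onset[pid] = int(n)
        logger.info("participant %s: dropped %d pre-onset passive day(s)", pid, n)
    ds.dailies = dailies[~pre].reset_index(drop=True)
    # assessment streams timestamped before onset are flagged, not dropped
    for stream in (ds.sessions, ds.moods):
        if len(stream):
            stream["excluded"] = stream["excluded"].astype(bool) | (
                stream["day_index"] < 1
            )
    ds.sessions = ds.sessions.reset_index(drop=True)
    ds.moods = ds.moods.reset_index(drop=True)
    return ds


def flag_nonwear(
    dailies: pd.DataFrame,
    step_threshold: int = 100,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Set the wear flag: non-wear iff steps < threshold or heart rate absent.

    A day with exactly ``step_threshold`` steps counts as worn (the rule is
    strictly "fewer than").  Records are retained with the flag so downstream
    stages can filter and report exact counts.
    """
    if (dailies["step_count"] < 0).any():
        bad = dailies.index[dailies["step_count"] < 0]
        raise ValidationError(f"negative step counts at rows {list(bad[:5])}")
    out = dailies.copy()
    out["wear"] = (
        (out["step_count"] >= step_threshold)
        & out["mean_heart_rate"].notna()
    )
    if report is not None:
        report.nonwear_days = int((~out["wear"]).sum())
        report.wear_days = int(out["wear"].sum())
    logger.info(
        "non-wear flagging: %d of %d days flagged",
        int((~out["wear"]).sum()), len(out),
    )
    return out


def filter_sparse_hours(
    records: pd.DataFrame,
    stream: str,
    min_per_hour: int = 25,
    report: CleaningReport | None = None,
) -> tuple[pd.DataFrame, int, list[int]]:
    """Drop clock-hour bins with fewer than ``min_per_hour`` pooled records.

    Bins are half-open clock-hour intervals [h:00, h+1:00); counts pool all
    participants and days.  Returns (kept records, dropped count, kept hours).
    """
    if stream not in ("dprime", "mood"):
        raise ValidationError(f"unknown stream {stream!r}")
    if len(records) == 0:
        raise ValidationError(f"empty {stream} stream")
    hours = np.floor(records["time_of_day"].to_numpy(dtype=float)).astype(int)
    counts = pd.Series(hours).value_counts()
    kept_hours = sorted(int(h) for h in counts.index[counts >= min_per_hour])
    keep = np.isin(hours, kept_hours)
    kept = records[keep].reset_index(drop=True)
    dropped = int((~keep).sum())
    if report is not None:
        report.sparse_hours[stream] = {
            "kept_hours": kept_hours,
            "dropped": dropped,
            "kept": int(keep.sum()),
            "counts_per_hour": {int(h): int(c) for h, c in counts.sort_index().items()},
        }
    logger.info(
        "%s sparse-hour filter: kept hours %s, dropped %d of %d records",
        stream, kept_hours, dropped, len(records),
    )
    return kept, dropped, kept_hours


def clean_dataset(
    raw: StudyDataset,
    step_threshold: int = 100,
    min_per_hour: int = 25,
) -> tuple[StudyDataset, CleaningReport]:
    """Apply the full cleaning sequence; returns (clean dataset, report)."""
    report = CleaningReport()
    ds = harmonize_onset(raw, report)
    ds.dailies = flag_nonwear(ds.dailies, step_threshold, report)
    if len(ds.sessions):
        active = ds.sessions[~ds.sessions["excluded"].astype(bool)]
        kept, _, _ = filter_sparse_hours(active, "dprime", min_per_hour, report)
        kept_keys = set(map(tuple, kept[["participant_id", "timestamp"]].itertuples(index=False)))
        mask = [
            (pid, ts) in kept_keys
            for pid, ts in ds.sessions[["participant_id", "timestamp"]].itertuples(index=False)
        ]
        ds.sessions["excluded"] = ds.sessions["excluded"].astype(bool) | ~np.asarray(mask)
    if len(ds.moods):
        active = ds.moods[~ds.moods["excluded"].astype(bool)]
        kept, _, _ = filter_sparse_hours(active, "mood", min_per_hour, report)
        kept_keys = set(map(tuple, kept[["participant_id", "timestamp"]].itertuples(index=False)))
        mask = [
            (pid, ts) in kept_keys
            for pid, ts in ds.moods[["participant_id", "timestamp"]].itertuples(index=False)
        ]
        ds.moods["excluded"] = ds.moods["excluded"].astype(bool) | ~np.asarray(mask)
    # renumber assessment indices over the retained sessions so X remains the
    # count of consecutive completed-and-included assessments
    if len(ds.sessions):
        ds.sessions["assessment_index"] = ds.sessions["assessment_index"].astype("float")
        ds.sessions.loc[ds.sessions["excluded"].astype(bool), "assessment_index"] = np.nan
        active = ~ds.sessions["excluded"].astype(bool)
        order = ds.sessions[active].sort_values(["participant_id", "timestamp"])
        ds.sessions.loc[order.index, "assessment_index"] = (
            order.groupby("participant_id").cumcount() + 1
        ).astype(float)
    return ds, report
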