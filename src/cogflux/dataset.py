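"""The harmonized study dataset: one container for all assessment streams.

Streams are long-format :class:`pandas.DataFrame` objects with fixed schemas:

``sessions``
    participant_id, timestamp, day_index, time_of_day, assessment_index,
    hits, false_alarms, n_targets, n_nontargets, d_prime, excluded
``trials`` (optional)
    participant_id, session_timestamp, trial_index, is_target, responded
``moods``
    participant_id, timestamp, day_index, time_of_day, item_interest,
    item_down, item_concentration, total, excluded
``dailies``
    participant_id, date, day_index, step_count, mean_heart_rate, wear

``onset_dates`` maps participant id to the calendar date of study day 1
(the first day with any cognitive or mood response).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .nback import DPRIME_MAX, DPRIME_MIN, ValidationError

SESSION_COLUMNS = [
    "participant_id", "timestamp", "day_index", "time_of_day",
    "assessment_index", "hits", "false_alarms", "n_targets", "n_nontargets",
    "d_prime", "excluded",
]
TRIAL_COLUMNS = [
    "participant_id", "session_timestamp", "trial_index", "is_target",
    "responded",
]
MOOD_COLUMNS = [
    "participant_id", "timestamp", "day_index", "time_of_day",
    "item_interest", "item_down", "item_concentration", "total", "excluded",
]
DAILY_COLUMNS = [
    "participant_id", "date", "day_index", "step_count", "mean_heart_rate",
    "wear",
]


@dataclass
class StudyDataset:
    sessions: pd.DataFrame
    moods: pd.DataFrame
    dailies: pd.DataFrame
    trials: pd.DataFrame | None = None
    onset_dates: dict[str, date] = field(default_factory=dict)

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            sessions=self.sessions.copy(),
            moods=self.moods.copy(),
            dailies=self.dailies.copy(),
            trials=None if self.trials is None else self.trials.copy(),
            onset_dates=dict(self.onset_dates),
        )

    def validate(self) -> None:
        """Schema and range checks; raises ValidationError naming offenders."""
        _require_columns(self.sessions, SESSION_COLUMNS, "sessions")
        _require_columns(self.moods, MOOD_COLUMNS, "moods")
        _require_columns(self.dailies, DAILY_COLUMNS, "dailies")
        if self.trials is not None:
            _require_columns(self.trials, TRIAL_COLUMNS, "trials")

        bad = self.sessions.index[
            (self.sessions["d_prime"] < DPRIME_MIN - 1e-9)
            | (self.sessions["d_prime"] > DPRIME_MAX + 1e-9)
        ]
        if len(bad):
            raise ValidationError(
                f"sessions rows {list(bad[:5])}: d_prime outside "
                f"[{DPRIME_MIN}, {DPRIME_MAX}]"
            )
        items = self.moods[["item_interest", "item_down", "item_concentration"]]
        bad = self.moods.index[((items < 1) | (items > 4)).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"moods rows {list(bad[:5])}: item scores outside the 4-point "
                "scale {1,2,3,4}"
            )
        bad = self.moods.index[self.moods["total"] != items.sum(axis=1)]
        if len(bad):
            raise ValidationError(
                f"moods rows {list(bad[:5])}: total does not equal the item sum"
            )
        bad = self.dailies.index[self.dailies["step_count"] < 0]
        if len(bad):
            raise ValidationError(
                f"dailies rows {list(bad[:5])}: negative step counts"
            )

    def counts(self) -> dict[str, int]:
        out = {
            "sessions": len(self.sessions),
            "moods": len(self.moods),
            "dailies": len(self.dailies),
        }
        if self.trials is not None:
            out["trials"] = len(self.trials)
        return out


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} stream is missing columns {missing}")
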