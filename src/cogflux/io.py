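"""CSV persistence for study datasets, with schema validation on read.

One long-format UTF-8 CSV per stream (sessions, trials, mood, daily) plus a
ground-truth table for simulated cohorts.  Timestamps are ISO-8601 and
timezone-naive local study time, since every diurnal rule is a clock-time
rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    DAILY_COLUMNS, MOOD_COLUMNS, SESSION_COLUMNS, TRIAL_COLUMNS, StudyDataset,
)
from .nback import DPRIME_MAX, DPRIME_MIN, ValidationError
from .simulate import GroundTruth

FILENAMES = {
    "sessions": "sessions.csv",
    "trials": "trials.csv",
    "moods": "mood.csv",
    "dailies": "daily.csv",
    "onsets": "onsets.csv",
    "truth": "ground_truth.csv",
}


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.sessions.to_csv(out / FILENAMES["sessions"], index=False)
    dataset.moods.to_csv(out / FILENAMES["moods"], index=False)
    dataset.dailies.to_csv(out / FILENAMES["dailies"], index=False)
    if dataset.trials is not None:
        dataset.trials.to_csv(out / FILENAMES["trials"], index=False)
    pd.DataFrame(
        {
            "participant_id": list(dataset.onset_dates),
            "onset_date": [str(d) for d in dataset.onset_dates.values()],
        }
    ).to_csv(out / FILENAMES["onsets"], index=False)


def _parse_timestamps(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], errors="coerce")
    bad = df.index[parsed.isna() & df[col].notna()]
    if len(bad):
        raise ValidationError(
            f"{name}: unparseable timestamps at rows {list(bad[:5])}"
        )
    return parsed


def read_dataset(in_dir: str | Path) -> StudyDataset:
    """Read a dataset directory; schema violations name their rows."""
    in_dir = Path(in_dir)
    sessions = pd.read_csv(in_dir / FILENAMES["sessions"])
    moods = pd.read_csv(in_dir / FILENAMES["moods"])
    dailies = pd.read_csv(in_dir / FILENAMES["dailies"])
    trials = None
    if (in_dir / FILENAMES["trials"]).exists():
        trials = pd.read_csv(in_dir / FILENAMES["trials"])
        trials["session_timestamp"] = _parse_timestamps(
            trials, "session_timestamp", "trials"
        )

    for df, cols, name in (
        (sessions, SESSION_COLUMNS, "sessions"),
        (moods, MOOD_COLUMNS, "moods"),
        (dailies, DAILY_COLUMNS, "dailies"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name}.csv is missing columns {missing}")

    sessions["timestamp"] = _parse_timestamps(sessions, "timestamp", "sessions")
    moods["timestamp"] = _parse_timestamps(moods, "timestamp", "moods")
    dailies["date"] = _parse_timestamps(dailies, "date", "dailies").dt.date

    bad = sessions.index[
        (sessions["d_prime"] < DPRIME_MIN - 1e-9)
        | (sessions["d_prime"] > DPRIME_MAX + 1e-9)
    ]
    if len(bad):
        raise ValidationError(
            f"sessions.csv rows {list(bad[:5])}: d_prime outside the "
            f"documented [{DPRIME_MIN}, {DPRIME_MAX}] bounds"
        )
    items = moods[["item_interest", "item_down", "item_concentration"]]
    bad = moods.index[((items < 1) | (items > 4)).any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"mood.csv rows {list(bad[:5])}: item scores outside the 4-point "
            "scale"
        )

    onsets = {}
    onset_path = in_dir / FILENAMES["onsets"]
    if onset_path.exists():
        odf = pd.read_csv(onset_path)
        onsets = {
            r.participant_id: pd.Timestamp(r.onset_date).date()
            for r in odf.itertuples()
        }
    ds = StudyDataset(
        sessions=sessions, moods=moods, dailies=dailies, trials=trials,
        onset_dates=onsets,
    )
    ds.validate()
    return ds


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.participants.to_csv(out / FILENAMES["truth"], index=False)
    with open(out / "ground_truth_globals.json", "w") as fh:
        json.dump(truth.coefficients, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)
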