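"""Harmonization and exclusion rules on hand-built fixtures."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from cogflux.cleaning import (
    CleaningReport, clean_dataset, filter_sparse_hours, flag_nonwear,
    harmonize_onset,
)
from cogflux.dataset import StudyDataset
from cogflux.nback import ValidationError


def _sessions(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp", "day_index", "time_of_day",
                 "assessment_index", "hits", "false_alarms", "n_targets",
                 "n_nontargets", "d_prime", "excluded"],
    )


def _moods(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp", "day_index", "time_of_day",
                 "item_interest", "item_down", "item_concentration", "total",
                 "excluded"],
    )


def _dailies(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "date", "day_index", "step_count",
                 "mean_heart_rate", "wear"],
    )


def session_row(pid, ts, tod=None):
    tod = ts.hour + ts.minute / 60 if tod is None else tod
    return [pid, ts, 0, tod, 0, 5, 2, 9, 21, 1.0, False]


def mood_row(pid, ts):
    return [pid, ts, 0, ts.hour + ts.minute / 60, 2, 2, 2, 6, False]


def daily_row(pid, d, steps=5000, hr=70.0, wear=True):
    return [pid, d, 0, steps, hr, wear]


@pytest.fixture
def onset_fixture():
    """A: first response on wear day 3 (2 passive lead-in days);
    B: responds on day 1; C: passive only."""
    d0 = date(2022, 3, 7)
    sessions = _sessions([
        session_row("A", datetime(2022, 3, 9, 9, 0)),
        session_row("A", datetime(2022, 3, 10, 9, 0)),
        session_row("B", datetime(2022, 3, 7, 10, 0)),
    ])
    moods = _moods([mood_row("B", datetime(2022, 3, 8, 14, 0))])
    dailies = _dailies(
        [daily_row("A", d0 + timedelta(days=i)) for i in range(5)]
        + [daily_row("B", d0 + timedelta(days=i)) for i in range(3)]
        + [daily_row("C", d0 + timedelta(days=i)) for i in range(4)]
    )
    return StudyDataset(sessions=sessions, moods=moods, dailies=dailies)


class TestHarmonizeOnset:
    def test_first_response_day_becomes_day_one(self, onset_fixture):
        report = CleaningReport()
        ds = harmonize_onset(onset_fixture, report)
        assert ds.onset_dates["A"] == date(2022, 3, 9)
        a = ds.sessions[ds.sessions["participant_id"] == "A"]
        assert a["day_index"].tolist() == [1, 2]

    def test_exact_count_of_dropped_passive_records(self, onset_fixture):
        report = CleaningReport()
        ds = harmonize_onset(onset_fixture, report)
        # A wore the device on 2022-03-07 and 03-08 without responding
        assert report.dropped_pre_onset == {"A": 2}
        a_days = ds.dailies[ds.dailies["participant_id"] == "A"]
        assert len(a_days) == 3

    def test_first_day_responder_keeps_all_records(self, onset_fixture):
        ds = harmonize_onset(onset_fixture, CleaningReport())
        b_days = ds.dailies[ds.dailies["participant_id"] == "B"]
        assert len(b_days) == 3
        assert b_days["day_index"].tolist() == [1, 2, 3]

    def test_passive_only_participant_excluded_with_warning(self, onset_fixture):
        report = CleaningReport()
        ds = harmonize_onset(onset_fixture, report)
        assert report.participants_excluded == ["C"]
        assert "C" not in set(ds.dailies["participant_id"])

    def test_idempotent(self, onset_fixture):
        once = harmonize_onset(onset_fixture, CleaningReport())
        twice = harmonize_onset(once, CleaningReport())
        pd.testing.assert_frame_equal(once.dailies, twice.dailies)
        pd.testing.assert_frame_equal(once.sessions, twice.sessions)


class TestFlagNonwear:
    def test_boundaries_and_missing_heart_rate(self):
        d = date(2022, 3, 7)
        dailies = _dailies([
            daily_row("A", d, steps=99, hr=70.0),
            daily_row("A", d, steps=100, hr=70.0),
            daily_row("A", d, steps=5000, hr=np.nan),
        ])
        out = flag_nonwear(dailies)
        assert out["wear"].tolist() == [False, True, False]

    def test_negative_steps_rejected(self):
        dailies = _dailies([daily_row("A", date(2022, 3, 7), steps=-1)])
        with pytest.raises(ValidationError):
            flag_nonwear(dailies)

    def test_records_flagged_not_deleted(self):
        dailies = _dailies([daily_row("A", date(2022, 3, 7), steps=10)])
        out = flag_nonwear(dailies)
        assert len(out) == 1

    def test_threshold_is_configurable(self):
        dailies = _dailies([daily_row("A", date(2022, 3, 7), steps=99)])
        assert flag_nonwear(dailies, step_threshold=50)["wear"].all()


def _hour_block(pid_prefix, hour, n, stream="dprime"):
    ts0 = datetime(2022, 3, 7, hour, 0)
    if stream == "dprime":
        return [session_row(f"{pid_prefix}{i}", ts0 + timedelta(minutes=i % 60))
                for i in range(n)]
    return [mood_row(f"{pid_prefix}{i}", ts0 + timedelta(minutes=i % 60))
            for i in range(n)]


class TestSparseHours:
    def test_bin_boundary_24_dropped_25_kept(self):
        records = _sessions(_hour_block("p", 9, 25) + _hour_block("q", 10, 24))
        kept, dropped, hours = filter_sparse_hours(records, "dprime")
        assert hours == [9]
        assert dropped == 24
        assert len(kept) == 25

    def test_single_big_bin_drops_nothing(self):
        records = _sessions(_hour_block("p", 9, 30))
        kept, dropped, hours = filter_sparse_hours(records, "dprime")
        assert dropped == 0 and hours == [9]

    def test_engineered_retention_windows(self):
        """d-prime survives 06:00-23:59 and mood only 12:00-17:59."""
        d_rows = []
        for h in range(6, 24):
            d_rows += _hour_block(f"d{h}", h, 25)
        d_rows += _hour_block("early", 5, 24)  # sparse early-morning bin
        sessions = _sessions(d_rows)
        kept, dropped, hours = filter_sparse_hours(sessions, "dprime")
        assert hours == list(range(6, 24))
        assert dropped == 24

        m_rows = []
        for h in range(12, 18):
            m_rows += _hour_block(f"m{h}", h, 25, stream="mood")
        m_rows += _hour_block("m11", 11, 24, stream="mood")
        m_rows += _hour_block("m18", 18, 20, stream="mood")
        moods = _moods(m_rows)
        kept_m, dropped_m, hours_m = filter_sparse_hours(moods, "mood")
        assert hours_m == list(range(12, 18))
        assert dropped_m == 44

    def test_conservation_and_idempotence(self):
        records = _sessions(_hour_block("p", 9, 25) + _hour_block("q", 10, 24))
        kept, dropped, _ = filter_sparse_hours(records, "dprime")
        assert len(kept) + dropped == len(records)
        again, dropped2, _ = filter_sparse_hours(kept, "dprime")
        assert dropped2 == 0
        pd.testing.assert_frame_equal(kept, again)

    def test_empty_stream_errors(self):
        with pytest.raises(ValidationError):
            filter_sparse_hours(_sessions([]), "dprime")

    def test_min_per_hour_is_configurable(self):
        records = _sessions(_hour_block("q", 10, 24))
        kept, dropped, hours = filter_sparse_hours(records, "dprime",
                                                   min_per_hour=10)
        assert dropped == 0 and hours == [10]


def test_nonwear_and_sparse_hours_commute(onset_fixture):
    ds = harmonize_onset(onset_fixture, CleaningReport())
    a = ds.copy()
    a.dailies = flag_nonwear(a.dailies)
    a_sessions, _, _ = filter_sparse_hours(a.sessions, "dprime", min_per_hour=1)
    b = ds.copy()
    b_sessions, _, _ = filter_sparse_hours(b.sessions, "dprime", min_per_hour=1)
    b.dailies = flag_nonwear(b.dailies)
    pd.testing.assert_frame_equal(a.dailies, b.dailies)
    pd.testing.assert_frame_equal(a_sessions, b_sessions)


def test_clean_dataset_reports_counts(default_cohort):
    ds, _ = default_cohort
    cleaned, report = clean_dataset(ds)
    counts = report.sparse_hours["dprime"]
    assert counts["kept"] + counts["dropped"] == (
        (~ds.sessions["excluded"].astype(bool)).sum()
    )
    # assessment indices renumbered over retained sessions only
    active = cleaned.sessions[~cleaned.sessions["excluded"].astype(bool)]
    for _, grp in active.groupby("participant_id"):
        idx = grp.sort_values("timestamp")["assessment_index"].to_numpy()
        assert (idx == np.arange(1, len(idx) + 1)).all()
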