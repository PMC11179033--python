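"""Scoring of 2-back sessions into the bounded d-prime outcome.

A session is a fixed-length block of trials in which each stimulus may or may
not match the stimulus shown two trials earlier ("target" trials).  Sensitivity
is summarized as d' = z(hit rate) - z(false-alarm rate), with the log-linear
extreme-rate correction (add 0.5 to each count and 1 to each denominator) so
that perfect or empty cells stay finite, and a final hard clamp to the
instrument's documented range of [-3.33, +3.33].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

#: Documented bounds of the d-prime score for this task implementation.
DPRIME_MIN = -3.33
DPRIME_MAX = 3.33


class ValidationError(ValueError):
    """Raised when input records violate a documented contract."""


@dataclass(frozen=True)
class TrialEvent:
    """One trial of a 2-back session.

    ``is_target`` is true iff the stimulus matches the one shown two trials
    earlier; trials 1 and 2 therefore can never be targets.  ``responded`` is
    the participant's binary response (tap / no tap).
    """

    participant_id: str
    session_timestamp: datetime
    trial_index: int  # 1-based, contiguous within a session
    is_target: bool
    responded: bool


@dataclass(frozen=True)
class SessionScore:
    """One scored n-back assessment."""

    participant_id: str
    session_timestamp: datetime
    hits: int
    false_alarms: int
    n_targets: int
    n_nontargets: int
    d_prime: float
    day_index: int | None = None  # 1-based study day, set by assign_time_fields
    time_of_day: float | None = None  # fractional clock hours in [0, 24)
    assessment_index: int | None = None  # 1-based completed-session counter
    excluded: bool = False  # e.g. timestamp precedes the participant's onset


def corrected_rates(
    hits: int, false_alarms: int, n_targets: int, n_nontargets: int
) -> tuple[float, float]:
    """Log-linear corrected hit and false-alarm rates.

    Adds 0.5 to each count and 1 to each denominator, which keeps both rates
    strictly inside (0, 1) for every possible session outcome.
    """
    if not (0 <= hits <= n_targets):
        raise ValidationError(f"hits={hits} outside [0, {n_targets}]")
    if not (0 <= false_alarms <= n_nontargets):
        raise ValidationError(f"false_alarms={false_alarms} outside [0, {n_nontargets}]")
    hit_rate = (hits + 0.5) / (n_targets + 1)
    fa_rate = (false_alarms + 0.5) / (n_nontargets + 1)
    return hit_rate, fa_rate


def d_prime_from_counts(
    hits: int, false_alarms: int, n_targets: int, n_nontargets: int
) -> float:
    """Bounded d' from raw counts: z(H) - z(F) on corrected rates, clamped."""
    hit_rate, fa_rate = corrected_rates(hits, false_alarms, n_targets, n_nontargets)
    d = float(norm.ppf(hit_rate) - norm.ppf(fa_rate))
    return float(np.clip(d, DPRIME_MIN, DPRIME_MAX))


def score_session(trials: Sequence[TrialEvent]) -> SessionScore:
    """Score one complete session of one participant into a :class:`SessionScore`.

    Raises :class:`ValidationError` for an empty session, non-contiguous or
    duplicate trial indices, targets within the first two trials, or trials
    spanning multiple participants/sessions.
    """
    if not trials:
        raise ValidationError("empty trial list")
    pids = {t.participant_id for t in trials}
    stamps = {t.session_timestamp for t in trials}
    if len(pids) != 1 or len(stamps) != 1:
        raise ValidationError("trials span more than one participant or session")
    indices = sorted(t.trial_index for t in trials)
    if indices != list(range(1, len(trials) + 1)):
        raise ValidationError("trial_index must be contiguous from 1 with no duplicates")
    for t in trials:
        if t.is_target and t.trial_index < 3:
            raise ValidationError(
                f"trial {t.trial_index} marked as 2-back target before trial 3"
            )
    n_targets = sum(t.is_target for t in trials)
    n_nontargets = len(trials) - n_targets
    hits = sum(t.is_target and t.responded for t in trials)
    false_alarms = sum((not t.is_target) and t.responded for t in trials)
    return SessionScore(
        participant_id=trials[0].participant_id,
        session_timestamp=trials[0].session_timestamp,
        hits=hits,
        false_alarms=false_alarms,
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        d_prime=d_prime_from_counts(hits, false_alarms, n_targets, n_nontargets),
    )


def time_of_day_hours(ts: datetime) -> float:
    """Fractional clock hours of a timestamp (14:30 -> 14.5)."""
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0


def assign_time_fields(
    scores: Iterable[SessionScore], onset_dates: Mapping[str, date]
) -> list[SessionScore]:
    """Populate day_index, time_of_day and assessment_index per participant.

    ``onset_dates`` maps participant id to the calendar date of study day 1.
    Sessions timestamped before onset are flagged ``excluded=True`` rather than
    dropped, and do not consume assessment indices.  Ties in timestamp are
    broken by input order, keeping indices distinct and deterministic.
    """
    scores = list(scores)
    order = sorted(
        range(len(scores)),
        key=lambda i: (scores[i].participant_id, scores[i].session_timestamp, i),
    )
    counters: dict[str, int] = {}
    out: list[SessionScore | None] = [None] * len(scores)
    for i in order:
        s = scores[i]
        if s.participant_id not in onset_dates:
            raise ValidationError(f"no onset date for participant {s.participant_id}")
        onset = onset_dates[s.participant_id]
        day_index = (s.session_timestamp.date() - onset).days + 1
        tod = time_of_day_hours(s.session_timestamp)
        if day_index < 1:
            out[i] = replace(
                s, day_index=day_index, time_of_day=tod, assessment_index=None,
                excluded=True,
            )
            continue
        counters[s.participant_id] = counters.get(s.participant_id, 0) + 1
        out[i] = replace(
            s,
            day_index=day_index,
            time_of_day=tod,
            assessment_index=counters[s.participant_id],
            excluded=False,
        )
    return [s for s in out if s is not None]
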