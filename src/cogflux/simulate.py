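"""Synthetic cohort generator for the high-frequency assessment pipeline.

The generator produces data with the statistical structure the downstream
analyses assume — practice effects following an inverse curve on d-prime,
quadratic time-of-day structure, weekday structure in activity and heart
rate, cross-domain coupling of daily fluctuations, AR(1) serial noise,
non-wear days and prompt nonresponse — together with a ground-truth ledger
of every latent parameter, so parameter-recovery and calibration tests have
a known target.

Two coupled representations of cognitive performance are emitted.  The
``sessions`` stream carries the latent d-prime directly (clamped to the
instrument bounds); this is the analysis-ready observable whose measurement
noise is exactly ``noise_sd_dprime``.  The ``trials`` stream realizes each
session as binary trial events whose response probabilities are calibrated
so that the *expected* scored d-prime equals the session's latent value;
scoring trials therefore adds binomial trial-sampling noise on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from functools import lru_cache
from math import sqrt
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom, norm

from .config import ConfigError, SimulationConfig
from .dataset import StudyDataset
from .nback import DPRIME_MAX, DPRIME_MIN, TrialEvent

#: Calendar date of study day 1 (a Monday, so weekday codes span 1..7
#: from the first week onward).
STUDY_START = date(2022, 1, 3)

#: Clock-hour centre used for the quadratic time-of-day effect.
DIURNAL_CENTER = 14.5

#: Centre used for the quadratic weekday effect (weekday coded 1=Mon..7=Sun).
WEEKDAY_CENTER = 4.0


@dataclass
class GroundTruth:
    """Latent parameters behind one generated cohort.

    ``participants`` has one row per participant: intercept, asymptote ``a``,
    slope ``b``, learner flag, mood baseline, mean steps and mean heart rate.
    ``coefficients`` collects the global coupling and trend coefficients,
    including the implied square-root-scale step-to-mood slope used when
    comparing against models that analyse steps on the square-root scale.
    """

    participants: pd.DataFrame
    coefficients: dict[str, Any]


# ---------------------------------------------------------------------------
# trial-level generation


def _score_matrix(n_targets: int, n_nontargets: int) -> np.ndarray:
    """Bounded d' for every (hits, false_alarms) outcome of the session."""
    h = np.arange(n_targets + 1)
    f = np.arange(n_nontargets + 1)
    zh = norm.ppf((h + 0.5) / (n_targets + 1))
    zf = norm.ppf((f + 0.5) / (n_nontargets + 1))
    return np.clip(zh[:, None] - zf[None, :], DPRIME_MIN, DPRIME_MAX)


def _probs_from_offset(c: float, n_targets: int, n_nontargets: int) -> tuple[float, float]:
    """Hit/false-alarm probabilities placing corrected rates at z = +/-c."""
    p_hit = ((n_targets + 1) * norm.cdf(c) - 0.5) / n_targets
    p_fa = ((n_nontargets + 1) * norm.cdf(-c) - 0.5) / n_nontargets
    return float(np.clip(p_hit, 0.0, 1.0)), float(np.clip(p_fa, 0.0, 1.0))


def _expected_score(
    p_hit: float, p_fa: float, n_targets: int, n_nontargets: int
) -> float:
    S = _score_matrix(n_targets, n_nontargets)
    wh = binom.pmf(np.arange(n_targets + 1), n_targets, p_hit)
    wf = binom.pmf(np.arange(n_nontargets + 1), n_nontargets, p_fa)
    return float(wh @ S @ wf)


@lru_cache(maxsize=100_000)
def calibrated_response_probs(
    latent_dprime: float, n_targets: int, n_nontargets: int
) -> tuple[float, float]:
    """Response probabilities whose *expected* scored d' equals the latent.

    Hit and false-alarm rates are placed symmetrically about the corrected-rate
    midpoint (z(H) = -z(F) = c) and the offset c is solved so that the exact
    expectation of the bounded score over the two binomials matches
    ``latent_dprime``.  Raises ConfigError outside the attainable range.
    """
    if not DPRIME_MIN <= latent_dprime <= DPRIME_MAX:
        raise ConfigError(
            f"latent d-prime {latent_dprime} outside the attainable range "
            f"[{DPRIME_MIN}, {DPRIME_MAX}]"
        )
    if latent_dprime >= DPRIME_MAX:
        return 1.0, 0.0
    if latent_dprime <= DPRIME_MIN:
        return 0.0, 1.0

    def g(c: float) -> float:
        ph, pf = _probs_from_offset(c, n_targets, n_nontargets)
        return _expected_score(ph, pf, n_targets, n_nontargets) - latent_dprime

    c = brentq(g, -6.0, 6.0, xtol=1e-10)
    return _probs_from_offset(c, n_targets, n_nontargets)


def _trial_arrays(
    latent_dprime: float, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(is_target, responded) arrays for one simulated session.

    Calibration is cached on a 0.01 grid of latent values; the grid rounding
    perturbs the expected score by well under 0.005.
    """
    if config.trials_per_session < 3:
        raise ConfigError("a 2-back session needs at least 3 trials")
    p_hit, p_fa = calibrated_response_probs(
        round(float(latent_dprime), 2), config.n_target_trials,
        config.trials_per_session - config.n_target_trials,
    )
    n = config.trials_per_session
    target_pos = rng.choice(
        np.arange(3, n + 1), size=config.n_target_trials, replace=False
    )
    is_target = np.zeros(n, dtype=bool)
    is_target[target_pos - 1] = True
    u = rng.random(n)
    responded = np.where(is_target, u < p_hit, u < p_fa)
    return is_target, responded


def generate_session_trials(
    latent_dprime: float,
    config: SimulationConfig,
    seed: int,
    participant_id: str = "sim",
    session_timestamp: datetime | None = None,
) -> list[TrialEvent]:
    """Realize one session as trial events around a latent d-prime.

    Emits ``trials_per_session`` trials with exactly ``n_target_trials``
    2-back matches (never in the first two trials); each target is responded
    to with the calibrated hit probability and each non-target with the
    calibrated false-alarm probability, so the expected scored d-prime
    equals the latent value.
    """
    rng = np.random.default_rng(seed)
    ts = session_timestamp or datetime.combine(STUDY_START, datetime.min.time())
    is_target, responded = _trial_arrays(latent_dprime, config, rng)
    n = config.trials_per_session
    return [
        TrialEvent(
            participant_id=participant_id,
            session_timestamp=ts,
            trial_index=i + 1,
            is_target=bool(is_target[i]),
            responded=bool(responded[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# cohort generation


def _ar1_innovate(prev: float, dt: float, phi: float, sd: float, z: float) -> float:
    """One step of a (continuous-time) AR(1) with stationary sd."""
    if prev is None or phi == 0.0:
        return sd * z
    rho = phi ** dt
    return rho * prev + sqrt(max(0.0, 1.0 - rho * rho)) * sd * z


def _split_total(total: int) -> tuple[int, int, int]:
    """Deterministic 3-item split of a mood total in [3, 12], items in 1..4."""
    base, rem = divmod(total, 3)
    items = [base + (1 if i < rem else 0) for i in range(3)]
    # keep every item inside the 4-point scale by shifting surplus
    for i in range(3):
        while items[i] > 4:
            items[i] -= 1
            j = min(range(3), key=lambda k: items[k])
            items[j] += 1
        while items[i] < 1:
            items[i] += 1
            j = max(range(3), key=lambda k: items[k])
            items[j] -= 1
    return items[0], items[1], items[2]


def weekday_code(d: date) -> int:
    """Weekday coded 1 (Monday) .. 7 (Sunday)."""
    return d.isoweekday()


def generate_cohort(
    config: SimulationConfig, include_trials: bool = True
) -> tuple[StudyDataset, GroundTruth]:
    """Generate one cohort plus its ground-truth parameter ledger.

    Fully reproducible from ``config`` (including ``config.seed``): the same
    configuration always yields byte-identical streams.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_nontargets = config.trials_per_session - config.n_target_trials

    # participant-level draws; asymptote and mean steps share a Gaussian
    # copula so a Spearman target can couple learning potential to activity
    rho = 2.0 * np.sin(np.pi * config.corr_asymptote_steps / 6.0)
    part_rows = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        z = rng.standard_normal(6)
        z_steps = rho * z[0] + sqrt(max(0.0, 1.0 - rho * rho)) * z[1]
        asym = max(0.05, config.asymptote_mean + config.asymptote_sd * z[0])
        mean_steps = max(500.0, config.step_mean + config.step_sd * z_steps)
        intercept = config.intercept_mean + config.intercept_sd * z[2]
        slope = max(0.0, config.slope_mean + config.slope_sd * z[3])
        learner = bool(rng.random() >= config.fraction_non_learners)
        if not learner:
            asym, slope = 0.0, 0.0
        baseline = float(
            np.clip(config.mood_baseline_mean + config.mood_baseline_sd * z[4], 3.0, 12.0)
        )
        mean_hr = max(40.0, config.hr_mean + config.hr_sd * z[5])
        part_rows.append(
            dict(
                participant_id=pid, intercept=intercept, asymptote=asym,
                slope=slope, learner=learner, mood_baseline=baseline,
                mean_steps=mean_steps, mean_hr=mean_hr,
            )
        )
    participants = pd.DataFrame(part_rows)

    session_rows: list[dict] = []
    trial_frames: list[tuple] = []
    mood_rows: list[dict] = []
    daily_rows: list[dict] = []
    c1, c2, c3 = config.dprime_day_poly

    for _, part in participants.iterrows():
        pid = part["participant_id"]

        # --- n-back sessions -------------------------------------------------
        k = 0
        e_prev: float | None = None
        t_prev = 0.0
        dp_noise_by_day: dict[int, list[float]] = {}
        for day in range(1, config.n_days + 1):
            day_date = STUDY_START + timedelta(days=day - 1)
            for slot in range(config.sessions_per_day):
                w0, w1 = config.session_windows[slot]
                tod = float(rng.uniform(w0, w1))
                u_miss = rng.random()
                z_noise = rng.standard_normal()
                if u_miss < config.p_session_missing:
                    continue
                k += 1
                t = (day - 1) + tod / 24.0
                e = _ar1_innovate(
                    e_prev, t - t_prev if e_prev is not None else 0.0,
                    config.ar_phi_dprime, config.noise_sd_dprime, z_noise,
                )
                e_prev, t_prev = e, t
                dp_noise_by_day.setdefault(day, []).append(e)
                practice = (
                    part["intercept"] + part["asymptote"] - part["slope"] / k
                    if part["learner"] else part["intercept"]
                )
                day0 = day - 1
                trend = c1 * day0 + c2 * day0 ** 2 + c3 * day0 ** 3
                h = tod - DIURNAL_CENTER
                diurnal = config.diurnal_linear * h + config.diurnal_quadratic * h * h
                latent = practice + trend + diurnal + e
                d_prime = float(np.clip(latent, DPRIME_MIN, DPRIME_MAX))
                minute = int(round((tod % 1.0) * 60))
                ts = datetime.combine(day_date, datetime.min.time()) + timedelta(
                    hours=int(tod), minutes=min(minute, 59)
                )
                p_hit, p_fa = _probs_from_offset(
                    d_prime / 2.0, config.n_target_trials, n_nontargets
                )
                session_rows.append(
                    dict(
                        participant_id=pid, timestamp=ts, day_index=day,
                        time_of_day=ts.hour + ts.minute / 60.0,
                        assessment_index=k,
                        hits=int(round(p_hit * config.n_target_trials)),
                        false_alarms=int(round(p_fa * n_nontargets)),
                        n_targets=config.n_target_trials,
                        n_nontargets=n_nontargets,
                        d_prime=d_prime, excluded=False,
                    )
                )
                if include_trials:
                    trial_seed = int(rng.integers(0, 2**31 - 1))
                    is_target, responded = _trial_arrays(
                        d_prime, config, np.random.default_rng(trial_seed)
                    )
                    trial_frames.append((pid, ts, is_target, responded))

        # --- daily steps and heart rate -------------------------------------
        step_fluct: dict[int, float] = {}
        eta_prev: float | None = None
        ehr_prev: float | None = None
        sqrt_base = sqrt(part["mean_steps"])
        for day in range(1, config.n_days + 1):
            day_date = STUDY_START + timedelta(days=day - 1)
            w = weekday_code(day_date) - WEEKDAY_CENTER
            eta = _ar1_innovate(
                eta_prev, 1.0, config.ar_phi_steps, config.noise_sd_steps,
                float(rng.standard_normal()),
            )
            eta_prev = eta
            det_sqrt = (
                sqrt_base
                + config.step_weekday_linear * w
                + config.step_weekday_quadratic * w * w
            )
            steps_true = max(0.0, det_sqrt + eta) ** 2
            step_fluct[day] = steps_true - max(0.0, det_sqrt) ** 2
            ehr = _ar1_innovate(
                ehr_prev, 1.0, config.ar_phi_hr, config.noise_sd_hr,
                float(rng.standard_normal()),
            )
            ehr_prev = ehr
            hr = float(
                np.exp(
                    np.log(part["mean_hr"])
                    + config.hr_weekday_linear * w
                    + config.hr_weekday_quadratic * w * w
                    + ehr
                )
            )
            nonwear = rng.random() < config.p_nonwear_day
            if nonwear:
                step_count = int(rng.integers(0, 100))
                hr_rec = np.nan
            else:
                step_count = int(round(steps_true))
                hr_rec = round(hr, 1)
            daily_rows.append(
                dict(
                    participant_id=pid, date=day_date, day_index=day,
                    step_count=step_count, mean_heart_rate=hr_rec,
                    wear=not nonwear,
                )
            )

        # --- mood ------------------------------------------------------------
        em_prev: float | None = None
        day_prev = 0
        for day in range(1, config.n_days + 1):
            day_date = STUDY_START + timedelta(days=day - 1)
            u_a, u_e = rng.random(), rng.random()
            tod_a = float(rng.uniform(*config.mood_afternoon_window))
            tod_e = float(rng.uniform(*config.mood_evening_window))
            z_noise = float(rng.standard_normal())
            if u_a >= config.p_mood_missing:
                tod = tod_a
            elif u_e >= config.p_mood_missing:
                # evening prompt only delivered because the afternoon one
                # went unanswered
                tod = tod_e
            else:
                continue
            em = _ar1_innovate(
                em_prev, float(day - day_prev) if em_prev is not None else 0.0,
                config.ar_phi_mood, config.noise_sd_mood, z_noise,
            )
            em_prev, day_prev = em, day
            dp_today = dp_noise_by_day.get(day, [])
            latent = (
                part["mood_baseline"]
                + config.mood_day_trend * (day - 1)
                + config.coupling_step_mood_same_day * step_fluct.get(day, 0.0)
                + config.coupling_step_mood_lag1 * step_fluct.get(day - 1, 0.0)
                + config.coupling_dprime_mood
                * (float(np.mean(dp_today)) if dp_today else 0.0)
                + em
            )
            total = int(round(float(np.clip(latent, 3.0, 12.0))))
            i1, i2, i3 = _split_total(total)
            minute = int(round((tod % 1.0) * 60))
            ts = datetime.combine(day_date, datetime.min.time()) + timedelta(
                hours=int(tod), minutes=min(minute, 59)
            )
            mood_rows.append(
                dict(
                    participant_id=pid, timestamp=ts, day_index=day,
                    time_of_day=ts.hour + ts.minute / 60.0,
                    item_interest=i1, item_down=i2, item_concentration=i3,
                    total=total, excluded=False,
                )
            )

    sessions = pd.DataFrame(session_rows)
    moods = pd.DataFrame(mood_rows)
    dailies = pd.DataFrame(daily_rows)
    trials = None
    if trial_frames:
        n = config.trials_per_session
        trials = pd.DataFrame(
            dict(
                participant_id=np.repeat([f[0] for f in trial_frames], n),
                session_timestamp=np.repeat(
                    pd.to_datetime([f[1] for f in trial_frames]), n
                ),
                trial_index=np.tile(np.arange(1, n + 1), len(trial_frames)),
                is_target=np.concatenate([f[2] for f in trial_frames]),
                responded=np.concatenate([f[3] for f in trial_frames]),
            )
        )
    onsets = {
        pid: STUDY_START for pid in participants["participant_id"]
    }
    dataset = StudyDataset(
        sessions=sessions, moods=moods, dailies=dailies, trials=trials,
        onset_dates=onsets,
    )
    truth = GroundTruth(
        participants=participants,
        coefficients=dict(
            coupling_step_mood_same_day=config.coupling_step_mood_same_day,
            coupling_step_mood_lag1=config.coupling_step_mood_lag1,
            coupling_dprime_mood=config.coupling_dprime_mood,
            # delta-method slope of mood on sqrt-scale step residuals
            coupling_sqrtstep_mood_same_day=(
                config.coupling_step_mood_same_day * 2.0 * sqrt(config.step_mean)
            ),
            coupling_sqrtstep_mood_lag1=(
                config.coupling_step_mood_lag1 * 2.0 * sqrt(config.step_mean)
            ),
            mood_day_trend=config.mood_day_trend,
            dprime_day_poly=tuple(config.dprime_day_poly),
            diurnal_linear=config.diurnal_linear,
            diurnal_quadratic=config.diurnal_quadratic,
            step_weekday_linear=config.step_weekday_linear,
            step_weekday_quadratic=config.step_weekday_quadratic,
            hr_weekday_linear=config.hr_weekday_linear,
            hr_weekday_quadratic=config.hr_weekday_quadratic,
        ),
    )
    return dataset, truth
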