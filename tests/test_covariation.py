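"""Residual construction and concurrent/lagged covariation models."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from cogflux.config import SimulationConfig
from cogflux.covariation import (
    build_residuals, concurrent_covariation, exclude_learning_period,
    lagged_covariation, restrict_complete_days,
)
from cogflux.nback import ValidationError
from cogflux.simulate import generate_cohort

from oracle_helpers import (
    SAME_DAY_ONLY, observable_step_mood_slope, residualize_flat,
)


def _fake_fit(pids, days, resid):
    data = pd.DataFrame({"participant_id": pids, "day_index": days})
    return SimpleNamespace(data=data, lmm=SimpleNamespace(resid=np.asarray(resid)))


def _residual_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "day_index", "mood", "dprime",
                       "steps", "heart_rate", "n_nback_today"],
    )


class TestBuildResiduals:
    def test_dprime_residuals_average_within_day(self):
        fits = {
            "dprime": _fake_fit(
                ["A"] * 3, [1, 1, 1], [0.2, -0.1, 0.2]
            ),
            "mood": _fake_fit(["A"], [1], [0.4]),
        }
        out = build_residuals(fits)
        assert out.loc[0, "dprime"] == pytest.approx(0.1)
        assert out.loc[0, "n_nback_today"] == 3

    def test_zero_noise_flat_cohort_gives_zero_residuals(self):
        cfg = SimulationConfig(
            n_participants=4, n_days=12, seed=6, fraction_non_learners=1.0,
            noise_sd_dprime=0.0, noise_sd_mood=0.0, noise_sd_steps=0.0,
            noise_sd_hr=0.0, diurnal_linear=0.0, diurnal_quadratic=0.0,
            mood_day_trend=0.0, step_weekday_linear=0.0,
            step_weekday_quadratic=0.0, hr_weekday_linear=0.0,
            hr_weekday_quadratic=0.0, coupling_step_mood_same_day=0.0,
            coupling_step_mood_lag1=0.0, coupling_dprime_mood=0.0,
            p_nonwear_day=0.0,
        )
        ds, _ = generate_cohort(cfg, include_trials=False)
        r = residualize_flat(ds)
        assert np.nanmax(np.abs(r["dprime"].to_numpy())) < 1e-6
        # steps are recorded as integer counts and heart rate to 0.1 bpm, so
        # their transformed-scale residuals are bounded by the recording
        # grain; mood totals are discretized to integers
        assert np.nanmax(np.abs(r["steps"].to_numpy())) < 0.02
        assert np.nanmax(np.abs(r["heart_rate"].to_numpy())) < 0.01
        assert np.nanmax(np.abs(r["mood"].to_numpy())) <= 0.5 + 1e-9

    def test_participant_residual_means_near_zero(self):
        from oracle_helpers import NULL_STRUCTURE

        ds, _ = generate_cohort(
            SimulationConfig(seed=77, **NULL_STRUCTURE), include_trials=False
        )
        r = residualize_flat(ds)
        means = r.groupby("participant_id")["steps"].mean().abs()
        assert means.max() < 0.3

    def test_missing_fit_rejected(self):
        with pytest.raises(ValidationError):
            build_residuals({"dprime": None})


class TestConcurrentModel:
    def test_response_regressed_on_itself_gives_unit_slope(self, default_cohort):
        ds, _ = default_cohort
        r = residualize_flat(ds)
        r = r.assign(mood_copy=r["mood"])
        res = concurrent_covariation(r, predictors=("mood_copy",))
        assert res.coefficient("mood_copy")["estimate"] == pytest.approx(
            1.0, abs=1e-6
        )

    def test_degenerate_predictor_dropped_with_remaining_kept(self, default_cohort):
        ds, _ = default_cohort
        r = residualize_flat(ds).assign(flat=0.0)
        res = concurrent_covariation(r, predictors=("steps", "flat"))
        assert res.predictors == ["steps"]

    def test_needs_multiple_participants(self):
        rows = [["A", d, 0.1, 0.1, 0.1, 0.1, 3] for d in range(1, 10)]
        with pytest.raises(ValidationError):
            concurrent_covariation(_residual_frame(rows))

    def test_coupling_recovered_within_confidence_interval(self):
        """Same-day step->mood coupling: negative sign, and the CI covers the
        Monte-Carlo observable-scale estimand."""
        cfg0 = SimulationConfig(**SAME_DAY_ONLY)
        truth = observable_step_mood_slope(cfg0)  # per sqrt-step unit
        hits = signs = 0
        n_rep = 30
        for i in range(n_rep):
            ds, _ = generate_cohort(
                SimulationConfig(seed=6000 + i, **SAME_DAY_ONLY),
                include_trials=False,
            )
            res = concurrent_covariation(residualize_flat(ds))
            row = res.coefficient("steps")
            signs += row["estimate"] < 0
            hits += abs(row["estimate"] - truth) < 1.96 * row["se"]
        assert signs == n_rep
        assert hits >= 0.85 * n_rep


class TestLaggedModel:
    def test_pairs_require_consecutive_days(self):
        rows = (
            [["A", d, 0.1 * d, np.nan, 0.2, np.nan, 3] for d in (1, 2, 3, 5)]
            + [["B", 1, 0.5, np.nan, 0.1, np.nan, 3]]  # single day: no pairs
            + [["C", d, -0.1 * d, np.nan, 0.3, np.nan, 3] for d in range(1, 10)]
        )
        frame = _residual_frame(rows)
        res = lagged_covariation(frame, "steps", "prev_day")
        # A: days (1,2),(2,3),(4,5)->(5 has no day 4) => 2 pairs; B: 0; C: 8
        assert res.n_obs == 10

    def test_too_few_pairs_rejected(self):
        rows = [["A", d, 0.1, np.nan, 0.2, np.nan, 3] for d in (1, 2)]
        with pytest.raises(ValidationError):
            lagged_covariation(_residual_frame(rows), "steps", "prev_day")

    def test_unknown_direction_rejected(self, default_cohort):
        ds, _ = default_cohort
        r = residualize_flat(ds)
        with pytest.raises(ValidationError):
            lagged_covariation(r, "steps", "tomorrow")


class TestExclusions:
    def _frame(self):
        rows = []
        for pid, days in (("L", range(1, 21)), ("N", range(1, 16))):
            rows += [[pid, d, 0.0, 0.0, 0.0, 0.0, 3] for d in days]
        return _residual_frame(rows)

    def _curves(self):
        return pd.DataFrame([
            {"participant_id": "L", "fit_adequate": True, "learning_day_90": 10},
            {"participant_id": "N", "fit_adequate": False,
             "learning_day_90": np.nan},
        ])

    def test_learner_loses_days_before_plateau_day(self):
        out = exclude_learning_period(self._frame(), self._curves())
        learner_days = out.loc[out["participant_id"] == "L", "day_index"]
        assert learner_days.min() == 10  # days 1-9 removed, boundary kept
        assert len(learner_days) == 11

    def test_non_learner_keeps_all_data(self):
        out = exclude_learning_period(self._frame(), self._curves())
        assert (out["participant_id"] == "N").sum() == 15

    def test_exclusion_never_adds_observations(self):
        frame = self._frame()
        out = exclude_learning_period(frame, self._curves())
        assert len(out) <= len(frame)
        again = restrict_complete_days(out)
        assert len(again) <= len(out)

    def test_complete_day_restriction_boundaries(self):
        rows = [["A", 1, 0.1, 0.0, 0.0, 0.0, 2],
                ["A", 2, 0.1, 0.0, 0.0, 0.0, 3]]
        out = restrict_complete_days(_residual_frame(rows))
        assert out["day_index"].tolist() == [2]

    def test_no_missing_sessions_makes_restriction_a_noop(self):
        cfg = SimulationConfig(n_participants=3, n_days=8, seed=2,
                               p_session_missing=0.0)
        ds, _ = generate_cohort(cfg, include_trials=False)
        r = residualize_flat(ds)
        assert len(restrict_complete_days(r)) == len(r)

    def test_retained_fraction_matches_binomial_rate(self):
        cfg = SimulationConfig(seed=8, p_session_missing=0.2)
        ds, _ = generate_cohort(cfg, include_trials=False)
        r = residualize_flat(ds)
        kept = len(restrict_complete_days(r))
        total_days = cfg.n_participants * cfg.n_days
        frac = kept / total_days
        assert abs(frac - 0.8 ** 3) < 0.07
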