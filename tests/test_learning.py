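"""Learning-curve smoothing, inverse fits, rates and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogflux.config import SimulationConfig
from cogflux.learning import (
    LearningCurve, baseline_adjust, characterize_cohort,
    correlate_learning_params, fit_inverse_curve, learning_rate_90, map_to_day,
    smooth,
)
from cogflux.nback import ValidationError
from cogflux.simulate import generate_cohort
from cogflux.trends import extract_intercepts, select_trend


def _adjusted(Y, X=None, days=None):
    X = np.arange(1, len(Y) + 1, dtype=float) if X is None else X
    days = np.ceil(np.asarray(X) / 3).astype(int) if days is None else days
    return pd.DataFrame({"X": X, "Y": Y, "day_index": days})


class TestSmooth:
    def test_partial_then_full_trailing_windows(self):
        assert smooth(np.array([1.0, 2, 3, 4])) == pytest.approx([1, 1.5, 2, 3])

    def test_constant_series_unchanged(self):
        x = np.full(10, 2.5)
        assert smooth(x) == pytest.approx(x)

    def test_linear_ramp_keeps_slope_in_full_window_region(self):
        # trailing average of an arithmetic sequence lags by (w-1)/2 steps but
        # keeps the slope: differences equal the ramp's increment from index w
        y = 0.7 * np.arange(20.0)
        s = smooth(y, window=3)
        assert np.diff(s)[2:] == pytest.approx(0.7)

    def test_empty_series_errors(self):
        with pytest.raises(ValidationError):
            smooth(np.array([]))


class TestBaselineAdjust:
    def test_subtraction(self):
        scores = pd.DataFrame({
            "assessment_index": [1, 2], "d_prime": [1.5, 2.0],
            "day_index": [1, 1],
        })
        adj = baseline_adjust(scores, 0.5)
        assert adj["Y"].tolist() == [1.0, 1.5]

    def test_zero_starting_point_is_identity(self):
        scores = pd.DataFrame({
            "assessment_index": [1, 2], "d_prime": [1.5, 2.0],
            "day_index": [1, 1],
        })
        adj = baseline_adjust(scores, 0.0)
        assert adj["Y"].tolist() == [1.5, 2.0]


class TestInverseCurveFit:
    def test_noiseless_recovery(self):
        X = np.arange(1, 31, dtype=float)
        curve = fit_inverse_curve(_adjusted(2 - 4 / X), presmoothed=True)
        assert curve.asymptote_a == pytest.approx(2.0, abs=1e-6)
        assert curve.slope_b == pytest.approx(4.0, abs=1e-6)
        assert curve.fit_adequate

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(0.3, 3.0), b=st.floats(0.3, 5.0))
    def test_exact_recovery_property(self, a, b):
        X = np.arange(1, 40, dtype=float)
        curve = fit_inverse_curve(_adjusted(a - b / X), presmoothed=True)
        assert curve.asymptote_a == pytest.approx(a, abs=1e-6)
        assert curve.slope_b == pytest.approx(b, abs=1e-6)

    def test_flat_series_is_a_non_learner(self):
        curve = fit_inverse_curve(_adjusted(np.ones(30)), presmoothed=True)
        assert not curve.fit_adequate
        assert abs(curve.slope_b) < 1e-6 or np.isnan(curve.slope_b)

    def test_noisy_flat_series_slope_nonsignificant(self):
        rng = np.random.default_rng(0)
        curve = fit_inverse_curve(
            _adjusted(1.0 + rng.normal(0, 0.3, 60)), presmoothed=True
        )
        assert not curve.fit_adequate

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            fit_inverse_curve(_adjusted(np.ones(4)))


class TestLearningRate:
    def _curve(self, a, b):
        return LearningCurve(
            participant_id="P", starting_point=0.0, asymptote_a=a, slope_b=b,
            se_a=0.1, se_b=0.1, t_a=10, t_b=10, p_a=0.001, p_b=0.001,
            fit_adequate=True, n_points=30,
        )

    def test_printed_formula(self):
        assert learning_rate_90(self._curve(2.0, 4.0)) == pytest.approx(20.0)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 10.0))
    def test_curve_value_at_rate_is_ninety_percent_of_asymptote(self, a, b):
        rate = learning_rate_90(self._curve(a, b))
        assert a - b / rate == pytest.approx(0.9 * a, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 10.0),
           c=st.floats(0.2, 5.0))
    def test_scale_property(self, a, b, c):
        base = learning_rate_90(self._curve(a, b))
        assert learning_rate_90(self._curve(a, c * b)) == pytest.approx(c * base)
        assert learning_rate_90(self._curve(c * a, b)) == pytest.approx(base / c)

    def test_non_learner_rate_undefined(self):
        curve = self._curve(2.0, 4.0)
        curve.fit_adequate = False
        with pytest.raises(ValidationError):
            learning_rate_90(curve)

    def test_map_to_day_with_three_daily_assessments(self):
        scores = pd.DataFrame({
            "assessment_index": np.arange(1, 31),
            "day_index": np.repeat(np.arange(1, 11), 3),
            "d_prime": 1.0,
        })
        assert map_to_day(20.0, scores) == 7  # 18 by day 6, 21 >= 20 on day 7


class TestCohortCharacterization:
    def test_fitted_curve_at_rate_matches_for_every_adequate_fit(self, default_cohort):
        ds, _ = default_cohort
        sp = extract_intercepts(select_trend(ds, "dprime").selected)
        curves = characterize_cohort(ds.sessions, sp)
        ok = curves[curves["fit_adequate"] & curves["learning_rate_90"].notna()]
        assert len(ok) >= 20
        value = ok["asymptote_a"] - ok["slope_b"] / ok["learning_rate_90"]
        assert value.to_numpy() == pytest.approx(
            (0.9 * ok["asymptote_a"]).to_numpy(), abs=1e-9
        )
        assert ok["stable_max"].to_numpy() == pytest.approx(
            (ok["asymptote_a"] + ok["starting_point"]).to_numpy()
        )

    def test_noiseless_non_learner_mean_adjusted_is_zero(self):
        cfg = SimulationConfig(
            n_participants=2, n_days=10, seed=1, fraction_non_learners=1.0,
            intercept_mean=1.0, intercept_sd=0.0, noise_sd_dprime=0.0,
            diurnal_linear=0.0, diurnal_quadratic=0.0, p_session_missing=0.0,
        )
        ds, _ = generate_cohort(cfg, include_trials=False)
        grp = ds.sessions[ds.sessions["participant_id"] == "P01"]
        adj = baseline_adjust(grp, 1.0)
        assert adj["Y"].mean() == pytest.approx(0.0, abs=1e-12)


class TestParamCorrelations:
    def _curves(self, values):
        n = len(values)
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "asymptote_a": values, "slope_b": np.asarray(values) * 2,
            "fit_adequate": True,
        })

    def test_identical_vectors_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1, 0.3, 12)
        curves = self._curves(vals)
        summaries = pd.DataFrame(
            {"mean_steps": vals}, index=[f"P{i}" for i in range(12)]
        )
        out = correlate_learning_params(curves, summaries)
        row = out[(out["parameter"] == "asymptote_a")].iloc[0]
        assert row["estimate"] == pytest.approx(1.0)

    def test_too_few_participants_rejected(self):
        curves = self._curves([1.0, 1.1, 0.9])
        summaries = pd.DataFrame(
            {"mean_steps": [1, 2, 3]}, index=["P0", "P1", "P2"]
        )
        with pytest.raises(ValidationError):
            correlate_learning_params(curves, summaries)

    def test_skewed_summary_falls_back_to_spearman(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(1, 0.3, 15)
        curves = self._curves(vals)
        summaries = pd.DataFrame(
            {"steps": np.exp(rng.normal(8, 2, 15) ** 2 / 10)},
            index=[f"P{i}" for i in range(15)],
        )
        out = correlate_learning_params(curves, summaries)
        assert (out["method"] == "spearman").any()

    def test_configured_rank_coupling_recovered(self):
        """Asymptotes coupled to mean steps at Spearman 0.5 in the generator
        are recovered within the bootstrap interval in most replicates."""
        hits = 0
        n_rep = 8
        for i in range(n_rep):
            cfg = SimulationConfig(seed=5000 + i, corr_asymptote_steps=0.5)
            ds, truth = generate_cohort(cfg, include_trials=False)
            # adjust at the true baselines so the check isolates the coupling
            sp = truth.participants.set_index("participant_id")["intercept"]
            curves = characterize_cohort(ds.sessions, sp)
            steps = (
                ds.dailies[ds.dailies["wear"]]
                .groupby("participant_id")["step_count"].mean()
                .rename("mean_steps").to_frame()
            )
            out = correlate_learning_params(curves, steps, seed=i)
            row = out[out["parameter"] == "asymptote_a"].iloc[0]
            hits += row["ci_low"] <= 0.5 <= row["ci_high"]
        assert hits >= 5
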