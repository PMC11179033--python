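"""Shared experiment configurations and independent oracles for the tests.

Everything here is deliberately independent of the code paths under test:
the d-prime oracle uses the standard library's Gaussian quantile, and the
observable-coupling oracle re-derives the mood-on-steps slope by direct
Monte Carlo over the generative description.
"""

from __future__ import annotations

from statistics import NormalDist

import numpy as np

from cogflux.config import SimulationConfig
from cogflux.covariation import build_residuals
from cogflux.trends import (
    COVARIANCE_BY_OUTCOME, DEFAULT_TRANSFORMS, TrendModelSpec, fit_trend,
)

#: flat-trajectory cohort with no periodic structure or couplings: the null
#: condition for selection type-I and covariation calibration studies
NULL_STRUCTURE = dict(
    coupling_step_mood_same_day=0.0,
    coupling_step_mood_lag1=0.0,
    coupling_dprime_mood=0.0,
    fraction_non_learners=1.0,
    diurnal_linear=0.0,
    diurnal_quadratic=0.0,
    mood_day_trend=0.0,
    step_weekday_linear=0.0,
    step_weekday_quadratic=0.0,
    hr_weekday_linear=0.0,
    hr_weekday_quadratic=0.0,
    ar_phi_steps=0.0,
)

#: explicit cubic day trend replacing the practice curve, used by the
#: trend-recovery and degree-selection power studies
CUBIC_TREND = dict(NULL_STRUCTURE, dprime_day_poly=(0.08, -0.003, 3.5e-5))

#: directionality condition: both step->mood couplings at their defaults on a
#: flat background with serially uncorrelated step fluctuations, so the
#: adjusted reverse-lag model has no genuine signal
DIRECTIONAL = dict(
    fraction_non_learners=1.0,
    diurnal_linear=0.0,
    diurnal_quadratic=0.0,
    mood_day_trend=0.0,
    step_weekday_linear=0.0,
    step_weekday_quadratic=0.0,
    hr_weekday_linear=0.0,
    hr_weekday_quadratic=0.0,
    ar_phi_steps=0.0,
)

#: same-day-coupling-only condition for coefficient-recovery checks
SAME_DAY_ONLY = dict(DIRECTIONAL, coupling_step_mood_lag1=0.0,
                     coupling_dprime_mood=0.0)


def dprime_oracle(hits, false_alarms, n_targets, n_nontargets,
                  lo=-3.33, hi=3.33):
    """Independent bounded d' via the standard library's Gaussian quantile."""
    z = NormalDist().inv_cdf
    d = z((hits + 0.5) / (n_targets + 1)) - z(
        (false_alarms + 0.5) / (n_nontargets + 1)
    )
    return min(max(d, lo), hi)


def residualize_flat(dataset):
    """Intercept-only residualization for flat-structure cohorts."""
    fits = {
        oc: fit_trend(
            dataset,
            TrendModelSpec(
                oc, degree=0, transform=DEFAULT_TRANSFORMS[oc],
                covariance=COVARIANCE_BY_OUTCOME[oc],
            ),
        )
        for oc in ("dprime", "mood", "steps", "heart_rate")
    }
    return build_residuals(fits)


def observable_step_mood_slope(
    config: SimulationConfig, n: int = 500_000, seed: int = 12345
) -> float:
    """Monte-Carlo estimand: slope of the observed (rounded, bounded 3-12)
    mood total on the square-root-scale step fluctuation.

    Derived directly from the generative description, independent of any
    model-fitting code; used as the truth in coefficient-recovery checks,
    since discretization of the bounded mood scale attenuates the latent
    coupling.
    """
    rng = np.random.default_rng(seed)
    m_i = np.maximum(
        500.0, config.step_mean + config.step_sd * rng.standard_normal(n)
    )
    w = rng.integers(1, 8, n) - 4.0
    det = (
        np.sqrt(m_i)
        + config.step_weekday_linear * w
        + config.step_weekday_quadratic * w * w
    )
    eta = config.noise_sd_steps * rng.standard_normal(n)
    fluct = np.maximum(0.0, det + eta) ** 2 - np.maximum(0.0, det) ** 2
    baseline = np.clip(
        config.mood_baseline_mean
        + config.mood_baseline_sd * rng.standard_normal(n),
        3.0, 12.0,
    )
    day = rng.integers(1, config.n_days + 1, n)
    latent = (
        baseline
        + config.mood_day_trend * (day - 1)
        + config.coupling_step_mood_same_day * fluct
        + config.noise_sd_mood * rng.standard_normal(n)
    )
    obs = np.round(np.clip(latent, 3.0, 12.0))
    return float(np.cov(obs, eta)[0, 1] / np.var(eta))
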