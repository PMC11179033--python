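"""Individual practice-curve characterization for the n-back task.

Each participant's d-prime series is baseline-adjusted by their starting
point (the per-participant intercept of the selected trend model), smoothed
with a trailing 3-assessment moving average (the typical number of
assessments per day), and fitted with the inverse curve

    Y = a - b / X,

where ``X`` counts the participant's consecutive completed assessments,
``a`` is the asymptote (the theoretically best baseline-adjusted score) and
``b`` the slope.  From an adequate fit (both parameters significant) come
the 90% learning rate — the number of assessments to reach 90% of the
asymptote, X = 10 b / a — the study day on which that count is reached, and
the stable maximal d-prime (asymptote plus starting point).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, shapiro, spearmanr
from scipy.stats import t as t_dist

from .nback import ValidationError


@dataclass
class LearningCurve:
    participant_id: str
    starting_point: float
    asymptote_a: float
    slope_b: float
    se_a: float
    se_b: float
    t_a: float
    t_b: float
    p_a: float
    p_b: float
    fit_adequate: bool
    n_points: int
    learning_rate_90: float | None = None  # assessments (real-valued)
    learning_day_90: int | None = None  # 1-based study day
    stable_max: float | None = None
    failure_reason: str | None = None


def baseline_adjust(
    scores: pd.DataFrame, starting_point: float
) -> pd.DataFrame:
    """Baseline-adjusted series for one participant.

    ``scores`` must hold one participant's sessions with ``assessment_index``
    and ``d_prime``; returns a frame with X (assessment index), Y (d-prime
    minus starting point) and day_index, ordered by X.
    """
    df = scores.sort_values("assessment_index")
    return pd.DataFrame(
        {
            "X": df["assessment_index"].to_numpy(dtype=float),
            "Y": df["d_prime"].to_numpy(dtype=float) - starting_point,
            "day_index": df["day_index"].to_numpy(),
        }
    )


def smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Trailing moving average preserving series length.

    The first ``window - 1`` points average all available preceding points
    (partial windows), so no future data enters any smoothed value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot smooth an empty series")
    if window < 1:
        raise ValidationError("window must be >= 1")
    c = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(1, values.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def fit_inverse_curve(
    adjusted: pd.DataFrame,
    participant_id: str = "",
    starting_point: float = 0.0,
    adequacy_alpha: float = 0.05,
    presmoothed: bool = False,
    window: int = 3,
) -> LearningCurve:
    """Least-squares inverse-curve fit of a baseline-adjusted series.

    Standard errors come from the least-squares covariance at the optimum;
    t statistics use n - 2 degrees of freedom.  The fit is adequate when both
    parameters are significant at ``adequacy_alpha`` (two-sided).  A failed
    or degenerate fit is reported through ``fit_adequate=False`` with a
    reason, never an exception.
    """
    X = adjusted["X"].to_numpy(dtype=float)
    Y = adjusted["Y"].to_numpy(dtype=float)
    if np.any(X < 1):
        raise ValidationError("assessment index X must be >= 1")
    if len(X) < 5:
        raise ValidationError("inverse-curve fit needs at least 5 points")
    Ys = Y if presmoothed else smooth(Y, window)

    def _failed(reason: str) -> LearningCurve:
        return LearningCurve(
            participant_id=participant_id, starting_point=starting_point,
            asymptote_a=np.nan, slope_b=np.nan, se_a=np.nan, se_b=np.nan,
            t_a=np.nan, t_b=np.nan, p_a=np.nan, p_b=np.nan,
            fit_adequate=False, n_points=len(X), failure_reason=reason,
        )

    # the inverse curve is linear in (a, b) with regressor -1/X, so the
    # least-squares problem has an exact solution; scipy's curve_fit on the
    # nonlinear form converges to the same optimum but its Jacobian-based
    # covariance degenerates on boundary/perfect fits
    A = np.column_stack([np.ones_like(X), -1.0 / X])
    try:
        popt, rss, rank, _ = np.linalg.lstsq(A, Ys, rcond=None)
        if rank < 2:
            return _failed("degenerate design (all X equal)")
        resid = Ys - A @ popt
        s2 = float(resid @ resid) / max(len(X) - 2, 1)
        pcov = s2 * np.linalg.inv(A.T @ A)
    except np.linalg.LinAlgError as exc:
        return _failed(f"optimizer failure: {exc}")
    a, b = float(popt[0]), float(popt[1])
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    dfree = max(len(X) - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # se == 0 happens on exactly-fitting degenerate series; a parameter
        # that is itself 0 is then a clean "no effect", not an infinite t
        tvals = np.where(
            se > 0, popt / se, np.where(np.abs(popt) < 1e-12, 0.0, np.inf)
        )
    pvals = 2.0 * t_dist.sf(np.abs(tvals), dfree)
    adequate = bool(pvals[0] < adequacy_alpha and pvals[1] < adequacy_alpha)
    curve = LearningCurve(
        participant_id=participant_id, starting_point=starting_point,
        asymptote_a=a, slope_b=b,
        se_a=float(se[0]), se_b=float(se[1]),
        t_a=float(tvals[0]), t_b=float(tvals[1]),
        p_a=float(pvals[0]), p_b=float(pvals[1]),
        fit_adequate=adequate, n_points=len(X),
        failure_reason=None if adequate else "non-significant parameter(s)",
    )
    if adequate and a > 0 and b > 0:
        curve.learning_rate_90 = learning_rate_90(curve)
        curve.stable_max = a + starting_point
    return curve


def learning_rate_90(curve: LearningCurve) -> float:
    """Assessments to reach 90% of the asymptote: X = 10 b / a.

    At this X the fitted curve equals a - b/(10 b / a) = 0.9 a exactly.
    """
    if not curve.fit_adequate or not curve.asymptote_a > 0:
        raise ValidationError(
            "90% learning rate is defined only for adequate fits with a > 0"
        )
    return 10.0 * curve.slope_b / curve.asymptote_a


def map_to_day(rate: float, scores: pd.DataFrame) -> int:
    """Smallest study day whose cumulative completed-assessment count
    reaches ``ceil(rate)``."""
    df = scores.sort_values("assessment_index")
    needed = ceil(rate)
    per_day = df.groupby("day_index").size().sort_index().cumsum()
    reached = per_day[per_day >= needed]
    if reached.empty:
        return int(per_day.index.max())
    return int(reached.index[0])


def characterize_cohort(
    sessions: pd.DataFrame,
    starting_points: pd.Series,
    adequacy_alpha: float = 0.05,
    window: int = 3,
) -> pd.DataFrame:
    """Fit one learning curve per participant; returns the curve table.

    Participants missing a starting point or with too few assessments are
    reported with ``fit_adequate=False`` and a reason.
    """
    rows = []
    for pid, grp in sessions.groupby("participant_id"):
        grp = grp[~grp["excluded"].astype(bool)]
        if pid not in starting_points.index:
            continue
        sp = float(starting_points.loc[pid])
        adjusted = baseline_adjust(grp, sp)
        try:
            curve = fit_inverse_curve(
                adjusted, participant_id=pid, starting_point=sp,
                adequacy_alpha=adequacy_alpha, window=window,
            )
        except ValidationError as exc:
            curve = LearningCurve(
                participant_id=pid, starting_point=sp, asymptote_a=np.nan,
                slope_b=np.nan, se_a=np.nan, se_b=np.nan, t_a=np.nan,
                t_b=np.nan, p_a=np.nan, p_b=np.nan, fit_adequate=False,
                n_points=len(adjusted), failure_reason=str(exc),
            )
        if curve.learning_rate_90 is not None:
            curve.learning_day_90 = map_to_day(curve.learning_rate_90, grp)
        rows.append(curve.__dict__)
    return pd.DataFrame(rows)


def correlate_learning_params(
    curves: pd.DataFrame, summaries: pd.DataFrame, n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate curve parameters with participant summary measures.

    ``curves`` is a characterize_cohort table; ``summaries`` has one row per
    participant with summary columns (e.g. mean mood, mean daily steps).
    Normality of each variable is checked with Shapiro-Wilk at alpha=.05;
    Pearson r is used when both pass, Spearman rho otherwise.  95% CIs come
    from the Fisher transform (Pearson) or a participant bootstrap (Spearman).
    """
    ok = curves[curves["fit_adequate"]].set_index("participant_id")
    if len(ok) < 5:
        raise ValidationError("need at least 5 participants with adequate fits")
    summaries = summaries.loc[summaries.index.intersection(ok.index)]
    ok = ok.loc[summaries.index]
    rng = np.random.default_rng(seed)
    rows = []
    for param in ("asymptote_a", "slope_b"):
        x = ok[param].to_numpy(dtype=float)
        for col in summaries.columns:
            y = summaries[col].to_numpy(dtype=float)
            if len(x) < 5:
                continue
            normal = (
                shapiro(x).pvalue > 0.05 and shapiro(y).pvalue > 0.05
            )
            if normal:
                r, p = pearsonr(x, y)
                z = np.arctanh(np.clip(r, -0.999999, 0.999999))
                hw = norm.ppf(0.975) / np.sqrt(len(x) - 3)
                lo, hi = np.tanh(z - hw), np.tanh(z + hw)
                method = "pearson"
            else:
                r, p = spearmanr(x, y)
                boots = []
                n = len(x)
                for _ in range(n_boot):
                    idx = rng.integers(0, n, n)
                    if len(np.unique(x[idx])) < 2 or len(np.unique(y[idx])) < 2:
                        continue
                    boots.append(spearmanr(x[idx], y[idx]).statistic)
                lo, hi = np.percentile(boots, [2.5, 97.5])
                method = "spearman"
            rows.append(
                dict(parameter=param, summary=col, method=method,
                     estimate=float(r), p=float(p), ci_low=float(lo),
                     ci_high=float(hi), n=len(x))
            )
    return pd.DataFrame(rows)
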