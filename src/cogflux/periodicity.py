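"""Diurnal and day-of-week structure on top of the selected trend models.

Time of day enters as a continuous clock-hour variable; weekday as a numeric
code 1 (Monday) through 7 (Sunday).  For each axis, linear and quadratic
fixed effects are appended to the outcome's selected trend model and kept
only when the likelihood-ratio test against the base model is significant.
Both variables are centred before squaring to limit collinearity; reported
coefficients are mapped back to the raw hour / weekday-code scale.

For d-prime and mood — the streams with within-day variation — time-of-day
terms are evaluated first and weekday terms are then tested on top of
whichever time-of-day model won.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd

from .lmm import likelihood_ratio
from .nback import ValidationError
from .trends import ModelComparison, TrendFit, fit_trend


@dataclass(frozen=True)
class PeriodicTermSpec:
    axis: str  # "time_of_day" or "weekday"
    degree: int = 2  # 1 = linear only, 2 = linear + quadratic

    def __post_init__(self):
        if self.axis not in ("time_of_day", "weekday"):
            raise ValidationError(f"unknown periodic axis {self.axis!r}")
        if self.degree not in (1, 2):
            raise ValidationError("periodic degree must be 1 or 2")


@dataclass
class PeriodicComparison:
    base: TrendFit
    augmented: TrendFit
    chi2: float
    df: int
    p: float
    retained: bool  # augmented model kept at the alpha threshold

    @property
    def selected(self) -> TrendFit:
        return self.augmented if self.retained else self.base


def weekday_of(d: date | datetime | pd.Timestamp) -> int:
    """Weekday code with Monday = 1 ... Sunday = 7."""
    return pd.Timestamp(d).isoweekday()


def _axis_values(frame: pd.DataFrame, axis: str) -> np.ndarray:
    if axis == "time_of_day":
        vals = frame["time_of_day"].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValidationError(
                "time-of-day terms are inapplicable to a stream with one "
                "observation per day"
            )
        return vals
    return frame["weekday"].to_numpy(dtype=float)


def periodic_columns(
    frame: pd.DataFrame, term: PeriodicTermSpec
) -> tuple[pd.DataFrame, float]:
    """Centred linear/quadratic columns for the axis; returns (columns, centre)."""
    vals = _axis_values(frame, term.axis)
    centre = float(np.mean(vals))
    cols = {f"{term.axis}_linear": vals - centre}
    if term.degree == 2:
        cols[f"{term.axis}_quadratic"] = (vals - centre) ** 2
    return pd.DataFrame(cols, index=frame.index), centre


def add_periodic_terms(
    base: TrendFit,
    term: PeriodicTermSpec,
    alpha: float = 0.05,
) -> PeriodicComparison:
    """Append periodic fixed effects to a fitted trend model and test them.

    The augmented model is retained only when the likelihood-ratio test
    against ``base`` is significant at ``alpha``.  The returned augmented fit
    carries raw-scale periodic coefficients in ``extra["periodic_raw"]``:
    for a centred quadratic b1*(x-c) + b2*(x-c)^2 the raw linear term is
    b1 - 2*b2*c and the quadratic term is b2.
    """
    frame = base.data
    extra_base = None
    if base.extra_terms:
        # keep whatever periodic columns the base model already carries
        extra_base = base.data[base.extra_terms]
    cols, centre = periodic_columns(frame, term)
    if extra_base is not None:
        cols = pd.concat([extra_base, cols], axis=1)
    aug = fit_trend(frame, base.spec, extra_columns=cols)
    aug.data = frame.copy()
    for c in cols.columns:
        aug.data[c] = cols[c].to_numpy()
    chi2, df, p = likelihood_ratio(base.lmm, aug.lmm)
    retained = bool(p < alpha and aug.converged)

    tab = aug.fixed_table.set_index("term")
    lin = float(tab.loc[f"{term.axis}_linear", "estimate"])
    raw = {"centre": centre, f"{term.axis}_linear": lin}
    if term.degree == 2:
        quad = float(tab.loc[f"{term.axis}_quadratic", "estimate"])
        raw[f"{term.axis}_linear"] = lin - 2.0 * quad * centre
        raw[f"{term.axis}_quadratic"] = quad
    aug.lmm.extra["periodic_raw"] = raw
    return PeriodicComparison(
        base=base, augmented=aug, chi2=chi2, df=df, p=p, retained=retained
    )


def periodic_analysis(
    comparison: ModelComparison, alpha: float = 0.05
) -> dict:
    """Run the outcome's periodic-term sequence on its selected trend model.

    d-prime and mood: time-of-day first, then weekday on the winner.
    steps and heart rate: weekday only.  Returns the final fit plus the
    individual comparisons.
    """
    outcome = comparison.outcome
    current = comparison.selected
    out: dict = {"outcome": outcome, "comparisons": {}}
    if outcome in ("dprime", "mood"):
        c_tod = add_periodic_terms(current, PeriodicTermSpec("time_of_day"), alpha)
        out["comparisons"]["time_of_day"] = c_tod
        current = c_tod.selected
    c_wd = add_periodic_terms(current, PeriodicTermSpec("weekday"), alpha)
    out["comparisons"]["weekday"] = c_wd
    out["final"] = c_wd.selected
    return out
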