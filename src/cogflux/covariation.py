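"""Concurrent and time-lagged covariation of daily fluctuations.

Fluctuations are the conditional residuals of each outcome's final model
(trend plus any retained periodic terms): the deviation of each observation
from that participant's own fitted trajectory.  Because d-prime is assessed
up to three times daily while everything else is a daily summary, d-prime
residuals are averaged within day to give one value per participant-day.

Covariation models are hierarchical: daily mood residuals regressed on
same-day (concurrent) or adjacent-day (lagged) residuals of the other
outcomes, with participant random intercepts and AR(1) day-sequence errors.
Predictors enter lagged models only when significant in the concurrent
model.  Sensitivity reruns exclude each learner's days before their 90%
learning plateau, and optionally restrict to days with all three n-back
assessments completed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMFit, fit_lmm
from .nback import ValidationError
from .trends import TrendFit

logger = logging.getLogger(__name__)

RESIDUAL_OUTCOMES = ("dprime", "mood", "steps", "heart_rate")


@dataclass
class CovariationResult:
    label: str  # concurrent / lag_prev_day / lag_next_day (+ suffixes)
    response: str
    predictors: list[str]
    table: pd.DataFrame  # term, estimate, se, t, p
    n_obs: int
    n_groups: int
    fit: LMMFit | None = None
    exclusions: dict = field(default_factory=dict)

    def coefficient(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def build_residuals(fits: dict[str, TrendFit]) -> pd.DataFrame:
    """Daily residual series from the final per-outcome models.

    ``fits`` maps outcome name to its final fitted model (trend plus retained
    periodic terms).  Returns one row per participant-day with residual
    columns per outcome (NaN when unobserved), the number of n-back
    assessments that day, and the residuals' day index.  Step and heart-rate
    residuals stay on their transformed (sqrt / log) scales.
    """
    missing = [o for o in fits if fits[o] is None]
    if missing:
        raise ValidationError(f"missing fits for outcomes {missing}")
    frames = []
    for outcome, fit in fits.items():
        df = fit.data[["participant_id", "day_index"]].copy()
        df["resid"] = fit.lmm.resid
        if outcome == "dprime":
            daily = (
                df.groupby(["participant_id", "day_index"])
                .agg(resid=("resid", "mean"), n_nback_today=("resid", "size"))
                .reset_index()
            )
        else:
            daily = df.groupby(["participant_id", "day_index"], as_index=False)[
                "resid"
            ].mean()
        daily = daily.rename(columns={"resid": outcome})
        frames.append(daily)
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=["participant_id", "day_index"], how="outer")
    if "n_nback_today" in out.columns:
        out["n_nback_today"] = out["n_nback_today"].fillna(0).astype(int)
    return out.sort_values(["participant_id", "day_index"]).reset_index(drop=True)


def _fit_daily_model(
    frame: pd.DataFrame, response: str, predictors: list[str], label: str,
    exclusions: dict | None = None,
) -> CovariationResult:
    cols = [response] + predictors
    data = frame.dropna(subset=cols)
    kept_predictors = []
    for p in predictors:
        if np.std(data[p].to_numpy(dtype=float)) < 1e-12:
            logger.warning("predictor %s has degenerate variance; dropped", p)
            continue
        kept_predictors.append(p)
    if not kept_predictors:
        raise ValidationError("no predictor with non-degenerate variance")
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in kept_predictors]
    )
    fit = fit_lmm(
        y=data[response].to_numpy(dtype=float),
        X=X,
        groups=data["participant_id"].to_numpy(),
        times=data["day_index"].to_numpy(dtype=float),
        term_names=["intercept"] + kept_predictors,
        re_slope=False,
        corr="ar1",
        df_method="cluster",
    )
    return CovariationResult(
        label=label, response=response, predictors=kept_predictors,
        table=fit.coef_table(), n_obs=fit.n_obs, n_groups=fit.n_groups,
        fit=fit, exclusions=dict(exclusions or {}),
    )


def concurrent_covariation(
    residuals: pd.DataFrame,
    response: str = "mood",
    predictors: tuple[str, ...] = ("dprime", "steps", "heart_rate"),
    exclusions: dict | None = None,
) -> CovariationResult:
    """Same-day covariation: mood residuals on the other domains' residuals."""
    usable = residuals.dropna(subset=[response])
    per_group = usable.groupby("participant_id").size()
    if (per_group >= 5).sum() < 2:
        raise ValidationError(
            "concurrent covariation needs >=2 participants with >=5 days"
        )
    return _fit_daily_model(
        residuals, response, list(predictors), "concurrent", exclusions
    )


def lagged_covariation(
    residuals: pd.DataFrame,
    predictor: str,
    direction: str = "prev_day",
    response: str = "mood",
    adjust_concurrent: bool = False,
    exclusions: dict | None = None,
) -> CovariationResult:
    """Mood residual on day t vs predictor residual on day t-1 or t+1.

    Pairs are formed only from consecutive calendar days on which both the
    response and the lagged predictor exist.  With ``adjust_concurrent`` the
    same-day predictor residual enters as a covariate; this is the variant to
    use for directionality questions, because when a same-day association is
    present the AR(1) whitening of an unadjusted lag model mixes it into the
    lagged coefficient (the whitened regressor contains the same-day value).
    """
    if direction not in ("prev_day", "next_day"):
        raise ValidationError(f"unknown lag direction {direction!r}")
    shift = -1 if direction == "prev_day" else +1
    lag_name = f"{predictor}_{direction}"
    lagged = residuals[["participant_id", "day_index", predictor]].copy()
    lagged["day_index"] = lagged["day_index"] - shift
    lagged = lagged.rename(columns={predictor: lag_name})
    base_cols = ["participant_id", "day_index", response]
    if adjust_concurrent:
        base_cols.append(predictor)
    merged = residuals[base_cols].merge(
        lagged, on=["participant_id", "day_index"], how="inner"
    )
    predictors = [lag_name] + ([predictor] if adjust_concurrent else [])
    merged = merged.dropna(subset=[response] + predictors)
    if len(merged) < 10:
        raise ValidationError(
            f"only {len(merged)} valid lagged pairs (<10) for {predictor} "
            f"{direction}"
        )
    label = f"lag_{direction}" + ("_adjusted" if adjust_concurrent else "")
    return _fit_daily_model(merged, response, predictors, label, exclusions)


def exclude_learning_period(
    residuals: pd.DataFrame, curves: pd.DataFrame
) -> pd.DataFrame:
    """Drop each learner's days strictly before their 90% plateau day.

    The boundary day itself is kept (it is the first at-plateau day).
    Non-learners — participants without an adequate curve fit — contribute
    all their data unchanged.
    """
    cutoff = {}
    for _, row in curves.iterrows():
        if row.get("fit_adequate") and pd.notna(row.get("learning_day_90")):
            cutoff[row["participant_id"]] = int(row["learning_day_90"])
    keep = np.ones(len(residuals), dtype=bool)
    for pid, day in cutoff.items():
        keep &= ~(
            (residuals["participant_id"] == pid)
            & (residuals["day_index"] < day)
        )
    return residuals[keep].reset_index(drop=True)


def restrict_complete_days(
    residuals: pd.DataFrame, n_required: int = 3
) -> pd.DataFrame:
    """Keep only days with exactly ``n_required`` completed n-back sessions."""
    if "n_nback_today" not in residuals.columns:
        raise ValidationError("residual frame lacks n_nback_today")
    return residuals[residuals["n_nback_today"] == n_required].reset_index(
        drop=True
    )


def run_full_covariation(
    residuals: pd.DataFrame,
    curves: pd.DataFrame | None,
    alpha: float = 0.05,
    predictors: tuple[str, ...] = ("dprime", "steps", "heart_rate"),
) -> dict[str, CovariationResult]:
    """The complete covariation sequence, every model's table archived.

    concurrent -> lagged (both directions) for concurrent-significant
    predictors -> rerun after learning-period exclusion -> rerun restricted
    to complete assessment days (when d-prime was concurrently significant
    post-exclusion).
    """
    results: dict[str, CovariationResult] = {}
    conc = concurrent_covariation(residuals, predictors=predictors)
    results["concurrent"] = conc
    sig = [
        p for p in conc.predictors
        if float(conc.coefficient(p)["p"]) < alpha
    ]
    for p in sig:
        for direction in ("prev_day", "next_day"):
            for adjust in (False, True):
                suffix = "_adjusted" if adjust else ""
                try:
                    results[f"lag_{direction}_{p}{suffix}"] = lagged_covariation(
                        residuals, p, direction, adjust_concurrent=adjust
                    )
                except ValidationError as exc:
                    logger.warning("lag model skipped: %s", exc)
    if curves is not None:
        post = exclude_learning_period(residuals, curves)
        conc_post = concurrent_covariation(
            post, predictors=predictors,
            exclusions={"learning_period_excluded": True},
        )
        results["concurrent_post_learning"] = conc_post
        sig_post = [
            p for p in conc_post.predictors
            if float(conc_post.coefficient(p)["p"]) < alpha
        ]
        for p in sig_post:
            for direction in ("prev_day", "next_day"):
                try:
                    results[f"lag_{direction}_{p}_post_learning"] = (
                        lagged_covariation(
                            post, p, direction,
                            exclusions={"learning_period_excluded": True},
                        )
                    )
                except ValidationError as exc:
                    logger.warning("lag model skipped: %s", exc)
        if "dprime" in sig_post and "n_nback_today" in post.columns:
            complete = restrict_complete_days(post)
            try:
                results["concurrent_post_learning_complete_days"] = (
                    concurrent_covariation(
                        complete, predictors=predictors,
                        exclusions={
                            "learning_period_excluded": True,
                            "complete_days_only": True,
                        },
                    )
                )
            except ValidationError as exc:
                logger.warning("complete-days model skipped: %s", exc)
    return results
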