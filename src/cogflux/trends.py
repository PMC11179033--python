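"""Change-over-time models per outcome stream.

Each outcome (d-prime, mood total, daily steps, daily mean heart rate) is
modelled with a hierarchical polynomial trend on time since onset: fixed
polynomial effects of degree 0-3, participant-level random intercept and
slope, and serially correlated residuals — CAR(1) on continuous time for the
irregularly timed assessment streams, AR(1) on the day index for the daily
summaries.  Models are fitted by maximum likelihood and compared with
sequential likelihood-ratio tests; AIC and BIC are reported alongside but do
not drive the selection.

Polynomial designs are orthogonalized internally (thin QR of the raw-time
Vandermonde) and coefficients are mapped back to the raw powers of time for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import shapiro

from .dataset import StudyDataset
from .lmm import LMMFit, fit_lmm, likelihood_ratio
from .nback import ValidationError

OUTCOMES = ("dprime", "mood", "steps", "heart_rate")

#: residual-correlation structure per outcome: unequally spaced assessment
#: streams use continuous-time AR, daily summaries use day-lag AR
COVARIANCE_BY_OUTCOME = {
    "dprime": "car1",
    "mood": "car1",
    "steps": "ar1",
    "heart_rate": "ar1",
}

DEFAULT_TRANSFORMS = {
    "dprime": "identity",
    "mood": "identity",
    "steps": "sqrt",
    "heart_rate": "log",
}


@dataclass(frozen=True)
class TrendModelSpec:
    outcome: str
    degree: int = 1
    transform: str = "identity"
    covariance: str = "car1"
    random_slope: bool = True

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.degree not in (0, 1, 2, 3):
            raise ValidationError("degree must be 0, 1, 2 or 3")
        if self.transform not in ("identity", "log", "sqrt"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.covariance not in ("car1", "ar1", "none"):
            raise ValidationError(f"unknown covariance {self.covariance!r}")


@dataclass
class TrendFit:
    """A fitted polynomial trend model for one outcome."""

    spec: TrendModelSpec
    lmm: LMMFit
    fixed_table: pd.DataFrame  # raw-time-scale coefficients
    data: pd.DataFrame  # the analysis frame the model was fitted on
    qr_R: np.ndarray  # maps orthogonal-basis coefficients to raw powers
    extra_terms: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.lmm.converged

    @property
    def loglik(self) -> float:
        return self.lmm.loglik

    @property
    def aic(self) -> float:
        return self.lmm.aic

    @property
    def bic(self) -> float:
        return self.lmm.bic

    @property
    def residuals(self) -> np.ndarray:
        return self.lmm.resid


@dataclass
class ModelComparison:
    outcome: str
    table: pd.DataFrame  # degree, loglik, aic, bic, chi2, df, p, selected
    fits: dict[int, TrendFit]
    selected_degree: int

    @property
    def selected(self) -> TrendFit:
        return self.fits[self.selected_degree]


# ---------------------------------------------------------------------------
# transforms


def transform_outcome(values: np.ndarray, transform: str) -> np.ndarray:
    """Element-wise transform with domain checks naming offending records."""
    values = np.asarray(values, dtype=float)
    if transform == "identity":
        return values
    if transform == "log":
        bad = np.flatnonzero(values <= 0)
        if len(bad):
            raise ValidationError(
                f"log transform requires strictly positive values; offending "
                f"record indices {[int(i) for i in bad[:5]]}"
            )
        return np.log(values)
    if transform == "sqrt":
        bad = np.flatnonzero(values < 0)
        if len(bad):
            raise ValidationError(
                f"sqrt transform requires non-negative values; offending "
                f"record indices {[int(i) for i in bad[:5]]}"
            )
        return np.sqrt(values)
    raise ValidationError(f"unknown transform {transform!r}")


def inverse_transform(values: np.ndarray, transform: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if transform == "identity":
        return values
    if transform == "log":
        return np.exp(values)
    if transform == "sqrt":
        return values ** 2
    raise ValidationError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# analysis frames


def outcome_frame(
    dataset: StudyDataset, outcome: str, transform: str | None = None
) -> pd.DataFrame:
    """Long-format analysis frame for one outcome.

    Columns: participant_id, time (days since onset; continuous for the
    assessment streams, integer day index for daily summaries), day_index,
    time_of_day (assessment streams only), weekday, y (transformed scale).
    Excluded/non-wear records are dropped here.
    """
    transform = transform or DEFAULT_TRANSFORMS[outcome]
    if outcome == "dprime":
        df = dataset.sessions
        df = df[~df["excluded"].astype(bool)].copy()
        df["time"] = (df["day_index"] - 1) + df["time_of_day"] / 24.0
        df["y"] = transform_outcome(df["d_prime"].to_numpy(), transform)
        dates = pd.to_datetime(df["timestamp"])
    elif outcome == "mood":
        df = dataset.moods
        df = df[~df["excluded"].astype(bool)].copy()
        df["time"] = (df["day_index"] - 1) + df["time_of_day"] / 24.0
        df["y"] = transform_outcome(df["total"].to_numpy(), transform)
        dates = pd.to_datetime(df["timestamp"])
    elif outcome in ("steps", "heart_rate"):
        df = dataset.dailies
        df = df[df["wear"].astype(bool)].copy()
        if outcome == "heart_rate":
            df = df[df["mean_heart_rate"].notna()].copy()
            df["y"] = transform_outcome(df["mean_heart_rate"].to_numpy(), transform)
        else:
            df["y"] = transform_outcome(df["step_count"].to_numpy(), transform)
        df["time"] = df["day_index"].astype(float)
        df["time_of_day"] = np.nan
        dates = pd.to_datetime(df["date"])
    else:
        raise ValidationError(f"unknown outcome {outcome!r}")
    df["weekday"] = dates.dt.dayofweek.to_numpy() + 1  # 1=Monday .. 7=Sunday
    cols = ["participant_id", "time", "day_index", "time_of_day", "weekday", "y"]
    return df[cols].reset_index(drop=True)


def _poly_basis(times: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal polynomial basis Q and the map R with vander = Q R."""
    P = np.vander(times, N=degree + 1, increasing=True)
    Q, R = np.linalg.qr(P)
    # fix signs so the constant column is positive (determinate basis)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs, R * signs[:, None]


# ---------------------------------------------------------------------------
# fitting and selection


def fit_trend(
    dataset_or_frame: StudyDataset | pd.DataFrame,
    spec: TrendModelSpec,
    extra_columns: pd.DataFrame | None = None,
    theta0: np.ndarray | None = None,
) -> TrendFit:
    """Fit the polynomial trend model described by ``spec``.

    ``extra_columns`` may carry additional fixed-effect columns (used by the
    periodicity stage); their coefficients are reported untransformed.
    """
    if isinstance(dataset_or_frame, StudyDataset):
        frame = outcome_frame(dataset_or_frame, spec.outcome, spec.transform)
    else:
        frame = dataset_or_frame.reset_index(drop=True)
    if frame["participant_id"].nunique() < 2 or len(frame) < 6:
        raise ValidationError(
            "trend fitting needs at least 3 observations from at least 2 "
            "participants"
        )
    t = frame["time"].to_numpy(dtype=float)
    Q, R = _poly_basis(t, spec.degree)
    names = [f"time^{j}" for j in range(spec.degree + 1)]
    names[0] = "intercept"
    X = Q
    extra_names: list[str] = []
    if extra_columns is not None:
        X = np.column_stack([Q, extra_columns.to_numpy(dtype=float)])
        extra_names = list(extra_columns.columns)
    lmm = fit_lmm(
        y=frame["y"].to_numpy(dtype=float),
        X=X,
        groups=frame["participant_id"].to_numpy(),
        times=t,
        term_names=names + extra_names,
        re_slope=spec.random_slope,
        corr=spec.covariance,
        est_phi=spec.covariance != "none",
        theta0=theta0,
    )
    # back-transform the polynomial block to raw powers of time
    k = spec.degree + 1
    Rinv = np.linalg.inv(R)
    beta_raw = Rinv @ lmm.beta[:k]
    covQ = _beta_cov(lmm, k)
    cov_raw = Rinv @ covQ @ Rinv.T
    se_raw = np.sqrt(np.maximum(np.diag(cov_raw), 0.0))
    from scipy.stats import t as t_dist

    with np.errstate(divide="ignore", invalid="ignore"):
        t_raw = np.where(se_raw > 0, beta_raw / se_raw, np.inf)
    dfree = max(lmm.n_obs - X.shape[1], 1)
    p_raw = 2.0 * t_dist.sf(np.abs(t_raw), dfree)
    rows = [
        dict(term=names[j], estimate=beta_raw[j], se=se_raw[j],
             t=t_raw[j], p=p_raw[j])
        for j in range(k)
    ]
    for j, name in enumerate(extra_names):
        rows.append(
            dict(term=name, estimate=lmm.beta[k + j], se=lmm.beta_se[k + j],
                 t=lmm.tvalues[k + j], p=lmm.pvalues[k + j])
        )
    return TrendFit(
        spec=spec, lmm=lmm, fixed_table=pd.DataFrame(rows), data=frame,
        qr_R=R, extra_terms=extra_names,
    )


def _beta_cov(lmm: LMMFit, k: int) -> np.ndarray:
    cov = lmm.extra.get("cov_beta")
    if cov is not None:
        return cov[:k, :k]
    # fall back to the diagonal if the full covariance was not stored
    return np.diag(lmm.beta_se[:k] ** 2)


def select_trend(
    dataset_or_frame: StudyDataset | pd.DataFrame,
    outcome: str,
    transform: str | None = None,
    alpha: float = 0.05,
    random_slope: bool = True,
) -> ModelComparison:
    """Sequential forward selection of the polynomial degree by LRT.

    Starting from the intercept-only model, a higher degree replaces the
    current selection only when its likelihood-ratio test against the current
    selection is significant at ``alpha``.  Degrees that fail to converge are
    skipped and logged in the comparison table.
    """
    transform = transform or DEFAULT_TRANSFORMS[outcome]
    spec0 = TrendModelSpec(
        outcome=outcome, degree=0, transform=transform,
        covariance=COVARIANCE_BY_OUTCOME[outcome], random_slope=random_slope,
    )
    if isinstance(dataset_or_frame, StudyDataset):
        frame = outcome_frame(dataset_or_frame, outcome, transform)
    else:
        frame = dataset_or_frame
    fits: dict[int, TrendFit] = {}
    rows = []
    selected = 0
    theta0 = None
    for degree in (0, 1, 2, 3):
        spec = TrendModelSpec(
            outcome=outcome, degree=degree, transform=transform,
            covariance=spec0.covariance, random_slope=random_slope,
        )
        # variance parameters change little between nested degrees, so each
        # degree warm-starts from the previous optimum
        fit = fit_trend(frame, spec, theta0=theta0)
        if fit.converged:
            theta0 = fit.lmm.extra.get("theta")
        fits[degree] = fit
        row = dict(
            degree=degree, converged=fit.converged, loglik=fit.loglik,
            aic=fit.aic, bic=fit.bic, chi2=np.nan, df=np.nan, p=np.nan,
            selected=False,
        )
        if not fit.converged:
            rows.append(row)
            continue
        if degree > 0 and fits[selected].converged:
            chi2, df, p = likelihood_ratio(fits[selected].lmm, fit.lmm)
            row.update(chi2=chi2, df=df, p=p)
            if p < alpha:
                selected = degree
        rows.append(row)
    table = pd.DataFrame(rows)
    table.loc[table["degree"] == selected, "selected"] = True
    return ModelComparison(
        outcome=outcome, table=table, fits=fits, selected_degree=selected
    )


def extract_intercepts(fit: TrendFit) -> pd.Series:
    """Per-participant starting point: fixed intercept + random intercept.

    The fixed intercept is the raw-scale polynomial coefficient at time zero;
    the random part is the participant's predicted (BLUP) intercept.
    """
    if not fit.converged:
        raise ValidationError("cannot extract intercepts from a non-converged fit")
    fixed_intercept = float(
        fit.fixed_table.loc[fit.fixed_table["term"] == "intercept", "estimate"].iloc[0]
    )
    re = fit.lmm.random_effects["intercept"]
    return (fixed_intercept + re).rename("starting_point")


def run_diagnostics(fit: TrendFit) -> dict:
    """Residual diagnostics: normality and spread versus fitted values.

    Reports only — the result never gates the pipeline.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    out: dict = {"n": int(resid.size)}
    if resid.size < 3 or np.allclose(resid, resid[0]):
        out.update(degenerate=True, shapiro_w=np.nan, shapiro_p=np.nan)
        return out
    sample = resid if resid.size <= 4500 else np.random.default_rng(0).choice(
        resid, 4500, replace=False
    )
    w, p = shapiro(sample)
    fitted = np.asarray(fit.lmm.fitted, dtype=float)
    # crude heteroscedasticity summary: spread in fitted-value thirds
    order = np.argsort(fitted)
    thirds = np.array_split(resid[order], 3)
    out.update(
        degenerate=False,
        shapiro_w=float(w),
        shapiro_p=float(p),
        resid_sd_by_fitted_third=[float(np.std(x)) for x in thirds],
        resid_mean=float(np.mean(resid)),
    )
    return out
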