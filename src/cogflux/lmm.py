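"""Maximum-likelihood linear mixed models with autoregressive residuals.

The model for participant ``i`` is

    y_i = X_i beta + Z_i b_i + e_i,
    b_i ~ N(0, sigma^2 Psi),      e_i ~ N(0, sigma^2 R_i(phi)),

where ``Z_i`` holds the random-effect design (intercept, or intercept and
time slope) and ``R_i`` is a correlation matrix with entries ``phi**|t_j -
t_k|``: on continuous time this is the CAR(1) structure for unequally spaced
assessments, on an integer day index the familiar AR(1).

Fitting maximizes the marginal likelihood with ``beta`` and ``sigma^2``
profiled out.  Because the AR correlation is Markov on ordered times, its
Cholesky whitening is bidiagonal and applied in O(n) per participant; the
random-effect part is folded in with the Woodbury identity, so one
likelihood evaluation costs O(N) with only q-by-q (q <= 2) solves.  The
free parameters are the log-Cholesky factor of ``Psi`` and a
logistic-mapped ``phi``; optimization is bounded quasi-Newton (L-BFGS-B)
with a small set of fixed restarts, falling back to a diagonal ``Psi``
when the full covariance is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import t as t_dist

_MIN_DT = 1e-3  # days; floor on time gaps so tied times stay non-singular
_MIN_SIGMA2 = 1e-12


@dataclass
class LMMFit:
    """A fitted mixed model (maximum likelihood)."""

    term_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    psi: np.ndarray  # absolute random-effect covariance (sigma^2 * Psi_rel)
    phi: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    n_params: int
    random_effects: pd.DataFrame  # one row per group; columns per RE term
    fitted: np.ndarray  # conditional fitted values, original row order
    resid: np.ndarray  # conditional residuals, original row order
    resid_marginal: np.ndarray
    converged: bool
    diagonal_psi: bool = False
    message: str = ""
    extra: dict = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.beta,
                "se": self.beta_se,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _prepare(groups: np.ndarray, times: np.ndarray):
    """Stable sort by (group, time); returns order and group slices."""
    order = np.lexsort((np.arange(len(groups)), times, groups))
    g_sorted = groups[order]
    # contiguous group boundaries
    starts = np.flatnonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1]])
    ends = np.r_[starts[1:], len(g_sorted)]
    return order, g_sorted, starts, ends


def _chol_from_theta(theta: np.ndarray, q: int, diagonal: bool) -> np.ndarray:
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(theta[0])
    else:
        L[0, 0] = np.exp(theta[0])
        L[1, 1] = np.exp(theta[2 if not diagonal else 1])
        if not diagonal:
            L[1, 0] = theta[1]
    return L


class _Profile:
    """Profiled negative log-likelihood over (Psi, phi)."""

    def __init__(self, y, X, Z, groups, times, corr, est_phi, diagonal):
        order, g_sorted, starts, ends = _prepare(groups, times)
        self.order = order
        self.starts, self.ends = starts, ends
        self.group_labels = g_sorted[starts]
        self.A = np.column_stack([X, y])[order]
        self.Z = Z[order]
        self.t = times[order].astype(float)
        self.N, self.p = len(y), X.shape[1]
        self.q = Z.shape[1]
        self.corr = corr
        self.est_phi = est_phi and corr != "none"
        self.diagonal = diagonal
        # time gaps within groups (first row of each group flagged)
        dt = np.empty(self.N)
        dt[:] = np.inf
        for s, e in zip(starts, ends):
            dt[s + 1 : e] = np.maximum(self.t[s + 1 : e] - self.t[s : e - 1], _MIN_DT)
        self.dt = dt
        self.first = np.zeros(self.N, dtype=bool)
        self.first[starts] = True
        self.n_theta = (1 if self.q == 1 else (2 if diagonal else 3)) + (
            1 if self.est_phi else 0
        )

    def _phi(self, theta) -> float:
        return float(expit(theta[-1])) if self.est_phi else 0.0

    def _whiten(self, phi: float):
        if phi <= 0.0:
            return self.A, self.Z, 0.0
        rho = np.where(self.first, 0.0, phi ** self.dt)
        w2 = 1.0 - rho * rho
        w = np.sqrt(w2)
        Aprev = np.vstack([np.zeros((1, self.A.shape[1])), self.A[:-1]])
        Zprev = np.vstack([np.zeros((1, self.q)), self.Z[:-1]])
        At = (self.A - rho[:, None] * Aprev) / w[:, None]
        Zt = (self.Z - rho[:, None] * Zprev) / w[:, None]
        logdet_R = float(np.sum(np.log(w2[~self.first])))
        return At, Zt, logdet_R

    def _assemble(self, theta):
        phi = self._phi(theta)
        L = _chol_from_theta(theta, self.q, self.diagonal)
        Psi = L @ L.T
        # Henderson form: (I + Psi G)^{-1} Psi == (Psi^{-1} + G)^{-1}, which
        # stays numerically stable when Psi is huge (noise-free data pushes
        # the ML optimum onto that ridge) or tiny
        Linv = np.linalg.inv(L)
        Psi_inv = Linv.T @ Linv
        logdet_psi = 2.0 * float(np.sum(np.log(np.diag(L))))
        At, Zt, logdet_R = self._whiten(phi)
        m = self.A.shape[1]
        C = np.zeros((m, m))
        logdet = logdet_R
        per_group = []
        for s, e in zip(self.starts, self.ends):
            Ag, Ug = At[s:e], Zt[s:e]
            G = Ug.T @ Ug
            H = Psi_inv + G
            sign, ld = np.linalg.slogdet(H)
            if sign <= 0 or not np.isfinite(ld):
                return None
            logdet += ld + logdet_psi  # log|I + Psi G|
            try:
                KPsi = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return None
            UA = Ug.T @ Ag
            C += Ag.T @ Ag - UA.T @ KPsi @ UA
            per_group.append((s, e, KPsi, UA, G))
        return phi, Psi, C, logdet, per_group, At, Zt

    def neg_loglik(self, theta) -> float:
        out = self._assemble(theta)
        if out is None:
            return 1e12
        _, _, C, logdet, _, _, _ = out
        Sxx = C[: self.p, : self.p]
        Sxy = C[: self.p, self.p]
        Syy = C[self.p, self.p]
        try:
            beta = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError:
            return 1e12
        rss = max(float(Syy - Sxy @ beta), _MIN_SIGMA2)
        sigma2 = rss / self.N
        return 0.5 * (self.N * np.log(2.0 * np.pi * sigma2) + logdet + self.N)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    times: np.ndarray,
    term_names: list[str] | None = None,
    re_slope: bool = False,
    corr: str = "car1",
    est_phi: bool = True,
    theta0: np.ndarray | None = None,
    df_method: str = "residual",
) -> LMMFit:
    """Fit the mixed model by profiled maximum likelihood.

    Parameters
    ----------
    y, X : response vector and fixed-effect design (with intercept column).
    groups : participant labels, one per row.
    times : observation times; continuous days for CAR(1), integer day
        index for AR(1) (``corr`` names the intended structure but both use
        ``phi**|dt|``; ``corr="none"`` fixes phi at 0).
    re_slope : include a random slope on (scaled) time next to the random
        intercept.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]
    t_scale = max(float(np.max(times) - np.min(times)), 1.0)
    z_time = (times - float(np.min(times))) / t_scale
    Z = np.column_stack([np.ones_like(y), z_time]) if re_slope else np.ones((len(y), 1))

    def _solve(diagonal: bool):
        prof = _Profile(y, X, Z, groups, times, corr, est_phi, diagonal)
        n_psi = 1 if prof.q == 1 else (2 if diagonal else 3)
        inits = []
        if theta0 is not None and len(theta0) == prof.n_theta:
            inits.append(np.asarray(theta0, dtype=float))
        for s0 in (-1.0, 0.0, -3.0):
            th = np.zeros(prof.n_theta)
            th[:n_psi] = s0
            if prof.q > 1 and not diagonal:
                th[1] = 0.0
            if prof.est_phi:
                th[-1] = logit(0.3)
            inits.append(th)
        best = None
        for th0 in inits:
            res = minimize(
                prof.neg_loglik, th0, method="L-BFGS-B",
                bounds=[(-35.0, 35.0)] * prof.n_theta,
                options={"maxiter": 200, "ftol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.success and best.fun < 1e11:
                break
        # degenerate (noise-free) data puts the optimum on an unbounded
        # large-Psi / tiny-sigma ridge the generic restarts never reach;
        # probe it explicitly and refine from there when it wins
        th_big = np.zeros(prof.n_theta)
        th_big[:n_psi] = 6.0
        if prof.q > 1 and not diagonal:
            th_big[2] = 6.0
            th_big[1] = 0.0
        if prof.est_phi:
            th_big[-1] = logit(0.05)
        if prof.neg_loglik(th_big) < best.fun - 1e-6:
            res = minimize(
                prof.neg_loglik, th_big, method="L-BFGS-B",
                bounds=[(-35.0, 35.0)] * prof.n_theta,
                options={"maxiter": 200, "ftol": 1e-10},
            )
            if res.fun < best.fun:
                best = res
        return prof, best

    diagonal = False
    prof, res = _solve(diagonal)
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        diagonal = True
        prof2, res2 = _solve(diagonal)
        if res2.fun < res.fun or not np.isfinite(res.fun):
            prof, res = prof2, res2
        else:
            diagonal = False
    converged = bool(np.isfinite(res.fun) and res.fun < 1e11)

    out = prof._assemble(res.x)
    if out is None:
        converged = False
        out = prof._assemble(np.zeros(prof.n_theta))
    phi, Psi_rel, C, logdet, per_group, At, Zt = out
    p = X.shape[1]
    Sxx, Sxy, Syy = C[:p, :p], C[:p, p], C[p, p]
    beta = np.linalg.solve(Sxx, Sxy)
    rss = max(float(Syy - Sxy @ beta), _MIN_SIGMA2)
    sigma2 = rss / prof.N
    cov_beta = sigma2 * np.linalg.inv(Sxx)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    # "residual" df is the asymptotic N - p convention; "cluster" uses
    # G - 1 df, the conservative choice when plug-in covariance parameters
    # are estimated from a modest number of participants
    if df_method == "cluster":
        df = max(len(prof.starts) - 1, 1)
    else:
        df = max(prof.N - p, 1)
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df)
    loglik = -0.5 * (prof.N * np.log(2.0 * np.pi * sigma2) + logdet + prof.N)

    # BLUPs: b_g = Psi U' Sigma^{-1} r  (relative scale; sigma^2 cancels)
    re_rows = []
    fitted_sorted = np.empty(prof.N)
    resid_marg_sorted = np.empty(prof.N)
    Xs = prof.A[:, :p]
    ys = prof.A[:, p]
    Zs = prof.Z
    resid_fix_sorted = ys - Xs @ beta
    rt_all = (At[:, p] - At[:, :p] @ beta)  # whitened marginal residuals
    for (s, e, KPsi, UA, G) in per_group:
        rt = rt_all[s:e]
        Ug = Zt[s:e]
        wvec = Ug.T @ rt
        b = KPsi @ wvec  # (Psi^{-1} + U'U)^{-1} U' r: the BLUP normal equation
        re_rows.append(b)
        fitted_sorted[s:e] = Xs[s:e] @ beta + Zs[s:e] @ b
        resid_marg_sorted[s:e] = resid_fix_sorted[s:e]
    re_df = pd.DataFrame(
        re_rows,
        columns=["intercept", "slope"][: Z.shape[1]],
        index=pd.Index(prof.group_labels, name="participant_id"),
    )
    if re_slope:
        re_df["slope"] = re_df["slope"] / t_scale  # back to per-day units

    inv_order = np.empty(prof.N, dtype=int)
    inv_order[prof.order] = np.arange(prof.N)
    fitted = fitted_sorted[inv_order]
    resid_marginal = resid_marg_sorted[inv_order]
    resid = y - fitted

    q = Z.shape[1]
    n_params = p + (q if diagonal or q == 1 else q * (q + 1) // 2) + 1 + (
        1 if (est_phi and corr != "none") else 0
    )
    aic = 2 * n_params - 2 * loglik
    bic = n_params * np.log(prof.N) - 2 * loglik

    return LMMFit(
        term_names=list(term_names),
        beta=beta, beta_se=se, tvalues=tvals, pvalues=pvals,
        sigma2=sigma2, psi=sigma2 * Psi_rel, phi=phi,
        loglik=float(loglik), aic=float(aic), bic=float(bic),
        n_obs=prof.N, n_groups=len(prof.starts), n_params=n_params,
        random_effects=re_df, fitted=fitted, resid=resid,
        resid_marginal=resid_marginal,
        converged=converged, diagonal_psi=diagonal,
        message=str(res.message),
        extra={"cov_beta": cov_beta, "theta": np.asarray(res.x, dtype=float)},
    )


def likelihood_ratio(small: LMMFit, large: LMMFit) -> tuple[float, int, float]:
    """Chi-square LRT of two nested ML fits: (statistic, df, p)."""
    from scipy.stats import chi2

    stat = max(2.0 * (large.loglik - small.loglik), 0.0)
    df = max(large.n_params - small.n_params, 1)
    return stat, df, float(chi2.sf(stat, df))
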