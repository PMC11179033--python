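# Methods

`cogflux` implements an analysis pipeline for six-week, high-frequency
wearable assessment of cognition, mood, and physical activity in outpatients
with depression: up to three brief 2-back sessions per day, up to two
3-item mood prompts per day, and passive daily step counts and mean heart
rate. This note documents the models, the numerical choices, what the
synthetic cohort generator does and does not emulate, and the design
decisions taken where several reasonable conventions existed.

## Session scoring

A 2-back session is scored as d′ = z(H) − z(F), where H and F are hit and
false-alarm rates under the log-linear extreme-rate correction (add 0.5 to
each count and 1 to each denominator), and the result is clamped to the
instrument's documented range [−3.33, +3.33]. The correction keeps every
possible session outcome finite; the clamp reproduces the printed bounds
exactly — a perfect 9-target/21-non-target session scores 3.33, an
all-wrong session −3.33. The exact correction used by the original task
software is unpublished; the clamped log-linear rule is this package's
declared convention, checked exhaustively against an independent Gaussian
quantile implementation over all 220 outcomes of the default session
geometry.

## Mixed models

All longitudinal models are linear mixed models estimated by maximum
likelihood (module `cogflux.lmm`):

* fixed polynomial effects of time since onset (degree 0–3), orthogonalized
  internally by thin QR of the raw-time Vandermonde and back-transformed to
  raw powers for reporting;
* participant random intercept and random time slope;
* serially correlated residuals with corr(e_j, e_k) = φ^|t_j − t_k|:
  continuous-time AR (CAR(1)) on fractional days for the unequally spaced
  assessment streams (d-prime, mood), AR(1) on the integer day index for
  the daily summaries (steps, heart rate).

The likelihood profiles out the fixed effects and the residual variance.
Because the AR correlation is Markov on ordered times, its Cholesky
whitening is bidiagonal (O(n) per participant), and the random-effect
contribution enters through the Woodbury identity with only 2×2 solves in
the Henderson form (Ψ⁻¹ + Z′Z)⁻¹, which remains stable on the
degenerate-data ridge where the noise variance goes to zero. Free
parameters (log-Cholesky of the relative random-effect covariance, logistic
φ) are optimized by bounded L-BFGS-B with fixed restarts, a warm start from
the previous nested model during degree selection, an explicit probe of the
large-Ψ ridge (reached by noise-free data), and a diagonal-covariance
fallback that is flagged on the fit. Non-convergence is reported, never
silently returned. Time gaps are floored at ~86 s so tied clock times stay
non-singular.

Transforms: identity for d-prime and mood, square root for daily steps,
natural log for heart rate (configurable per run). Degree selection is a
sequential forward likelihood-ratio test at α = .05 starting from the
intercept-only model; AIC/BIC are reported but do not drive the decision.
Under a flat-truth cohort this sequential rule keeps the intercept-only
model at roughly 1 − α (three sequential α-level tests bound the
familywise selection error by 3α).

Degrees of freedom: trend-model coefficient tables use the asymptotic
N − p convention (inference there flows through LRTs). The daily
residual-covariation models instead use t with G − 1 degrees of freedom
(G = number of participants): simulation showed the asymptotic convention
rejects true-null covariation at ~7–8% because the GLS covariance is a
plug-in estimate from only 30 clusters, and the cluster-count df is the
standard conservative remedy that restores the nominal 5%.

## Periodic structure

Time of day enters as continuous clock hours and weekday as a numeric code
1 (Monday) to 7 (Sunday), each with linear and quadratic fixed effects
appended to the selected trend model and kept only when the LRT against the
base model is significant at .05. Both variables are centred before
squaring; reported coefficients are mapped back to the raw hour /
weekday-code scale. Weekday is treated as a numeric 1–7 variable rather
than six indicator contrasts because the analyses report single linear and
quadratic weekday slopes. For d-prime and mood, time-of-day terms are
tested before weekday terms.

## Learning curves

Each participant's starting point is their fixed-plus-predicted (BLUP)
intercept from the selected d-prime trend model. The baseline-adjusted
series Y = d′ − starting point, indexed by the participant's consecutive
completed assessments X, is smoothed with a *trailing* 3-assessment moving
average (partial windows at the start, so no future data enters) and
fitted with the inverse curve Y = a − b/X. The curve is linear in (a, b),
so the least-squares problem is solved exactly; standard errors come from
the least-squares covariance with n − 2 df. A fit is adequate when both
parameters are significant at .05 (two-sided). The 90% learning rate is
X = 10·b/a — at that X the fitted curve equals 0.9·a identically — and
the learning day is the first study day whose cumulative completed-session
count reaches ⌈10·b/a⌉. The stable maximal d′ is asymptote plus starting
point. The unsmoothed fit is also available for sensitivity reporting
(`presmoothed=True` fits the series as given).

An identifiability point that shapes the recovery checks: a trajectory
`start + a − b/X` constrains its parameters only through the plateau
(start + a) and the slope b; the start/asymptote split is fixed by the
baselining convention, not by the data. The extracted starting point is a
level estimate (it tracks the participant's plateau ordering at r ≈ 0.98),
so asymptote recovery is assessed with series adjusted at the true
generative baselines, and the raw-scale plateau (stable maximum) is the
end-to-end recoverable quantity.

## Residual covariation

Fluctuations are conditional residuals from each outcome's final model
(selected trend plus retained periodic terms; for mood the trend-only model
when periodic terms fail retention). d-prime residuals are averaged within
day. Daily mood residuals are regressed on same-day residuals of d-prime,
steps (square-root scale) and heart rate (log scale), with participant
random intercepts and AR(1) day-sequence errors. Predictors significant in
the concurrent model are carried into lagged models (previous-day and
next-day), with pairs formed only from consecutive calendar days where both
values exist.

Lag models are fitted unadjusted and adjusted for the same-day predictor;
directionality conclusions use the adjusted variant. The reason is
structural: when a same-day association is present, the AR(1) whitening of
an unadjusted next-day model mixes −φ̂ times the same-day coefficient into
the lagged estimate (the couplings themselves make the mood residuals
serially dependent), so only the adjusted reverse-lag coefficient is null
when no reverse effect exists.

Sensitivity reruns exclude each learner's days strictly before their 90%
learning day (the boundary day is kept as the first at-plateau day;
non-learners contribute everything), and optionally restrict to days with
all three sessions completed.

## The synthetic cohort generator

The generator (`cogflux.simulate`) emulates the study design: 30
participants × 42 days from a Monday onset; three session windows
(morning/afternoon/evening) with uniform jitter; an afternoon mood prompt
whose evening counterpart is delivered only when the afternoon one went
unanswered; daily steps and heart rate with quadratic weekday profiles
(steps lower at the week's onset and end); latent d-prime following
`intercept + a − b/k` over completed assessments k for learners (intercept
only for non-learners) plus a centred quadratic time-of-day term; a subtle
linear mood drift; same-day and previous-day coupling of step fluctuations
to mood and a small coupling of daily cognitive fluctuations to mood;
AR(1)/CAR(1) serial noise per stream; non-wear days (steps under 100 with
heart rate deleted jointly); and session/prompt nonresponse. Every latent
parameter is returned in a ground-truth ledger.

Key defaults and their anchors:

| parameter | default | rationale |
|---|---|---|
| intercept mean/sd | 0.95 / 0.55 | plateau mean 1.95 and range ≈ 0.74–2.93 on the raw d′ scale; most between-person variance sits in baseline ability |
| asymptote mean/sd | 1.0 / 0.20 | learning gain ~1 d′ unit with moderate spread |
| slope mean/sd | 2.2 / 0.5 | 90% learning rate 10·b/a ≈ 22 assessments, range ≈ 13–31 |
| fraction non-learners | 0.1 | ≈ 3 of 30 participants without a practice effect |
| diurnal linear/quadratic | −0.03 / 0.01 per h, h² (centred at 14.5) | convex profile: better performance early and late in the day |
| mood baseline / noise | 7.5 ± 1.5 / 1.0 | mild-moderate symptom range on the 3–12 total |
| step→mood couplings | −0.001 per step (same-day and lag-1) | the printed coefficient scale; negative = more activity, better mood |
| step noise (sqrt scale) | 1.2 (~200 raw steps) | chosen so the implied concurrent coupling strength matches a t-statistic near −4 at ~1,100 days, i.e. the reported effect size; the weekday profile carries the larger (~1,000-step) systematic day-to-day variation |
| d′ serial φ | 0.05 per day | adjacent same-day sessions correlate ≈ 0.55, next-day ≈ 0.05 |
| non-wear / session / prompt missingness | 0.02 / 0.10 / 0.15 | ≈ 25/1,160 non-wear days; realistic nonresponse |

Mood totals are produced by clipping the continuous latent total to
[3, 12] and rounding; items are a deterministic 3-way split of the total.
Two consequences are deliberate and documented: the bounded integer scale
attenuates latent couplings by a few percent (recovery tests therefore
compare against a Monte-Carlo *observable-scale* estimand), and the mood
stream carries rounding grain that makes "zero-noise" residuals bounded by
0.5 rather than 0.

The sessions stream carries the latent (clamped) d-prime directly, so
`noise_sd_dprime` is exactly the measurement noise the trend models see.
The trials stream realizes each session as binary responses whose hit and
false-alarm probabilities are placed symmetrically about the corrected-rate
midpoint and calibrated (by exact enumeration over the two binomials,
cached on a 0.01 latent grid) so that the *expected* bounded score equals
the session's latent value; scoring trials therefore adds binomial
trial-sampling noise on top of the latent stream. The number of 2-back
matches per session is a free parameter (default 9); the stimulus pool
size is recorded but does not affect scoring.

What the generator does not emulate: realistic compliance-by-hour
profiles, device wear-time patterns beyond whole non-wear days,
reaction times, item-level mood response styles, or any treatment effect.
Passing tests demonstrate that the pipeline recovers the structure the
generator encodes at study scale; they do not certify behaviour on real
data with features outside that structure.

## Study-scale checks and the problem sizes used

The acceptance-level suite runs, at the default 30 × 42 scale: parameter
recovery over 100 replicate cohorts (starting points vs true intercepts and
inverse-curve asymptotes vs truth among learners, both r ≥ 0.9 on average;
stable maxima vs true plateaus); cubic-degree selection power over 60
cubic-trend replicates and null selection over 100 flat replicates;
covariation type-I calibration over 200 zero-coupling replicates (pooled
over predictors and lag directions); lag-directionality power over 60
replicates with both step→mood couplings active on a flat background with
white step fluctuations (the configuration in which a reverse lag is
genuinely absent); cleaning-rule exactness on a hand-enumerated fixture;
and bit-reproducibility of the full pipeline. Replicate counts were chosen
to keep the whole suite comfortably inside a half-hour on one CPU while
leaving binomial error well below the asserted margins.

## Known limitations

* The CAR(1) time unit is days; φ is rescalable but a single φ cannot give
  both moderate within-day and moderate between-day correlation.
* ML (not REML) variance components are mildly biased downward at G = 30;
  selection is unaffected (LRTs on nested ML fits) and coefficient
  calibration is handled through the cluster-df convention.
* The learning-period exclusion convention keeps the boundary day; the
  alternative (dropping it) changes kept-day counts by at most one per
  learner.
* Bootstrap CIs for Spearman correlations resample participants with
  replacement; with 27 adequate fits they are adequate but not
  second-order accurate.
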