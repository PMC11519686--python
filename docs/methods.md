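# Methods

`previts` implements a multi-intervention interrupted time series (ITS)
analysis of weekly anxiety/depression prevalence of the kind used to study
how dated public-health events — here, the phased US COVID-19 vaccine
rollout and major pandemic milestones — shifted a population mental-health
indicator.  This note documents the models, the conventions and numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Outcome derivation

The outcome is the CDC BRFSS core item "for how many days during the past
30 days was your mental health not good?" (0–30, with survey dialect codes
88 = none, 77 = don't know, 99 = refused).  Responses are dichotomized at
**≥ 15 days**, the cutoff that tracks the PHQ-4 anxiety/depression screen
at its clinical threshold; 77/99 are treated as missing and dropped
(complete-case analysis), 88 maps to zero days.  Weekly prevalence is the
survey-weighted ratio

    z_t = 100 · Σ_i w_i y_i / Σ_i w_i        (percentage points),

aggregated by ISO week of the interview date.  The cutoff and the week
convention are configurable; the ISO-week assignment (and its truncation
of partial first/last weeks) is a convention of this package and is
recorded in output metadata.  Survey weights are consumed as given — no
raking or calibration is performed — and the weekly point estimates enter
the time-series stage as-is: sampling variance of the weekly proportions
is not propagated into the ITS fit, matching the common practice of
treating the derived series as the data.  Stratified series use the
groupings age 18–64/≥65, female/male, Hispanic/NH-White/NH-Black/NH-other,
household income <$25k / $25–50k / ≥$50k / refused, physically-unhealthy
days 0–13/14–30, and raising-children yes/no/refused; records with
unrecognized levels go to an explicit "unclassified" bucket.

## Intervention design

Eleven dated interruptions (8 vaccine-rollout phases, 3 pandemic-related
events, January 2020 – June 2022) are encoded as binary indicator columns
I_k(t) on the weekly grid.  Because the outcome item asks about the past
30 days, each indicator switches on **4 weeks** (one month) after its
event date; lags of 0/2/6 weeks are exposed for sensitivity analyses.

* Rollout phases form one chronological sequence of **mutually exclusive
  segments**: phase k's column is 1 from its lagged onset up to the lagged
  onset of the next rollout phase, the final phase running to the series
  end.  All eight phases are pooled into a single sequence (3→4→5→6→8→9→
  10→11) rather than split into booster/pediatric tracks.
* Pandemic-related events are coded as **permanent steps** (1 from lagged
  onset onward) — the conventional ITS encoding for a lasting shock; pulse
  and segment codings are available.  Whether such dummies should persist
  to the series end is a modelling assumption, made explicit here.
* Segment boundaries use the *lagged* onset of the following phase, for
  consistency with the lagged starts.

Events whose lagged onset falls outside the observation window yield an
all-zero column (with a logged warning); the estimator reports such
coefficients as NaN rather than failing.

## ARIMA-error ITS estimator

The estimating equation is

    z_t = c·t + Σ_k ω_k I_k(t) + η_t,     η_t ~ ARIMA(p, d, q),

a regression with ARIMA errors (static transfer functions; no rational
dynamics).  With d = 1 the trend "constant" c is the drift of the
differenced equation — a linear slope in levels; with d = 0 it is the
intercept.  Estimation differences z and the design columns d times, then
maximizes the exact Gaussian likelihood: for fixed ARMA parameters the
error covariance is the stationary ARMA autocovariance Toeplitz matrix;
Cholesky whitening reduces the problem to least squares, concentrating
out β = (c, ω) and σ² in closed form, and the resulting profile objective
is maximized over the ≤ p+q ARMA parameters (bounded scalar search for
one parameter, Nelder–Mead with a white-noise restart otherwise;
parameter tolerance 1e-8; stationarity/invertibility enforced through the
companion-root check).  Hannan–Rissanen estimates on the OLS residuals
provide warm starts.  For p = q = 0 the fit is closed-form least squares.
The implementation is validated in the test suite against the independent
state-space ML estimator in statsmodels on a fixture series.

**ARMA nuisance estimation and uncertainty.**  By default the ARMA
parameters are estimated on the *restricted* (REML) profile likelihood,
which corrects the well-known downward bias of ML variance/correlation
estimates when 12–13 regression coefficients are absorbed; plain ML is
available via `method="ml"`.  Standard errors for the regression block use
the GLS covariance (X'Σ⁻¹X)⁻¹ at the fitted ARMA parameters with (i) a
residual-degrees-of-freedom correction of σ̂², (ii) an additive two-stage
allowance J V_ψ J' for the uncertainty of the ARMA parameters themselves
(J = ∂β̂/∂ψ by central differences, V_ψ from the curvature of the profile
objective), and (iii) Student-t critical values.  In Monte-Carlo
experiments under the correctly specified main-model scenario this
combination brings empirical 95%-CI coverage to ≈ 94–95% where the naive
plug-in GLS interval covers ≈ 92–93%; two-sided p-values at the 5% level
reject at ≈ 5% under the null.  CIs are reported at 95% with two-tailed
p-values and no multiple-testing correction, matching the conventions of
the applied ITS literature this package follows.

**Diagnostics.**  BIC = −2·loglik + k·ln(n_eff) with k counting ARMA
terms, regression terms and the innovation variance, n_eff = n − d.
Ljung–Box Q = n(n+2) Σ_{k≤m} ρ̂_k²/(n−k) on the whitened residuals,
default m = 18 lags (a common weekly-data choice; configurable), referred
to χ² with m minus the fitted ARMA parameter count (floor 1) degrees of
freedom.  Stationary R² = 1 − Σê²/Σ(Δᵈz − mean)², i.e. variance of the
differenced series explained relative to its mean — the mean baseline is
used because the trend-adjusted alternative is not uniquely defined for
this statistic.  Residual ACF (sample) and PACF (Durbin–Levinson) come
with ±1.96/√n white-noise bands.  `select_order` fits a candidate grid
and returns the minimum-BIC order among converged fits whose Ljung–Box
p-value exceeds 0.05 (ties broken by smaller p+q); if none passes, the
minimum-BIC fit is returned with a flagged warning.

**Missing weeks** abort the fit by default; optional linear interpolation
is applied with a recorded message.

## Recovery harness

`recovery_study` simulates R series from a scenario (independent
sub-seeds drawn from a seed sequence), refits the estimator, and reports
per effect: Monte-Carlo mean, bias, empirical SD, RMSE, 95%-CI coverage
of the injected truth, and the rejection rate at two-sided p < 0.05
(the type-I error rate when the injected effect is zero).  Replicate
failures are counted, never fatal.  The acceptance checks inject the
reference effect magnitudes (−0.93, −1.28, −0.89 pp at the
total-population scale; +2.26, +3.95, +2.68 pp at stratum scales) as
ground truth and require the Monte-Carlo mean to match within three
Monte-Carlo standard errors at 500 replicates, and CI coverage/type-I
error to sit within 2 pp of nominal at 1000 replicates.

## LSTM mean–variance forecaster

A sliding-window sequence-to-one recurrent model reads `window = 12`
weeks of features — the prevalence value plus the 11 binary intervention
indicators — and predicts the next week's prevalence as a Gaussian.  One
LSTM layer (hidden size 32 by default) feeds two parallel linear heads;
the variance head passes through Softplus(x) = log(1+eˣ) so σ² > 0 (with
a 1e-6 floor), and σ = √σ².  Training minimizes the mean Gaussian
negative log-likelihood ½log(2πσ²) + (y−μ)²/(2σ²) with Adam at learning
rate 0.001 for 10 epochs by default; per-epoch train/test MSE curves (on
the raw prevalence scale) support epoch selection.  The implementation is
pure NumPy with hand-written backpropagation through time; analytic
gradients are checked against finite differences to 1e-5 in the tests,
and training is exactly reproducible under a fixed seed.

Conventions where the underlying design is open: chronological 80/20
train/test split (random splitting would leak future weeks into
training); the prevalence feature and targets standardized by train-split
mean/SD with predictions de-standardized before reporting; one full pass
per epoch over the training windows in seeded random order with updates
every 4 windows (small batches give the fixed 10-epoch budget enough
update steps to fit the mean head); the Softplus head emits the
*variance*.  95% predictive intervals are μ_t ± 1.96·σ_t.

The "mean-predictor" baseline used in the sanity checks is the
**train-mean (climatology) forecaster** — predicting the training-split
mean for every test week — the standard reference forecaster computable
without test labels.  On trending series the recurrent network must
extrapolate beyond its standardized training range, where saturating
activations compress predictions; it beats the climatology baseline by a
wide margin there, but a reader should not expect near-zero test error on
strongly trending data.  On stationary noisy series the predictive
intervals are well calibrated (coverage within ±5 pp of nominal at ~200
held-out points in the tests).

## Synthetic-data generator

The generator defines the study conditions for every test:

    z_t = baseline + drift·t + Σ_k δ_k I_k(t) + u_t,

with u_t ARMA(1,1) innovations (σ_ε), optionally integrated once (d = 1,
the default, mirroring an ARIMA(0,1,1) outcome process with default
θ = 0.5 — the main-model structure; no usable reference point estimate
exists for this coefficient, so θ = 0.5 is a package choice).  The default
grid is 217 ISO weeks, 2019-W01 through 2023-W08; the default
total-population scale uses baseline 12 pp and drift 0.034 pp/week (the
reference trend constant), σ_ε = 0.5; stratum-scale scenarios use the
reference stratum baselines (13.9 / 20.8 / 11.9 pp) with d = 0 noise, and
ARMA(1,1) parameters φ = −0.5, θ = −0.4 where a stratum's reference ARMA
pair is too close to a cancelling (unidentified) configuration to use
directly.  Closed-form ARMA(≤1,≤1) moments (`theoretical_moments`) serve
as oracles: γ₀ = σ²(1+θ²+2φθ)/(1−φ²), γ₁ = σ²(1+φθ)(φ+θ)/(1−φ²).  d = 0
noise is started in its stationary regime via a 300-draw burn-in.

Microdata generation draws, per week, a configurable number of
respondents with log-normal(0, 0.5) survey weights, stratum labels from
fixed population shares, and a days response whose exceedance probability
P(days ≥ cutoff) equals the week's target prevalence shifted per stratum
(shifts centred so the mixture matches the target); below-cutoff days are
zero-inflated (mass at code 88), don't-know/refused codes appear at a 2%
default rate.  The weekly respondent count is a plumbing choice — the
real survey's weekly sample-size distribution is not modelled — and the
weight law is a convenience: no raking, no landline/cell frames, no
geography.  Consequently, passing tests demonstrate the *estimators'*
statistical properties under the assumed generating model, not robustness
to real BRFSS complexities (design effects, weight trimming, seasonal
interviewing patterns).

Simulated series are Gaussian and therefore unbounded; the [0, 100]
prevalence bound is enforced only on survey-derived series.

## Problem sizes

The acceptance computations use the study's own scale throughout: 217
weeks, the full 11-event lagged design, 500 replicates per recovery
target and 1000 for the calibration targets.  A recovery study of 500
replicates fits in well under a minute per target on a single CPU with
the profile-GLS estimator; LSTM calibration checks use a 1012-week
stationary series so that the test partition holds ~200 points.

## Known limitations

* The estimator treats the weekly series as observed without sampling
  error; strata with few respondents per week violate this more strongly.
* CI coverage rests on the Gaussian ARMA error model; the two-stage
  variance allowance is a first-order correction, and coverage of effects
  identified by very short segments remains ~1 pp below nominal.
* The LSTM is a single-series model; no hyper-parameter search is
  performed beyond the epoch-selection curves; real-data error magnitudes
  from other analyses are not reproduced here because they depend on
  unstated split details of those series.
* Seasonal ARIMA terms, GARCH innovations and state-space structural
  models are out of scope.
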