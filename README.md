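# previts

**Multi-intervention interrupted time series analysis of weekly survey
prevalence** — for epidemiologists and biostatisticians studying how dated
public-health events (vaccine rollout phases, pandemic milestones, policy
changes) shifted a population-level mental-health indicator derived from
survey microdata.

The package covers the full pipeline:

1. **Outcome derivation** — binarize the BRFSS core "mentally unhealthy
   days" item at the ≥15-day cutoff (the dichotomization that tracks a
   PHQ-4 anxiety/depression screen) and aggregate to survey-weighted
   weekly prevalence `z_t = 100·Σwᵢyᵢ/Σwᵢ`, overall and by stratum
   (age, sex, race/ethnicity, income, physical health, raising children).
2. **Intervention design** — encode a built-in calendar of 11 dated
   interruptions (8 vaccine-rollout phases as mutually exclusive
   chronological segments, 3 pandemic events as permanent steps), each
   switching on 4 weeks after its event date.
3. **ARIMA-error ITS estimation** — fit

       z_t = c·t + Σ_k ω_k I_k(t) + η_t,   η_t ~ ARIMA(p,d,q)

   by exact Gaussian maximum likelihood (regression coefficients and the
   innovation variance concentrated out by whitened GLS; REML estimation
   of the ARMA nuisance parameters), with 95% CIs, two-tailed p-values,
   and the standard diagnostics: BIC, Ljung–Box Q, Stationary R²,
   residual ACF/PACF, plus BIC-based order selection.
4. **LSTM distributional forecasting** — a sliding-window (12 weeks)
   recurrent network over the prevalence value and the intervention
   indicators, with two linear heads predicting the mean and (through a
   Softplus) the variance, trained with the Gaussian negative
   log-likelihood ½log(2πσ²)+(y−μ)²/(2σ²) by Adam (lr 0.001, 10 epochs);
   95% predictive intervals μ_t ± 1.96·σ_t.  Implemented in pure NumPy
   with hand-written, finite-difference-verified backpropagation.
5. **Synthetic data** — a seeded generator for weekly series (drift +
   lagged step effects + ARIMA noise) and BRFSS-style respondent
   microdata whose weighted aggregation tracks a target series, so every
   stage is testable without any data download.
6. **Monte-Carlo harness** — parameter-recovery studies reporting bias,
   RMSE, CI coverage and type-I error for the ITS estimator.

See `docs/methods.md` for the full model documentation and conventions.

## Worked example

Simulate a 217-week series (ISO weeks 2019-W01…2023-W08) at the
main-model scale — drift 0.034 pp/week, integrated MA(1) noise — with
reductions injected on two rollout phases, and refit it:

```python
import previts as pv

sc = pv.Scenario(baseline=12.0, drift=0.034, ma_theta=0.5, innovation_sd=0.5,
                 d=1, effects={4: -0.93, 10: -1.28}, seed=11)
series = pv.simulate_weekly_series(sc)
fit = pv.fit_its(series, sc.design(), order=(0, 1, 1))
print(fit.summary())
```

```
ARIMA(0,1,1) ITS fit  n_eff=216  loglik=-159.666  BIC=394.59
Ljung-Box Q=19.19 (p=0.318)  Stationary R2=0.185
    term  estimate      se  ci_lower  ci_upper  p_value
constant    0.0664  0.0518   -0.0358    0.1686   0.2016
   evt01    0.5776  0.4835   -0.3756    1.5309   0.2336
   evt02    0.1982  0.4731   -0.7346    1.1310   0.6757
   evt03   -0.1923  0.4683   -1.1156    0.7310   0.6818
   evt04   -0.7548  0.6632   -2.0624    0.5528   0.2564
   evt05    0.0750  0.8148   -1.5316    1.6815   0.9268
   evt06   -0.2542  0.9640   -2.1550    1.6466   0.7923
   evt07    0.0427  0.4691   -0.8823    0.9676   0.9276
   evt08    0.2881  1.0811   -1.8436    2.4198   0.7901
   evt09    0.0907  1.1792   -2.2343    2.4156   0.9388
   evt10   -0.9287  1.2867   -3.4656    1.6083   0.4713
   evt11   -0.2186  1.3769   -2.9334    2.4962   0.8740
     ma1    0.4451     NaN       NaN       NaN      NaN
```

The `constant` row is the weekly trend in levels (truth 0.034 pp/week
here), `evt04`/`evt10` recover the injected −0.93 and −1.28 pp level
shifts up to sampling noise (single-replicate SEs of 0.66 and 1.29 pp —
averaged over 500 replicates the estimator is unbiased; see
`recovery_study`), `ma1` is the moving-average coefficient of the
differenced noise, and the non-significant Ljung–Box Q says the model
residuals look like white noise.

The same pipeline runs end-to-end from the command line:

```bash
previts run-all --seed 11 --out results_dir        # simulate → fit → report
previts derive microdata.csv --out weekly.csv      # microdata → weekly series
previts fit-arima weekly.csv --order 0,1,1
previts fit-lstm weekly.csv --seed 1
previts recovery --seed 1 --reps 200 --effect 4=-0.93
```

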