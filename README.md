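# nof1steps

Analysis pipeline for personalized (N-of-1) crossover trials with a
minute-level wearable step-count outcome. A trial consists of a 2-week
baseline followed by six 2-week treatment blocks (yoga, massage, usual
care), with participants randomized 1:1 between two position-balanced block
sequences. The package covers the full chain:

1. **simulate** — synthetic Fitbit-like cohorts with a diurnal Poisson
   minute intensity, weekday/temperature covariate effects, additive
   day-level treatment effects, AR(1) day-to-day noise, and the device
   missingness mechanism (non-wear minutes record step count 0 and no heart
   rate). Ground truth is retained for testing, never consumed by analysis.
2. **ingest** — CSV readers, wear classification (WORN / CARRIED /
   MISSING from the heart-rate-presence and step-count pair), day-level
   wear fractions and the baseline adherence filter (≥ 11 of 14 days at
   ≥ 80% wear).
3. **impute** — per-minute Poisson log-linear fits (intercept, weekday,
   temperature) on complete data with hour/day pooled fallbacks, model-based
   filling of MISSING minutes, penalized cubic-spline smoothing of imputed
   stretches, and aggregation to daily totals.
4. **effects** — feasible generalized least squares under AR(1) errors
   (iterated lag-1 residual autocorrelation + Cholesky whitening), three
   treatment contrasts with t-based 95% CIs, and CI-based classification
   into POSITIVE / NEGATIVE / NO_EFFECT.
5. **report** — fixed-effect inverse-variance pooling, forest-plot data,
   per-contrast label counts, and a static HTML report (effects tables,
   forest panels, line graphs, boxplots) per participant plus a cohort page.

## CLI

```sh
nof1steps simulate --config cfg.yaml --out data/ --seed 1
nof1steps impute   --minutes data/minutes.csv --covariates data/covariates.csv \
                   --design cfg.yaml --sequences data/sequences.csv --out data/
nof1steps analyze  --daily data/daily.csv --design cfg.yaml --out data/effects.csv
nof1steps report   --effects data/effects.csv --daily data/daily.csv --out data/report/
nof1steps run      --config cfg.yaml --out data/ --seed 1   # all of the above
```

All commands work without a config file (package defaults: 26 participants,
14-day baseline, 14-day blocks). A config YAML may contain `design`,
`simulation`, `analysis` and `n_participants` sections; see
`nof1steps/config.py` for the recognized keys. `nof1steps impute
--no-impute` produces zero-filled daily totals for comparison with the
imputed analysis.

## File formats

- minute CSV: `participant_id,date,minute,steps,heart_rate` (minute
  0–1439; empty heart-rate field = absent, i.e. non-wear),
- covariate CSV: `date,temperature_f` (weekday is derived from the date),
- daily series CSV: `participant_id,day_index,block,total_steps,
  fraction_imputed,weekday,temperature_f`,
- effects CSV: `participant_id,contrast,beta_hat,se,ci_low,ci_high,label,
  rho_hat,n_days,converged`.

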