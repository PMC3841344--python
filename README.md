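# timeoutmi

Exposure-time analysis for online behavioral interventions whose loggers
censor long page views with an inactivity time-out.

When a web program logs a participant out after a fixed period of
inactivity (commonly 30 minutes), the close stamp of that page view is
the forced logout, not the end of reading — the true viewing time is
missing. Excluding those views is a complete-case analysis; assigning an
arbitrary constant (0 or the threshold) is a single uninformed
imputation. Both can bias engagement conclusions. This package treats
timed-out views as missing data and handles them properly:

1. **`weblog`** — parse time-stamped navigation event logs into per-page
   viewing durations; flag views whose elapsed time reaches the
   threshold (default 30 min) as timed-out/missing.
2. **`mice`** — arrange the data in wide format (one row per
   participant, one column per successive page view) and multiply
   impute the missing durations by chained equations: per-position
   normal linear regressions on log duration with proper
   (parameter + residual) posterior draws; sparse tail positions share
   a pooled model.
3. **`zipmodel`** — fit a zero-inflated Poisson model to total rounded
   minutes (never-access participants are the excess zeros); the
   exponentiated arm coefficient is the between-arm ratio of mean
   minutes online.
4. **`pooling`** — combine the per-imputation estimates and standard
   errors with Rubin's rules.
5. **`sensitivity`** — the end-to-end comparison: constant-assignment
   analyses over a grid from near zero to the threshold versus the
   multiple-imputation analysis.
6. **`simulate`** — a synthetic cohort generator (participant table,
   event log, ground-truth durations) calibrated so that desk-scale
   runs resemble a realistic trial: ~37% never access, right-skewed
   page views with median ~1 minute, ~10% of views censored. Missing
   at random by construction, with an optional switch to informative
   missingness for stress tests.
7. **`reporting`** — cohort summary reports, the observed-duration
   histogram, and the sensitivity figure, with percentages printed to
   two decimals (half-up).

## Command line

```sh
# generate a synthetic cohort
timeoutmi simulate --n 1000 --seed 1 --out-dir run/sim

# parse the event log into viewing records (+ summary)
timeoutmi parse --events run/sim/events.csv --out-dir run/parsed

# multiply impute timed-out durations (M datasets + manifest)
timeoutmi impute --records run/parsed/records.csv \
    --participants run/sim/participants.csv --m 5 --iterations 10 \
    --seed 1 --out-dir run/imputed

# full MI analysis with Rubin pooling of the arm effect
timeoutmi analyze --records run/parsed/records.csv \
    --participants run/sim/participants.csv --seed 1 --out-dir run/mi

# constant-assignment sensitivity grid (table + figure)
timeoutmi sensitivity --records run/parsed/records.csv \
    --participants run/sim/participants.csv --out-dir run/sens

# cohort-level summary report + duration histogram
timeoutmi report --events run/sim/events.csv \
    --participants run/sim/participants.csv --out-dir run/report
```

Simulation parameters can also come from a flat `key = value` config
file (`--config`), with `--set key=value` overrides.

## Notes

- All deliverable I/O is plain text (CSV, JSON, key=value); figures are
  PNG.
- Every random step takes an explicit seed; identical seeds give
  byte-identical outputs end-to-end.
- Imputed durations are not truncated at the time-out threshold by
  default; `--truncate-at` / `truncate_at=` enables an upper bound.
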