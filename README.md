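# neorisk

In-hospital mortality risk scoring for very-low-birth-weight (VLBW)
neonates. The package implements, as a tested pipeline:

- **Published equation scoring** (`neorisk.models`) — the four logistic
  equations (prenatal `M1`, first-24-hours `M2`, and the during-admission
  pair `M3_early`/`M3_late` stratified at day 30 of life), shipped as a
  versioned data file with their coefficients, standard errors, printed
  odds ratios/CIs, Kappa-optimal cut points and FNR-derived severity
  bands. Scoring computes the linear predictor `z`, the death probability
  `1/(1+e^-z)` and the four-level severity category (mild / moderate /
  severe / very severe).
- **Synthetic cohort generation** (`neorisk.cohort`) — SEN1500-like
  cohorts with configurable marginal prevalences, a truncated-normal
  gestational-age distribution, diagnosis flags with severity sub-flags,
  and an outcome drawn from a *known* logistic mechanism (any model spec),
  so every downstream stage can be checked against ground truth.
- **Development stage** (`neorisk.development`) — univariable preselection
  (chi-square / Mann-Whitney at p < 0.15), the pseudo-evolution expansion
  of each record over standardized days {1, 3, 8, 15, 22, 31, 46, 61}
  with diagnosis time-window gating (RDS days 0–7, NEC 14–45, IVH 0–10,
  PVL > 21, BPD > 28), maximum-likelihood logistic fitting including the
  day-30 stratified dynamic model, Kappa-optimal cutoff search and
  FNR-based severity band derivation.
- **Validation stage** (`neorisk.evaluation`) — AUC with DeLong CI, Brier
  score, Cohen Kappa with strength labels, accuracy at a fixed cutoff,
  Hosmer-Lemeshow calibration, Nagelkerke R², and the real-time per-day
  scoring scenario (days 1, 8, 15, 31, 61).
- **Interface** (`neorisk.io`, `neorisk.pipeline`, `neorisk.cli`) —
  validated CSV cohort I/O, deterministic end-to-end orchestration with
  seed/config-hash stamped artifacts, and a CLI.

## CLI

```bash
# generate a synthetic cohort
neorisk simulate --n 2000 --seed 1 --out cohort.csv

# score a patient CSV with the prenatal model
neorisk predict --cohort cohort.csv --model M1 --out scored.csv

# during-admission model at a given day of life (routes at day 30)
neorisk predict --cohort cohort.csv --model M3 --day 15 --out scored.csv

# development stage: refit equations, cutoffs and severity bands
neorisk develop --cohort cohort.csv --out dev_artifacts/

# validation stage against published or freshly developed models
neorisk validate --cohort holdout.csv --models dev_artifacts/development.json \
    --bands derived --out val_artifacts/

# full deterministic pipeline (simulate -> develop -> validate)
neorisk run --seed 1 --out run_artifacts/
neorisk report --artifacts run_artifacts/
```

All commands accept `--help`. Cohort CSVs are UTF-8, comma-separated,
0/1 booleans, lowercase enum tokens; see `neorisk.io.COHORT_COLUMNS` for
the data dictionary.

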