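# breath2plasma

Pipeline linking exhaled drug concentration (gas phase, ppbv) to plasma
concentration (μg/mL) in small-animal bolus studies:

- **calibration** — quadratic signal↔concentration curve fitting and
  inversion with LOD/LOQ bookkeeping (`fit_calibration`,
  `signal_to_concentration`, `convert_units`);
- **pk_core** — closed-form 1/2/3-compartment models, micro↔macro constant
  conversion, least-squares fitting with curve-stripping start values,
  AIC model selection, and derived parameters (half-lives, CL, AUC);
- **preprocessing** — LOD censoring (zeroed before the observed peak,
  excluded at/after it) and nearest-time pairing of the breath grid with the
  sparse plasma schedule;
- **agreement** — Spearman correlation, pooled/per-group OLS of
  LN(plasma ng/mL) on LN(breath pptv), breath→plasma prediction, ICC(2,1)
  absolute agreement with Bland-Altman limits, ANOVA and paired t-tests;
- **synthetic_data** — seeded synthetic cohorts with the 3-group × 6-subject
  design (6/12/24 mg/kg), lognormal inter-individual variability, a
  configurable power-law breath–plasma link, measurement noise and LOD
  censoring, emitted with full ground truth;
- **pipeline_cli** — CSV I/O, orchestration and report generation.

## CLI

```bash
# generate a synthetic cohort (series.csv, subjects.csv, ground_truth.json)
breath2plasma simulate --seed 1 --out runs/sim

# fit the calibration curve from a standards CSV (concentration_ppbv, signal_intensity)
breath2plasma calibrate --standards standards.csv --out curve.json

# full pipeline: censor -> fit PK -> group summary -> regression -> ICC/Bland-Altman
breath2plasma report --series runs/sim/series.csv --subjects runs/sim/subjects.csv \
    --out runs/report

# predict plasma (ng/mL) from breath (pptv) with the fitted pooled model
breath2plasma predict --model runs/report/report.json --ce 5870
```

`fit-pk` and `agree` run the corresponding pipeline stages with the same
options. Series CSVs have exactly the columns
`subject_id, group, matrix, time_min, concentration, unit, censor_flag`;
doses travel in the subjects CSV (`subject_id, group, dose_mg, body_mass_g`).
Exit codes: 2 for schema violations, 3 if every fit fails.

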