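# ckd-labscan

A laboratory-database pipeline for chronic kidney disease (CKD) assessment:
from a flat table of outpatient lab records to per-patient index
assessments (eGFR, predicted ACR, KDIGO staging, CKD and diabetes flags,
requesting specialty) and stage-stratified Kaplan-Meier curves of repeat
creatinine testing — plus a seeded synthetic lab-record generator so the
whole pipeline is testable without any proprietary data.

## What it computes

- **eGFR** from serum creatinine, age and sex via the 2021 race-free
  CKD-EPI equation (`kidney_markers`).
- **Predicted ACR (pACR)** from any of three urinary modalities:
  quantitative ACR (passthrough), quantitative protein-to-creatinine ratio
  (clamped log-linear crosswalk), or semi-quantitative dipstick grades
  (indicator crosswalk) (`kidney_markers`).
- **KDIGO classification**: G stages G1–G5, albuminuria categories A1–A3,
  the 18-cell risk heatmap, and a CKD flag (eGFR < 60, or A2/A3 at
  higher eGFR) (`staging`).
- **Cohort construction**: outpatient/adult/study-window filtering with
  full flow accounting, first-creatinine index selection, nearest urinary
  pairing within ±365 days, lab-based diabetes flagging (HbA1c > 6.5 % or
  glucose > 200 mg/dL within ±365 days) (`cohort_builder`).
- **Retest incidence**: one minus the Kaplan-Meier survival function of
  time to the first repeat creatinine, with administrative censoring at
  study end, stratified by G stage (`followup_km`).
- **Synthetic cohorts** with a configurable latent structure — stage
  mixture, per-stage pairing odds, A3 rates, exponential retest hazards,
  specialty mixes, CKD-dependent demographics — that the pipeline must
  recover (`synthetic_data`).
- **Reports**: KDIGO cross-tab, pairing and A3 fractions per stage,
  specialty shares, KM summaries, all as stable JSON/CSV (`reporting`).

## CLI

```sh
# generate a synthetic lab-record CSV (plus optional latent-truth sidecar)
ckd-labscan simulate --out records.csv --seed 1 --n 50000 --truth-out truth.json

# run the full pipeline; writes assessments.csv, flow.json, summary.json, km_G*.csv
ckd-labscan run --in records.csv --out outdir/

# KM curves only (optionally conditioned on an observed retest, or plotted)
ckd-labscan km --in records.csv --out kmdir/ --plot

# one-command default-configuration round trip
ckd-labscan reproduce --seed 1 --n 200000 --out summary.json
```

Pipeline and generator settings are plain YAML mirroring
`ckd_labscan.PipelineConfig` and `ckd_labscan.GeneratorConfig`; pass them
with `--config`.

## Layout

```
src/ckd_labscan/
  kidney_markers.py   eGFR + pACR conversions, unit normalization
  staging.py          G/A bands, CKD flag, KDIGO heatmap
  cohort_builder.py   CSV dialect, filters, index/pairing/diabetes logic
  followup_km.py      product-limit cumulative incidence
  synthetic_data.py   seeded generator + eGFR inverter
  reporting.py        summaries, JSON schema, pipeline composition
  cli.py              click entry points
```
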