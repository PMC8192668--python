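# sirtdose

Planning dosimetry and dose-response analysis for Y-90 selective internal
radiation therapy (SIRT) with glass microspheres.

The package implements:

- **MIRD non-penetrating dose arithmetic** (`sirtdose.dosimetry`) — the
  single-compartment ("standard") prescription to the perfused lobe and the
  two-compartment ("partition") prescription splitting activity between a
  pooled tumor compartment and normal liver via the tumor-to-normal uptake
  ratio (TNR), with lung shunt correction.
- **Dose-response models** (`sirtdose.response`) — a logit tumor control
  probability (TCP) curve with maximum-likelihood fitting, and a
  whole-liver tolerance-dose NTCP model (killed lobule fraction,
  microsphere-spacing factor) with robust numerical inversion.
- **Recovery-coefficient partial-volume correction** (`sirtdose.recovery`)
  — a saturating RC-vs-volume curve fitted to phantom sphere measurements,
  applied to mean uptake values.
- **Prescription parameterization** (`sirtdose.parameterization`) — the
  chart of mean per-lesion change in TCP over every (standard dose ×
  partition dose) combination, the equal-TCP equivalence line, per-lesion
  delta-TCP histograms, and volume-stratified planning-vs-delivered
  concordance.
- **NTCP-limited planning** (`sirtdose.ntcp_planning`) — the whole-liver
  dose at a target complication probability (default 15%) compared against
  a 120 Gy standard plan, restricted to treatments targeting > 40% of the
  liver.
- **Synthetic cohorts** (`sirtdose.cohort`) — seeded generation of
  treatment populations (≈35 patients / ≈39 treatments / ≈120 lesions)
  with volume-dependent planning-vs-delivered discordance, so the whole
  pipeline runs without any patient data.
- **I/O and CLI** (`sirtdose.io`, `sirtdose.cli`) — a versioned cohort
  schema (CSV and JSON), a reproducible pipeline driver, and a `sirtdose`
  command-line tool.

## CLI

```bash
# generate a synthetic cohort
sirtdose simulate --seed 1 --out cohort.csv

# individual analyses
sirtdose chart --cohort cohort.csv --out chart.csv
sirtdose histogram --cohort cohort.csv --sm-dose 120 --pm-dose 75
sirtdose equivalence --cohort cohort.csv
sirtdose ntcp --cohort cohort.csv
sirtdose concordance --cohort cohort.csv

# full pipeline: all CSVs, heatmap/histogram PNGs, and a run manifest
sirtdose all --seed 1 --out-dir out/
```

TCP curve parameters (`--tcp-midpoint`, `--tcp-slope`) default to a
documented placeholder logit (midpoint 150 Gy, slope 50 Gy); supply your
institutional fit for real analyses. Microsphere specific activity is a
required per-treatment input for NTCP planning — no default is assumed.

## Cohort schema

CSV files start with the line `# sirtdose-cohort-v1` and carry one lesion
per row with the treatment-level columns repeated (masses in kg, doses in
Gy, activities in GBq, volumes in ml, dose-per-activity in Gy/GBq). The
equivalent nested JSON uses `{"schema_version": 1, "treatments": [...]}`.
`sirtdose simulate --out cohort.json` writes the JSON form.
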