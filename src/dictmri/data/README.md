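# Bundled staging fixtures

Transcribed contingency tables from a published colorectal-cancer staging
study (rows = imaging-assigned T stage, columns = pathological T stage):

- `table_mr_staging.csv` — MR staging vs pathology, 146 patients
  (pathology margins 41 / 58 / 47; imaging margins 55 / 56 / 35).
- `table_ct_staging.csv` — CT staging vs pathology, 98 patients
  (pathology margins 36 / 37 / 25; imaging margins 41 / 34 / 23).
- `cohort_demographics.csv` — per-stage sex counts of the MR cohort.
  Note: these rows sum to 88 men / 58 women, while the study's narrative
  text reports 86 / 60; the tabulated counts are kept as printed.

The source report's printed specificity and coincidence denominators are
not derivable from these counts; `dictmri.staging` recomputes every metric
from the raw table with the standard definitions.
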