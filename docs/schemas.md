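# Table schemas

All tables are plain CSV-compatible pandas DataFrames. Columns listed here
are the contract between the synthetic generator, any external data source,
and the pipeline readers.

## Cohort (person-level)

| column | type | meaning |
|---|---|---|
| `id` | int | subject identifier, unique |
| `age_at_index` | float | age in years at the index date (≥ 18 after eligibility) |
| `sex` | `M`/`F` | |
| `index_year`, `index_month` | int | calendar month of the index date |
| `modality` | `HD`/`PD` | assigned dialysis modality (constant per subject) |
| `time` | float | months from index to death/censoring (continuous) |
| `event` | `death`/`censored` | |
| `urbanization` | {0,1,2} | rural / satellite / metropolitan |
| `diabetes` … `rheumatologic` | 0/1 | eleven comorbidity flags (see `dialcea.COVARIATES`) |
| `dialysis_months` | float | consecutive months on the assigned modality |
| `switch_months` | float | longest sustained spell on the other modality |
| `malignancy` | bool | any malignancy record |
| `prior_transplant` | bool | transplanted before dialysis |
| `transplant_month` | float/NaN | months from index to transplantation, if any |
| `censored_at_transplant` | bool | added by `apply_eligibility` |

## Claims

| column | type | meaning |
|---|---|---|
| `id` | int | subject id (must exist in the cohort) |
| `date` | date | claim date |
| `setting` | `inpatient`/`ambulatory` | |
| `code` | str | diagnosis code; matched by string prefix against the code map |

## Monthly cost records

| column | type | meaning |
|---|---|---|
| `id` | int | subject id |
| `month` | int | months since index, 1-based; only alive months appear |
| `outpatient`, `inpatient` | float | cost that month, nominal currency |
| `year` | int | calendar year of the month (for CPI adjustment) |

## EQ-5D survey records

| column | type | meaning |
|---|---|---|
| `id` | int | respondent id |
| `modality` | `HD`/`PD` | |
| `vintage` | int | months on dialysis at interview |
| `age`, `sex` | float, `M`/`F` | matching covariates |
| `diabetes`, `stroke`, … | 0/1 | matching covariates (configurable) |
| `mobility`, `self_care`, `usual_activities`, `pain_discomfort`, `anxiety_depression` | {1,2,3} | EQ-5D-3L domain levels |
| `utility` | float | tariff score of the profile |
| `vas` | int | visual analogue scale, 0–100 |

## Life table

| column | type | meaning |
|---|---|---|
| `age` | int | 0–110, every age present once per sex |
| `sex` | `M`/`F` | |
| `hazard` | float | monthly mortality hazard, ≥ 0 |

## Value set (YAML)

See `src/dialcea/data/value_set_template.yaml`: `name`,
`any_dysfunction_constant`, `extreme_level_constant`, and `decrements` with
levels 2 and 3 for each of the five dimensions.

## Comorbidity code map (YAML)

Mapping `comorbidity name -> list of code prefixes`; see
`src/dialcea/data/toy_code_map.yaml`.

## Curves (CSV round-trip)

* Survival: `month`, `survival` (`SurvivalCurve.to_frame`/`from_frame`)
* Utility: `month`, `utility`
* Cost: `month`, `inpatient`, `outpatient`, `total`, `outpatient_share`
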