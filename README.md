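# cohortforge

An offline, scriptable cohort-identification and surveillance-reporting
engine for longitudinal patient-level EHR tables, written for
pharmacoepidemiologists and clinical researchers who want hospital-style
"clinical surveillance" queries — reusable code-set templates, declarative
inclusion/exclusion criteria, hierarchical patient lists with full
attrition provenance, and standard report views — without a data warehouse
or a web stack.

The package ships a complete worked example: the *osteoporotic-fracture
treatment gap*. Guidelines recommend anti-osteoporosis medication (AOM)
after a hip or vertebral fracture, yet a large share of eligible patients
is never treated. The example identifies incident fracture patients with a
new-user design and measures how many start an AOM within a year.

## The cohort model

An *identification spec* is executed in two stages over three flat tables
(`patients.csv`, `events.csv`, `encounters.csv`):

1. **Index.** For each patient, the index date is the earliest diagnosis
   inside the observation window `[t₀, t₁]` that matches a diagnosis
   template (a named set of ICD-9 code patterns: exact codes, 3-character
   category prefixes such as `820`, or inclusive category ranges such as
   `140–208`). An optional *first-ever washout* drops patients with any
   matching diagnosis before `t₀`.
2. **Criteria.** Ordered steps restrict the indexed set. Each step either
   requires or forbids a matching event/encounter inside an inclusive
   day-offset window relative to index — a 1-year lookback is `[−365, −1]`,
   1-year treatment ascertainment is `[+1, +365]` — or imposes a minimum
   age in completed years. Index-day events (offset 0) belong to neither
   lookback nor follow-up. Attrition is attributed sequentially: a patient
   excludable by several criteria is counted under the first one, so step
   counts are disjoint and conserve the index count.

Every run yields a `PatientList` (case number, members with index dates,
attrition record, query cost) stored in a `DataMart`; later specs can name
a stored list as their source population, producing a traceable hierarchy
of nested cohorts. Three report views summarise any list: descriptive
characteristics (mean ± SD, level counts with percentages), calendar-bucketed
incidence/proportion trends (monthly, quarterly, yearly; optionally
stratified by sex or fracture type), and the root-to-leaf attrition table.

Synthetic data comes in two flavours: a *fixture* mode that constructs one
patient category per cohort-flow branch so the pipeline reproduces chosen
attrition counts exactly, and a stochastic *population* mode with stated
distributions for parameter-recovery tests.

## Worked example

The packaged study (`cohortforge/data/fracture_study.yaml`) runs three
chained identifications over 2010–2014: incident hip/vertebral fracture
patients aged 50+ with no malignancy (ICD-9 140–208), no osteoporotic
fracture (820, 805, 806), no Paget disease (731.0) and no AOM dispensing in
the year before index; then members with a follow-up visit within 3 months;
then members starting one of nine AOMs within 1 year.

```bash
cohortforge simulate --mode fixture \
    --spec src/cohortforge/data/fracture_fixture.yaml --out data
cohortforge identify --data data \
    --specs src/cohortforge/data/fracture_study.yaml --mart mart
```

```
wrote 4698 patients, 9230 events, 6891 encounters to data
[605e7828-…] incident osteoporotic fracture cohort: n=2193 cost=0.111s
[96fce0a6-…] continued follow-up within 3 months: n=1808 cost=0.028s
[fa152413-…] AOM initiation within 1 year: n=464 cost=0.029s
```

Of 4698 indexed patients, 557 are excluded for prior malignancy, 1769 for a
prior osteoporotic fracture and 179 for prior AOM use, leaving 2193
incident cases; 1808 (82.44%) keep a 3-month follow-up and only 464
(21.16%) start treatment within a year — the treatment gap. The
characteristics view of the treated cohort:

```bash
cohortforge report --mart mart --view characteristics \
    --case "AOM initiation within 1 year" --data data
```

```
n = 464
age_at_index: mean 76.06 (SD 9.89, n = 464)
bmi: mean 23.16 (SD 4.01, n = 422)
sex: female 384 (82.76%); male 80 (17.24%)
marital_status: married 334 (71.98%); unmarried 130 (28.02%)
income_level: normal 463 (99.78%); low 1 (0.22%)
```

and the attrition (source-record) view walks the hierarchy root-to-leaf:

```bash
cohortforge report --mart mart --view attrition \
    --case "AOM initiation within 1 year"
```

```
… incident osteoporotic fracture cohort   index                          4698
… incident osteoporotic fracture cohort   prior malignant neoplasm   557 4141
… incident osteoporotic fracture cohort   prior osteoporotic fracture 1769 2372
… incident osteoporotic fracture cohort   prior AOM use              179 2193
… AOM initiation within 1 year            index                          2193
… AOM initiation within 1 year            AOM dispensing within 1 year 1729 464
```

Quarterly treatment trends come from
`cohortforge report --view trend --case <denominator> --numerator <nested list>`.

The same workflow is available as a library: `generate_fixture` /
`generate_population`, `run_batch(fracture_study_specs(), ds, mart)`,
`summarize_characteristics`, `incidence_trend`, `proportion_trend`,
`attrition_report`.

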