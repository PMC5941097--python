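# Methods

## Data model

Three headered CSV tables with ISO-8601 dates model a patient-level
hospital extract. `patients` carries demographics (birth date, sex, BMI,
marital status, income level, occupation, optional death date); `events`
carries dated clinical events on four dimensions — diagnosis (ICD-9),
pharmacy (lowercase canonical drug names), procedure, laboratory — each
with a care setting (outpatient, admission, emergency) and, for pharmacy
rows only, the days a dispensing covers; `encounters` carries dated
hospital contacts. Unknown categorical values are the literal string
`unknown`; missing optional fields are empty cells, so malformed and
missing are never conflated. Duplicate event rows on (patient, date,
dimension, code, setting) are dropped at load with a logged count: claims
extracts routinely repeat lines and all downstream logic is set-based, so
multiplicity carries no information here. Laboratory events are modelled
with code and date only; no result values are represented.

## Code matching

Template patterns come in three kinds. *Exact* is string equality.
*Prefix* implements ICD-9 category semantics: the pattern `820` matches
`820` and any dotted subcode `820.x…`, but never `8200` — categories are
exactly three characters, and stored codes carry explicit decimal points.
*Range* compares the integer value of a three-digit leading category
against inclusive bounds; V- and E-codes never match a numeric range.
Pharmacy matching is exact-only against a controlled vocabulary, because
drugs are named, not coded, in the study definition. These choices make
matching unambiguous where a bare statement like "codes 140–208" leaves
room for interpretation, and they are property-tested against an
independent regex oracle.

## Index rule and washout

The index date is the earliest matching diagnosis inside the observation
window, restricted to the requested care settings; multiple qualifying
codes on the same earliest day collapse to a single index date. Two
washout modes are supported. `first_ever` (the default) admits a patient
only if no matching diagnosis exists anywhere before the window — the
strictest "newly diagnosed" reading, appropriate when the database's full
history is trusted. `none` takes the first in-window occurrence and leaves
the new-user restriction to explicit lookback criteria. The packaged
fracture study uses `none` together with a `[−365, −1]` prior-fracture
exclusion criterion: that is the only combination under which prior
fracture can appear as a visible, counted exclusion step in the attrition
flow, since under `first_ever` any pre-index matching code either moves
the index or removes the patient before criteria run. Both modes share
one code path and are tested against the same naive interpreter.

## Criteria windows and attrition

Criterion windows are inclusive signed day-offsets relative to index:
"within 1 year before" is `[−365, −1]`, "within 3 months after" is
`[+1, +90]`, "within 1 year after" is `[+1, +365]`. Calendar-language
windows were translated to day offsets because offsets are unambiguous
under leap years and month lengths; the index day itself (offset 0)
belongs to neither side, which the tests pin down explicitly. Age criteria
use completed years by birthday-anniversary arithmetic.

Attrition is attributed sequentially: each criterion counts only patients
still alive in the pipeline, so step counts are disjoint and
`index − Σ excluded = final` holds by construction (asserted on every
run). The final member set is order-invariant — criteria are independent
per-patient predicates — so criterion order is bookkeeping, not logic;
this is property-tested under random permutations.

## Patient lists, hierarchy, batch execution

Every run mints a version-4 UUID case number. Determinism contracts cover
member sets and attrition, not identifiers or timestamps. Lists persist as
one directory per case number (`members.csv` + `metadata.json`) so marts
are inspectable and diffable. Queued specs execute strictly FIFO with an
append-only audit log; a failing spec is recorded and skipped so one bad
definition cannot block a queue. A spec's `source_list` may name a case
number or, for self-contained queue files, the topic of an earlier list
(latest match wins).

## Reports

Characteristics reports use the sample standard deviation (n−1) and count
missing BMI separately (`n_nonmissing`); categorical percentages are over
the full cohort n, with missing occupation folded into `unknown`. Trend
buckets are calendar-aligned periods (quarters are Jan–Mar … Oct–Dec,
labelled `YYYY Qn`) spanning the observation window contiguously, so empty
buckets are visible; bucketing is a partition and totals are conserved
under any stratification. Fracture-type strata classify each member by
which code set (hip, vertebral, or both) matched on the index day, since
multi-code index days are otherwise undefined. Proportion trends require
the numerator cohort to be nested in the denominator cohort and report a
null proportion for empty-denominator buckets. Percentage rendering is
round-half-up at caller-chosen precision (0–2 decimals) because published
tables mix display precisions.

## Pharmacy duration normalisation

Long-acting drugs (annual zoledronate infusions, semi-annual denosumab)
are sometimes recorded as 1-day prescriptions. An opt-in correction
replaces a recorded duration of exactly 1 with the drug's canonical
duration when that canonical value exceeds 30 days. It is opt-in, returns
a new dataset, and is deliberately conservative: only the pathological
1-day records are touched, plausible recorded values are kept. Cohort
membership in the packaged study is presence-based and unaffected; the
correction matters for exposure-duration analyses built on top.

## Synthetic data

*Fixture mode* constructs one mutually exclusive patient category per
cohort-flow branch: eligible treated / eligible untreated / indexed
without 3-month follow-up, one category per exclusion reason (prior
malignancy, prior fracture, prior AOM, under 50, Paget history), and
never-indexed patients with out-of-window fractures only. Index dates are
allocated round-robin over the window's calendar quarters, except that
prior-fracture patients index only in the first observation year so their
earlier fracture code can predate the window (otherwise it would itself
become the index). Category counts therefore map one-to-one onto attrition
entries, which is what makes the packaged flow exactly reproducible; the
property is verified by running the engine, not assumed. Default
demographic composition mirrors the treated cohort of the worked example:
82.76% female, 71.98% married, 99.78% normal income, age 76.47 (SD 10.10)
years drawn as rounded normals truncated to [52, 105] (so age-based
exclusion cannot bleed across categories), BMI 22.95 (SD 3.86) truncated
to [12, 45] with every eleventh value missing to exercise missing-data
paths.

*Population mode* draws independent patients: age at window start from a
normal distribution, per-year Bernoulli fracture incidence with uniform
dates, treatment with probability `p_treat` as an AOM dispensing uniform
in `[+1, +365]`, follow-up with probability `p_fu` as an encounter uniform
in `[+1, +90]`, and lookback comorbidity/drug histories at stated
background rates. Defaults encode the worked example's regime —
`p_treat = 0.21`, `p_fu = 0.82`, n = 5000, age 76.47 ± 10.10, 82.8%
female — plus a 6% yearly fracture incidence and background history rates
(malignancy 8%, prior AOM 4%, pre-window fracture 5%, Paget 0.5%) chosen
once as plausible magnitudes for an elderly hospital population; the
engine's recovered proportions are then compared against the generating
parameters within three binomial standard errors. The generator emulates
the statistical structure the analysis relies on (incident events,
lookback histories, post-index utilisation), not clinical realism: there
is no disease progression, coding noise, re-fracture correlation, or
utilisation beyond the modelled visits. Passing recovery tests therefore
shows the pipeline measures what the generator encodes — not that real
hospital data would yield these rates.

Both generators route all randomness through a single seeded
`numpy.random.Generator`, giving bitwise-identical output files for a
given seed.

## Numerical and edge-case choices

Dates are handled as pandas timestamps (day precision); float
serialisation uses shortest round-trip `repr` so write→load is exact.
Empty cohorts are valid everywhere: an empty index set yields an empty
list with attrition recorded, characteristics of an empty list report
n = 0, trend rows for an empty observation-less list are empty. The sample
SD of a single observation is NaN rather than an error. Leap-day birthdays
celebrate on 1 March in non-leap years, matching the naive month/day
comparison.

## Problem sizes

The deterministic worked-example fixture holds 4698 patients (~9k events)
and runs the full chain in well under a second. Oracle-equivalence checks
use 100 random datasets of 30–150 patients against a pure-python
per-patient interpreter; parameter recovery uses one 5000-patient
population. These sizes make every distributional claim testable at three
standard errors while keeping the whole suite fast.

## Known limitations

No ICD-10 or ATC hierarchy semantics; no database connectivity, ETL, or
anonymisation; no access control or review workflow; reports are tables,
not charts. The published cohort's absolute counts originate in a real
hospital database, so outside the fixture construction they are regimes to
emulate, not quantities derivable from first principles.
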