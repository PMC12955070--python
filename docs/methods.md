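# Methods

## Problem setting

German claims data codes diagnoses in ICD-10-GM. Most rare diseases (RDs)
are not distinguishable in that system; Orphanet identifiers (Orphacodes)
disambiguate them. The Alpha-ID-SE terminology bridges the two: every
diagnostic term of the ICD-10-GM alphabetical index has a stable
identifier, its ICD code(s) and, where the term names a rare disease, an
Orphacode. The package assesses how completely, plausibly and uniquely a
hospital dataset documents RD cases, and how much of that quality a
transformation pipeline (e.g. claims → FHIR core-data-set) preserved.

## Tracer diagnoses

An ICD-10-GM code is a *tracer* iff every **valid** terminology term
carrying that code as its primary code has an Orphacode — the code
exclusively encodes (annotated) rare diseases, so it marks an RD case
even without a documented Orphacode. Retired (validity-0) terms are kept
for audit but never participate in tracer derivation, link checking or
candidate queries; a code with zero valid terms is not a tracer. Only the
primary ICD code participates; secondary (star) codes are carried as data
but do not define tracers. Curated expert tracer lists are supported as a
separate provenance and are never mixed with derived tracers.

## Parameters

All parameters are non-negative counts over one dataset.

| No. | name | counts |
|-----|------|--------|
| P1 | rdCase | distinct cases with ≥1 diagnosis carrying an Orphacode **or** a tracer ICD |
| P2 | orphaCase | distinct cases with ≥1 Orphacode-bearing diagnosis |
| P3 | tracerCase | distinct cases with ≥1 tracer-coded diagnosis |
| P4–P6 | *_rel | P1–P3 · 100 000 / total inpatient cases, rounded half-up; absent without a known total |
| P7 | im_misg | mandatory items no record carries any value for |
| P8 | vm_misg | absent values in slots of items that are present somewhere |
| P9 | vo | values violating range/syntax rules |
| P10 | oc_misg | tracer diagnoses without an Orphacode |
| P11 | link_ip | (ICD, Orphacode) pairs not found in the terminology |
| P12 | rdCase_dup | surplus records in identical (case, patient, ICD, Orphacode) groups: Σ(g−1) |
| P13 | rdCase_amb | RD cases with an ambiguous diagnosis (rules below) |

`max(P2, P3) ≤ P1 ≤ P2 + P3` holds by construction and is enforced.
Parameters are counted on raw records: duplicate detection does not
precede case counting (a deduplicated view can be obtained by removing
the surplus records the P12 issues name).

P12 counts *surplus* records (g−1 per duplicate group) rather than whole
groups: that is the number of removable records, the actionable quantity.

### Ambiguity rules (P13)

- **Rule (a):** a tracer-coded diagnosis without an Orphacode whose ICD
  code has more than one candidate Orphacode in the terminology. The code
  subsumes several RDs and nothing disambiguates them. A tracer code with
  exactly one candidate is *not* ambiguous — the missing annotation is
  still a P10 finding, but the disease is determined.
- **Rule (b)** (interpretation, switchable off via
  `RunConfig.ambiguous_rule_b`): a diagnosis carrying an (ICD, Orphacode)
  pair where the ICD has multiple candidates and the recorded Orphacode
  is not among them — the implausible link fails to pin down which RD is
  meant. A *plausible* pair on a multi-RD code is unambiguous: the
  Orphacode resolves it.

A case counts once toward P13 regardless of how many diagnoses trigger.
Note the inherent coupling: every rule-(a) diagnosis is also a P10
missing Orphacode. Issue categories are otherwise disjoint.

## Indicators

Each indicator is `100 · (1 − issues / denominator)`, clipped to
[0, 100]. A zero denominator makes the indicator *vacuous*: it reports 0
with its evaluability flag cleared (so a dataset with no Orphacodes shows
0 % on the Orphacode-related indicators rather than a misleading 100 %).

| indicator | dimension | issues | denominator |
|-----------|-----------|--------|-------------|
| dqi_co_ocr | completeness | P10 | tracer diagnoses |
| dqi_co_icr | completeness | P7 | mandatory items (15 by default) |
| dqi_co_vcr | completeness | P8 | value slots (records × present items of their type) |
| dqi_pl_opr | plausibility | P11 | linked diagnoses (ICD and Orphacode both present) |
| dqi_pl_rpr | plausibility | P9 | values actually checked by the rules |
| dqi_un_cur | uniqueness | P13 | P1 |
| dqi_un_cdr | uniqueness | P12 | diagnosis-bearing case records |

These denominators are the only choice consistent with the two published,
recomputable anchors: an RD Case Unambiguity Rate above 94 % in both
study datasets (9/163 → 94.48 %, 14/783 → 98.21 %) and an Orphacoding
Plausibility Rate above 97 % (21/729 → 97.12 %).

## Mandatory items and value slots

The default catalog has 15 items across the Person (patient_id,
birth_date, sex, address_city, address_postal_code), Treatment Case
(case_id, patient_ref, admission_date, discharge_date, encounter_class)
and Diagnosis (condition_id, case_ref, icd_code, diagnosis_date,
diagnosis_role) modules. The exact item set of a given core-data-set
version is site business — the catalog is injected via config, and the
default is a documented approximation. An item is *missing* (P7) iff no
record of its type carries a value; otherwise each record of that type
contributes one value slot, and an absent value there counts toward P8.
Reduced-precision dates (year, year-month — legal in FHIR) are present
values; completeness never punishes them.

## Outlier rules

Defaults: age at admission ≤ 130 years; discharge ≥ admission; birth date
not after a configurable reference date (default 2022-12-31); code fields
restricted to `[A-Z0-9.!+*-]` (special characters in code fields are a
known plausibility-issue source in practice). Each evaluation on present
values increments the checked-value denominator. Rules referencing
unknown fields are rejected at config time.

## Comparative statistic

With a reference parameter set (direct export) and a transformed one
(FAIRified rendition of the same source):

```
Pi_lost = Pi_transformed − Pi_reference   for i ∈ {7, 8, 9}
Pi_lost = Pi_reference − Pi_transformed   otherwise
```

The sign flip reflects that P7–P9 count issues (more is worse) while the
other parameters count present observation units. Positive losses in P9
(outliers) and P12 (duplicates) are classified *possibly-intentional* —
curation may legitimately remove them; other positive losses are
classified as issues; negative losses are reported, never clamped
(manual claims curation can insert data). Comparison requires both sets
to be computed under the same terminology, tracer set and item catalog
(fingerprint-checked). Relative parameters (P4–P6) are compared only when
both inpatient totals are known and equal.

The summary decomposes the transformed dataset's distinct issues as:
positive completeness losses (among P1, P7, P8, P10) + transformed
ambiguous cases (P13) + shared missing items (transformed P7 minus the
positive P7 loss). On the published counts this reproduces
1977 + 9 + 2 = 1988.

## k-anonymous reporting

Violation groups (category × group key, e.g. all missing Orphacodes on
one ICD code) touching fewer than k distinct patients are suppressed and
folded into one aggregate row; k defaults to 5. Dataset-level findings
that reference no patient (missing items) disclose nothing about
individuals and are always reported. CSV fallbacks are byte-deterministic
for identical inputs; the XLSX workbook carries the same rows.

## Synthetic fixture generator

The generator emulates the paired-dataset study design: a reference
dataset (direct-export shape) and a degraded dataset (FAIRification
emulation) over the same population, each rendered as PAS-style CSV and
as FHIR NDJSON from one record set, plus a terminology whose derived
tracer set is known by construction.

Default conditions: 60 patients, 80 inpatient cases in study year 2021,
one tracer-coded diagnosis per case, a 20 000-case inpatient total for
the relative frequencies, and a planted issue mix of 2 missing items (the
address pair, mirroring privacy-driven omission), 7 missing Orphacodes,
2 implausible links, 9 duplicate rows and 2 ambiguous cases — roughly one
tenth of the issue profile observed in a real university-hospital
rare-disease export. Degradation switches: `drop_all_orphacodes`
(emulating Orphacodes not being part of the claims format),
`drop_items`, `drop_case_fraction`.

Planted issues claim disjoint cases so the ledger arithmetic is exact,
with the one documented coupling (expected P10 = planted missing
Orphacodes + planted ambiguous cases). Outliers are planted as
discharge-before-admission inversions because the violation is strictly
case-local; the age rule is exercised by unit tests. Dropped cases are
taken from the clean tail so no planted issue disappears. Identifiers
embed a 4-hex-digit hash of the seed; the only randomness is in dates and
patient attributes, so identical specs are byte-reproducible.

What the generator does **not** emulate: realistic disease prevalence,
multi-diagnosis case structure, free-text noise, coding-habit drift
between wards, or re-identification risk. Passing the recovery suite
shows the counting and detection machinery is exact under controlled
conditions; it does not certify behavior on the messier shapes of real
PAS exports, which is what the configurable schema/catalog/rules exist
for.

## Numerical choices

- Relative frequencies round half-up to integers (`decimal`).
- Indicators are floats on [0, 100], clipped after division; they are
  rounded to 2 decimals only at the reporting boundary.
- Ages use a 365.25-day year.
- Empty CSV cells and absent FHIR elements both map to absent (`None`);
  empty-string sentinels never enter the model.
- ICD codes are normalized to uppercase dot notation; trailing usage
  markers (`!`, `+`, `*`) are split into a separate attribute so codes
  compare equal across sources. Orphacode prefixes (`ORPHA:`) are
  stripped; a non-numeric remainder is a warning, not a load failure.
- Terminology streams where more than half the lines are malformed are
  rejected outright; below that, bad lines are collected for audit.
- FHIR paging: when the server reports a total, remaining pages are
  addressed by offset (enabling parallel fetch with an order-independent,
  id-keyed merge); otherwise next-links are followed sequentially.
  Transient page failures are retried with backoff before a hard error
  naming the page.

## Problem sizes

The recovery suite runs 100 random fixture specs of 15–50 cases each, and
the default generator spec uses 80 cases — small enough that the full
suite completes in well under a minute while exercising every detector
and both readers; the counting machinery is size-independent, so nothing
about the method changes at hospital scale.

## Known limitations

- The published site-specific counts stem from non-public hospital data;
  only the printed, recomputable arithmetic is reproduced.
- Ambiguity rule (b) is an interpretation (see above) and can be
  disabled; rule (a) is the uncontroversial core.
- Tracer derivation inherits the terminology's annotation gaps: a code
  missing one Orphacode annotation is not a tracer even if it exclusively
  encodes RDs.
- The FHIR reader consumes the three profiles it needs and does not
  validate against StructureDefinitions; authentication is limited to a
  bearer token.
- Cause attribution of losses to specific ETL stages is out of scope; the
  comparison quantifies *what* changed, not *why*.
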