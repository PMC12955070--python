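"""Synthetic paired fixtures with a planted-issue ledger.

Real rare-disease claims data cannot be shared, so every detector and
both readers are exercised against generated data: a small Alpha-ID-SE
style terminology, a *reference* dataset (emulating a direct PAS export)
and a *degraded* dataset (emulating the FAIRified rendition of the same
population), each rendered both as a PAS-style CSV and as FHIR NDJSON.

Every planted issue is recorded in a ledger together with the exact
parameter set the engine must recover. Planted issues are mutually
exclusive per case so the ledger arithmetic stays exact, with one
documented coupling: an ambiguous case planted via a multi-Orphacode
tracer code without an Orphacode necessarily also counts as one missing
Orphacode, so expected P10 = missing_orphacodes + ambiguous_cases.

Identifiers embed a short hash of the seed, so fixtures from different
seeds never collide and identical specs are byte-reproducible.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import datetime as _dt
import hashlib
import io
import json
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .config import ICD10GM_SYSTEM, ORPHANET_SYSTEM
from .model import (
    CaseDataset,
    DiagnosisRecord,
    EncounterRecord,
    PatientRecord,
)
from .terminology import AlphaTerminology, TracerSet, parse_alpha_id_se

__all__ = [
    "FixtureSpec",
    "TerminologyFixture",
    "PlantedLedger",
    "PairFixture",
    "FixtureError",
    "gen_terminology",
    "build_pair",
    "gen_dataset_pair",
]

#: items that may be planted as wholly missing or dropped by degradation
#: (never the missing-value substrate items, so ledger counts stay exact)
DROPPABLE_ITEMS = (
    "address_city",
    "address_postal_code",
    "sex",
    "diagnosis_role",
    "encounter_class",
    "birth_date",
)

#: items used as the missing-value substrate (one record each, case-local)
_VALUE_SUBSTRATE = ("discharge_date", "diagnosis_date")


class FixtureError(ValueError):
    """The fixture spec is unsatisfiable; the message names the constraint."""


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one generated dataset pair.

    The defaults emulate a cohort about one tenth the size of a mid-size
    university-hospital rare-disease export, with the issue mix observed
    in direct claims exports: a couple of address items withheld for
    privacy, a block of tracer diagnoses without Orphacodes, a few
    implausible code links, duplicated billing rows and the occasional
    ambiguous multi-RD code.
    """

    n_patients: int = 60
    n_cases: int = 80
    # terminology composition
    n_tracer_single: int = 8
    n_tracer_multi: int = 2
    n_non_tracer: int = 3
    # planted issues (reference dataset)
    missing_items: int = 2
    missing_values: int = 0
    outliers: int = 0
    missing_orphacodes: int = 7
    implausible_links: int = 2
    duplicates: int = 9
    ambiguous_cases: int = 2
    # FAIRification-emulation switches (degraded dataset)
    drop_all_orphacodes: bool = False
    drop_items: tuple[str, ...] = ()
    drop_case_fraction: float = 0.0
    # context
    total_inpatient_cases: int = 20_000
    study_year: int = 2021
    seed: int = 0

    @property
    def n_dropped_cases(self) -> int:
        return int(self.drop_case_fraction * self.n_cases)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_cases < 1:
            raise FixtureError("need at least one patient and one case")
        planted = [self.missing_items, self.missing_values, self.outliers,
                   self.missing_orphacodes, self.implausible_links,
                   self.duplicates, self.ambiguous_cases]
        if any(c < 0 for c in planted):
            raise FixtureError("planted counts must be non-negative")
        if not 0.0 <= self.drop_case_fraction < 1.0:
            raise FixtureError("drop_case_fraction must be in [0, 1)")
        if self.n_patients > self.n_cases:
            # every patient must be reachable from a case so the CSV and
            # FHIR renderings describe the same record set
            raise FixtureError("n_patients must not exceed n_cases")
        if any(c < 0 for c in (self.n_tracer_single, self.n_tracer_multi, self.n_non_tracer)):
            raise FixtureError("terminology counts must be non-negative")
        if self.n_tracer_single < 1:
            raise FixtureError("need at least one single-Orphacode tracer code")
        if self.ambiguous_cases > 0 and self.n_tracer_multi < 1:
            raise FixtureError("ambiguous_cases require a multi-Orphacode tracer code")
        if self.missing_items > len(DROPPABLE_ITEMS):
            raise FixtureError(
                f"at most {len(DROPPABLE_ITEMS)} items can be planted missing: {DROPPABLE_ITEMS}"
            )
        bad_drop = set(self.drop_items) - set(DROPPABLE_ITEMS)
        if bad_drop:
            raise FixtureError(f"drop_items not droppable: {sorted(bad_drop)}")
        planted_items = set(DROPPABLE_ITEMS[: self.missing_items])
        if planted_items & set(self.drop_items):
            raise FixtureError("drop_items overlap the items already planted missing")
        needed = (self.missing_orphacodes + self.implausible_links
                  + self.ambiguous_cases + self.outliers + self.missing_values
                  + self.duplicates + self.n_dropped_cases)
        if needed > self.n_cases:
            raise FixtureError(
                f"planted issues and case drops need {needed} distinct cases, "
                f"only {self.n_cases} available"
            )


@dataclass
class TerminologyFixture:
    text: str
    terminology: AlphaTerminology
    tracers: TracerSet
    single_codes: list[str]
    multi_codes: list[str]
    non_tracer_codes: list[str]
    orpha_of: dict[str, int]  # single-code -> its Orphacode


def gen_terminology(spec: FixtureSpec) -> TerminologyFixture:
    """Emit a terminology whose derived tracer set is known by construction.

    Single-Orphacode tracer codes get one fully annotated term;
    multi-Orphacode tracer codes get two terms with distinct Orphacodes
    (the ambiguity substrate); non-tracer codes get one annotated and one
    unannotated term, so the all-terms-annotated rule rejects them.

    Only the terminology counts are validated here (all-zero counts give
    an empty terminology); dataset satisfiability is checked by
    :func:`build_pair`.
    """
    if any(c < 0 for c in (spec.n_tracer_single, spec.n_tracer_multi, spec.n_non_tracer)):
        raise FixtureError("terminology counts must be non-negative")
    lines = []
    alpha_counter = 1
    orpha_counter = 100_001
    single, multi, non_tracer = [], [], []
    orpha_of = {}

    def emit(icd: str, orpha: int | None, label: str) -> None:
        nonlocal alpha_counter
        orpha_text = "" if orpha is None else str(orpha)
        lines.append(f"1|I{alpha_counter:06d}|{icd}|||{orpha_text}|{label}")
        alpha_counter += 1

    for i in range(spec.n_tracer_single):
        icd = f"E{70 + i // 10}.{i % 10}"
        single.append(icd)
        orpha_of[icd] = orpha_counter
        emit(icd, orpha_counter, f"Synthetic single-term RD {i}")
        orpha_counter += 1
    for i in range(spec.n_tracer_multi):
        icd = f"Q{80 + i // 10}.{i % 10}"
        multi.append(icd)
        emit(icd, orpha_counter, f"Synthetic multi-RD code {i}, form A")
        emit(icd, orpha_counter + 1, f"Synthetic multi-RD code {i}, form B")
        orpha_counter += 2
    for i in range(spec.n_non_tracer):
        icd = f"M{30 + i // 10}.{i % 10}"
        non_tracer.append(icd)
        emit(icd, orpha_counter, f"Synthetic mixed code {i}, rare term")
        emit(icd, None, f"Synthetic mixed code {i}, common term")
        orpha_counter += 1

    text = "\n".join(lines) + ("\n" if lines else "")
    terminology = parse_alpha_id_se(io.StringIO(text))
    from .terminology import derive_tracers

    tracers = derive_tracers(terminology)
    expected = frozenset(single) | frozenset(multi)
    if tracers.codes != expected:  # construction self-check
        raise AssertionError("generated terminology does not derive the planted tracer set")
    return TerminologyFixture(text, terminology, tracers, single, multi, non_tracer, orpha_of)


@dataclass
class PlantedLedger:
    """Ground truth accompanying a generated pair."""

    planted: dict[str, int]
    record_ids: dict[str, list[str]]
    expected_reference: dict[str, int | None]
    expected_degraded: dict[str, int | None]
    expected_lost: dict[str, int | None]
    dropped_case_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PairFixture:
    spec: FixtureSpec
    terminology: TerminologyFixture
    reference: CaseDataset
    degraded: CaseDataset
    ledger: PlantedLedger


def _rel(count: int, total: int) -> int:
    return int(Decimal(100_000 * count / total).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _seed_tag(seed: int) -> str:
    return hashlib.sha256(str(seed).encode()).hexdigest()[:4]


def _expected_vector(
    spec: FixtureSpec, *, degraded: bool
) -> dict[str, int | None]:
    n_drop = spec.n_dropped_cases if degraded else 0
    n_cases = spec.n_cases - n_drop
    n_diagnoses = spec.n_cases + spec.duplicates - n_drop
    p1 = p3 = n_cases
    p2 = n_cases - spec.missing_orphacodes - spec.ambiguous_cases
    p7 = spec.missing_items
    p10 = spec.missing_orphacodes + spec.ambiguous_cases
    p11 = spec.implausible_links
    p13 = spec.ambiguous_cases
    if degraded:
        p7 += len(spec.drop_items)
        if spec.drop_all_orphacodes:
            p2 = 0
            p10 = n_diagnoses  # every diagnosis is tracer-coded and bare
            p11 = 0
    total = spec.total_inpatient_cases
    return {
        "P1": p1, "P2": p2, "P3": p3,
        "P4": _rel(p1, total), "P5": _rel(p2, total), "P6": _rel(p3, total),
        "P7": p7, "P8": spec.missing_values, "P9": spec.outliers,
        "P10": p10, "P11": p11, "P12": spec.duplicates, "P13": p13,
    }


def _expected_lost(ref: dict, deg: dict) -> dict[str, int | None]:
    lost = {}
    for i in range(1, 14):
        a, b = ref[f"P{i}"], deg[f"P{i}"]
        if a is None or b is None:
            lost[f"P{i}"] = None
        elif i in (7, 8, 9):
            lost[f"P{i}"] = b - a
        else:
            lost[f"P{i}"] = a - b
    return lost


def _blank_item(name: str, patients, encounters, diagnoses) -> None:
    if name in ("address_city", "address_postal_code"):
        for p in patients:
            p.address_items.pop(name, None)
    elif name == "sex":
        for p in patients:
            p.sex = None
    elif name == "birth_date":
        for p in patients:
            p.birth_date = None
    elif name == "diagnosis_role":
        for d in diagnoses:
            d.role = None
    elif name == "encounter_class":
        for e in encounters:
            e.encounter_class = None
    else:  # pragma: no cover - guarded by validate()
        raise FixtureError(f"item {name!r} cannot be blanked")


def build_pair(spec: FixtureSpec) -> PairFixture:
    """Generate the reference/degraded dataset pair in memory.

    Every case carries exactly one tracer-coded diagnosis; planted issue
    categories claim disjoint cases (see module docstring for the single
    documented coupling). The degraded dataset applies the
    FAIRification-emulation switches on top of a deep copy.
    """
    spec.validate()
    term_fix = gen_terminology(spec)
    rng = random.Random(spec.seed)
    tag = _seed_tag(spec.seed)

    patients: list[PatientRecord] = []
    for i in range(spec.n_patients):
        birth_year = rng.randint(1940, 2010)
        birth = _dt.date(birth_year, rng.randint(1, 12), rng.randint(1, 28))
        patients.append(
            PatientRecord(
                patient_id=f"p{tag}{i:04d}",
                birth_date=birth.isoformat(),
                sex="male" if i % 2 == 0 else "female",
                address_items={
                    "address_city": f"City{i % 10}",
                    "address_postal_code": f"72{i % 100:03d}",
                },
            )
        )

    encounters: list[EncounterRecord] = []
    diagnoses: list[DiagnosisRecord] = []
    record_ids: dict[str, list[str]] = {k: [] for k in (
        "missing_items", "missing_values", "outliers", "missing_orphacodes",
        "implausible_links", "duplicates", "ambiguous_cases",
    )}

    # case-index allocation: disjoint blocks per category, clean cases last
    blocks = {}
    cursor = 0
    for name, count in (
        ("missing_orphacodes", spec.missing_orphacodes),
        ("implausible_links", spec.implausible_links),
        ("ambiguous_cases", spec.ambiguous_cases),
        ("outliers", spec.outliers),
        ("missing_values", spec.missing_values),
        ("duplicates", spec.duplicates),
    ):
        blocks[name] = range(cursor, cursor + count)
        cursor += count

    single = term_fix.single_codes
    multi = term_fix.multi_codes

    for j in range(spec.n_cases):
        patient = patients[j % spec.n_patients]
        case_id = f"c{tag}{j:04d}"
        cond_id = f"d{tag}{j:04d}"
        admission = _dt.date(spec.study_year, 1, 1) + _dt.timedelta(days=rng.randint(0, 330))
        discharge = admission + _dt.timedelta(days=rng.randint(1, 15))
        icd = single[j % len(single)]
        orpha: int | None = term_fix.orpha_of[icd]
        diagnosis_date: str | None = admission.isoformat()
        discharge_date: str | None = discharge.isoformat()

        if j in blocks["missing_orphacodes"]:
            orpha = None
            record_ids["missing_orphacodes"].append(cond_id)
        elif j in blocks["implausible_links"]:
            orpha = 900_000 + j  # never present in the terminology
            record_ids["implausible_links"].append(cond_id)
        elif j in blocks["ambiguous_cases"]:
            icd = multi[j % len(multi)]
            orpha = None  # multi-RD code left undisambiguated
            record_ids["ambiguous_cases"].append(case_id)
        elif j in blocks["outliers"]:
            discharge_date = (admission - _dt.timedelta(days=3)).isoformat()
            record_ids["outliers"].append(case_id)
        elif j in blocks["missing_values"]:
            k = j - blocks["missing_values"].start
            if _VALUE_SUBSTRATE[k % 2] == "discharge_date":
                discharge_date = None
                record_ids["missing_values"].append(case_id)
            else:
                diagnosis_date = None
                record_ids["missing_values"].append(cond_id)

        encounters.append(
            EncounterRecord(
                case_id=case_id,
                patient_id=patient.patient_id,
                admission_date=admission.isoformat(),
                discharge_date=discharge_date,
                encounter_class="IMP",
            )
        )
        diagnosis = DiagnosisRecord(
            case_id=case_id,
            patient_id=patient.patient_id,
            condition_id=cond_id,
            icd_code=icd,
            orphacode=orpha,
            diagnosis_date=diagnosis_date,
            role="primary" if j % 3 else "secondary",
        )
        diagnoses.append(diagnosis)
        if j in blocks["duplicates"]:
            dup = copy.deepcopy(diagnosis)
            dup.condition_id = f"d{tag}{j:04d}x"
            diagnoses.append(dup)
            record_ids["duplicates"].append(dup.condition_id)

    planted_items = list(DROPPABLE_ITEMS[: spec.missing_items])
    for name in planted_items:
        _blank_item(name, patients, encounters, diagnoses)
        record_ids["missing_items"].append(name)

    reference = CaseDataset(
        patients=patients,
        encounters=encounters,
        diagnoses=diagnoses,
        provenance="EXP",
        total_inpatient_cases=spec.total_inpatient_cases,
    )

    # --- degraded dataset -------------------------------------------------
    deg_patients = copy.deepcopy(patients)
    deg_encounters = copy.deepcopy(encounters)
    deg_diagnoses = copy.deepcopy(diagnoses)
    dropped_case_ids: list[str] = []
    if spec.n_dropped_cases:
        # drop from the clean tail so no planted issue disappears
        clean = [e.case_id for e in encounters[cursor:]]
        dropped_case_ids = clean[-spec.n_dropped_cases:]
        dropped = set(dropped_case_ids)
        deg_encounters = [e for e in deg_encounters if e.case_id not in dropped]
        deg_diagnoses = [d for d in deg_diagnoses if d.case_id not in dropped]
    if spec.drop_all_orphacodes:
        for d in deg_diagnoses:
            d.orphacode = None
    for name in spec.drop_items:
        _blank_item(name, deg_patients, deg_encounters, deg_diagnoses)

    degraded = CaseDataset(
        patients=deg_patients,
        encounters=deg_encounters,
        diagnoses=deg_diagnoses,
        provenance="FHIR",
        total_inpatient_cases=spec.total_inpatient_cases,
    )

    expected_ref = _expected_vector(spec, degraded=False)
    expected_deg = _expected_vector(spec, degraded=True)
    ledger = PlantedLedger(
        planted={
            "missing_items": spec.missing_items,
            "missing_values": spec.missing_values,
            "outliers": spec.outliers,
            "missing_orphacodes": spec.missing_orphacodes,
            "implausible_links": spec.implausible_links,
            "duplicates": spec.duplicates,
            "ambiguous_cases": spec.ambiguous_cases,
        },
        record_ids=record_ids,
        expected_reference=expected_ref,
        expected_degraded=expected_deg,
        expected_lost=_expected_lost(expected_ref, expected_deg),
        dropped_case_ids=dropped_case_ids,
    )
    return PairFixture(spec, term_fix, reference, degraded, ledger)


# --- file rendering -------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id", "case_id", "admission_date", "discharge_date", "birth_date",
    "sex", "address_city", "address_postal_code", "encounter_class",
    "diagnosis_id", "icd_code", "orphacode", "diagnosis_date", "diagnosis_role",
]


def render_csv(ds: CaseDataset) -> str:
    """One row per diagnosis, patient/encounter attributes repeated."""
    patients = {p.patient_id: p for p in ds.patients}
    encounters = {e.case_id: e for e in ds.encounters}
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for d in ds.diagnoses:
        p = patients.get(d.patient_id or "")
        e = encounters.get(d.case_id or "")
        writer.writerow([
            d.patient_id or "",
            d.case_id or "",
            (e.admission_date if e else "") or "",
            (e.discharge_date if e else "") or "",
            (p.birth_date if p else "") or "",
            (p.sex if p else "") or "",
            (p.address_items.get("address_city") if p else "") or "",
            (p.address_items.get("address_postal_code") if p else "") or "",
            (e.encounter_class if e else "") or "",
            d.condition_id or "",
            d.icd_code or "",
            "" if d.orphacode is None else str(d.orphacode),
            d.diagnosis_date or "",
            d.role or "",
        ])
    return out.getvalue()


def render_ndjson(ds: CaseDataset) -> str:
    """All resources in one NDJSON stream: Patients, Encounters, Conditions."""
    lines = []
    for p in ds.patients:
        res: dict = {"resourceType": "Patient", "id": p.patient_id}
        if p.birth_date:
            res["birthDate"] = p.birth_date
        if p.sex:
            res["gender"] = p.sex
        address = {}
        if "address_city" in p.address_items:
            address["city"] = p.address_items["address_city"]
        if "address_postal_code" in p.address_items:
            address["postalCode"] = p.address_items["address_postal_code"]
        if address:
            res["address"] = [address]
        lines.append(json.dumps(res, sort_keys=True))
    for e in ds.encounters:
        res = {"resourceType": "Encounter", "id": e.case_id}
        if e.patient_id:
            res["subject"] = {"reference": f"Patient/{e.patient_id}"}
        period = {}
        if e.admission_date:
            period["start"] = e.admission_date
        if e.discharge_date:
            period["end"] = e.discharge_date
        if period:
            res["period"] = period
        if e.encounter_class:
            res["class"] = {"system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                            "code": e.encounter_class}
        lines.append(json.dumps(res, sort_keys=True))
    for d in ds.diagnoses:
        res = {"resourceType": "Condition", "id": d.condition_id}
        if d.patient_id:
            res["subject"] = {"reference": f"Patient/{d.patient_id}"}
        if d.case_id:
            res["encounter"] = {"reference": f"Encounter/{d.case_id}"}
        coding = []
        if d.icd_code:
            coding.append({"system": ICD10GM_SYSTEM, "code": d.icd_code, "version": "2021"})
        if d.orphacode is not None:
            coding.append({"system": ORPHANET_SYSTEM, "code": str(d.orphacode)})
        if coding:
            res["code"] = {"coding": coding}
        if d.diagnosis_date:
            res["recordedDate"] = d.diagnosis_date
        if d.role:
            res["category"] = [{"coding": [{"code": d.role}]}]
        lines.append(json.dumps(res, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def gen_dataset_pair(spec: FixtureSpec, out_dir: str | Path) -> tuple[PairFixture, dict[str, Path]]:
    """Generate the pair and write terminology, CSV/NDJSON files and ledger."""
    pair = build_pair(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "terminology": out / "alpha_terminology.txt",
        "reference_csv": out / "reference.csv",
        "reference_ndjson": out / "reference.ndjson",
        "degraded_csv": out / "degraded.csv",
        "degraded_ndjson": out / "degraded.ndjson",
        "ledger": out / "ledger.json",
    }
    paths["terminology"].write_text(pair.terminology.text, encoding="utf-8")
    paths["reference_csv"].write_text(render_csv(pair.reference), encoding="utf-8")
    paths["reference_ndjson"].write_text(render_ndjson(pair.reference), encoding="utf-8")
    paths["degraded_csv"].write_text(render_csv(pair.degraded), encoding="utf-8")
    paths["degraded_ndjson"].write_text(render_ndjson(pair.degraded), encoding="utf-8")
    paths["ledger"].write_text(pair.ledger.to_json(), encoding="utf-8")
    return pair, paths
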