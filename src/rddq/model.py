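"""Harmonized case-data model.

Both input routes — the patient-administration-system CSV export and the
MII core-data-set FHIR resources (Patient / Encounter / Condition) — are
loaded into one :class:`CaseDataset` of patient, encounter and diagnosis
records, so the quality engine is source-agnostic.

Dates are kept as normalized ISO-8601 strings because FHIR legally allows
reduced precision (year or year-month); a reduced-precision date is a
*present* value for completeness purposes and is padded only when date
arithmetic (e.g. age checks) needs it.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

__all__ = [
    "PatientRecord",
    "EncounterRecord",
    "DiagnosisRecord",
    "CaseDataset",
    "MandatoryItem",
    "MandatoryItemCatalog",
    "DEFAULT_CATALOG",
    "normalize_date",
    "parse_partial_date",
    "item_value",
]

_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?")


def normalize_date(raw: str | None) -> str | None:
    """Normalize a date string to ISO-8601, keeping reduced precision.

    ``"2021-03-04T10:00:00"`` → ``"2021-03-04"``; ``"2021-03"`` stays as is.
    Unparseable non-empty input is returned verbatim so that it remains a
    present (if implausible) value rather than vanishing.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if not text:
        return None
    m = _DATE_RE.match(text)
    if not m:
        return text
    parts = [p for p in m.groups() if p is not None]
    return "-".join(parts)


def parse_partial_date(value: str | None) -> _dt.date | None:
    """Parse an ISO date, padding reduced precision to the first day/month."""
    if not value:
        return None
    m = _DATE_RE.match(value)
    if not m:
        return None
    year, month, day = m.group(1), m.group(2) or "01", m.group(3) or "01"
    try:
        return _dt.date(int(year), int(month), int(day))
    except ValueError:
        return None


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: str | None = None
    sex: str | None = None
    address_items: dict[str, str] = field(default_factory=dict)


@dataclass
class EncounterRecord:
    case_id: str
    patient_id: str | None = None
    admission_date: str | None = None
    discharge_date: str | None = None
    #: encounter class code, e.g. "IMP" (inpatient) / "AMB" (ambulatory)
    encounter_class: str | None = None

    @property
    def inpatient(self) -> bool | None:
        if self.encounter_class is None:
            return None
        return self.encounter_class.upper() in ("IMP", "INPATIENT", "STATIONAER")


@dataclass
class DiagnosisRecord:
    case_id: str | None
    patient_id: str | None = None
    condition_id: str | None = None
    icd_code: str | None = None
    orphacode: int | None = None
    diagnosis_date: str | None = None
    #: "primary" | "secondary" | None (unknown)
    role: str | None = None


@dataclass(frozen=True)
class MandatoryItem:
    """One mandatory data item of the core-data-set profile in force."""

    module: str  # "Person" | "Treatment Case" | "Diagnosis"
    name: str
    record_type: str  # "patient" | "encounter" | "diagnosis"


@dataclass(frozen=True)
class MandatoryItemCatalog:
    """Ordered catalog of mandatory items; names unique."""

    items: tuple[MandatoryItem, ...]

    def __post_init__(self) -> None:
        names = [i.name for i in self.items]
        if len(names) != len(set(names)):
            raise ValueError("mandatory item names must be unique")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def for_type(self, record_type: str) -> tuple[MandatoryItem, ...]:
        return tuple(i for i in self.items if i.record_type == record_type)

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(
            "|".join(f"{i.module}:{i.name}:{i.record_type}" for i in self.items).encode()
        ).hexdigest()[:16]


#: Default 15-item catalog approximating the 2021 core-data-set base
#: modules Person, Treatment Case and Diagnosis. Site profiles differ;
#: the catalog is injected via config, this is only the documented default.
DEFAULT_CATALOG = MandatoryItemCatalog(
    items=(
        MandatoryItem("Person", "patient_id", "patient"),
        MandatoryItem("Person", "birth_date", "patient"),
        MandatoryItem("Person", "sex", "patient"),
        MandatoryItem("Person", "address_city", "patient"),
        MandatoryItem("Person", "address_postal_code", "patient"),
        MandatoryItem("Treatment Case", "case_id", "encounter"),
        MandatoryItem("Treatment Case", "patient_ref", "encounter"),
        MandatoryItem("Treatment Case", "admission_date", "encounter"),
        MandatoryItem("Treatment Case", "discharge_date", "encounter"),
        MandatoryItem("Treatment Case", "encounter_class", "encounter"),
        MandatoryItem("Diagnosis", "condition_id", "diagnosis"),
        MandatoryItem("Diagnosis", "case_ref", "diagnosis"),
        MandatoryItem("Diagnosis", "icd_code", "diagnosis"),
        MandatoryItem("Diagnosis", "diagnosis_date", "diagnosis"),
        MandatoryItem("Diagnosis", "diagnosis_role", "diagnosis"),
    )
)

_ITEM_GETTERS = {
    "patient_id": lambda r: r.patient_id,
    "birth_date": lambda r: r.birth_date,
    "sex": lambda r: r.sex,
    "address_city": lambda r: r.address_items.get("address_city"),
    "address_postal_code": lambda r: r.address_items.get("address_postal_code"),
    "case_id": lambda r: r.case_id,
    "patient_ref": lambda r: r.patient_id,
    "admission_date": lambda r: r.admission_date,
    "discharge_date": lambda r: r.discharge_date,
    "encounter_class": lambda r: r.encounter_class,
    "condition_id": lambda r: r.condition_id,
    "case_ref": lambda r: r.case_id,
    "icd_code": lambda r: r.icd_code,
    "diagnosis_date": lambda r: r.diagnosis_date,
    "diagnosis_role": lambda r: r.role,
}


def item_value(item: MandatoryItem, record) -> object | None:
    """Value of a mandatory item on a record, ``None`` when absent.

    Empty strings never occur here — readers map empty cells to ``None``.
    """
    getter = _ITEM_GETTERS.get(item.name)
    if getter is None:
        raise KeyError(f"mandatory item {item.name!r} is not mapped to a record field")
    return getter(record)


@dataclass
class CaseDataset:
    """Harmonized patients/encounters/diagnoses with provenance."""

    patients: list[PatientRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    item_catalog: MandatoryItemCatalog = DEFAULT_CATALOG
    provenance: str = ""
    total_inpatient_cases: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_inpatient_cases is not None and self.total_inpatient_cases <= 0:
            raise ValueError("total_inpatient_cases must be positive when given")

    @property
    def case_ids(self) -> set[str]:
        return {e.case_id for e in self.encounters}

    def orphan_diagnoses(self) -> list[DiagnosisRecord]:
        """Diagnoses whose case reference does not resolve in the dataset."""
        known = self.case_ids
        return [d for d in self.diagnoses if d.case_id is not None and d.case_id not in known]

    def sorted_copy(self) -> "CaseDataset":
        """Order-normalized copy, for comparing datasets from different readers."""
        return CaseDataset(
            patients=sorted(self.patients, key=lambda p: p.patient_id),
            encounters=sorted(self.encounters, key=lambda e: e.case_id),
            diagnoses=sorted(
                self.diagnoses,
                key=lambda d: (d.condition_id or "", d.case_id or "", d.icd_code or "", d.orphacode or 0),
            ),
            item_catalog=self.item_catalog,
            provenance=self.provenance,
            total_inpatient_cases=self.total_inpatient_cases,
        )
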