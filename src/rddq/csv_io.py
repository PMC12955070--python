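"""Reader for PAS-style CSV exports (one row per documented diagnosis)."""

from __future__ import annotations

import io
from pathlib import Path
from typing import TextIO

import pandas as pd

from .config import DEFAULT_CSV_SCHEMA
from .model import (
    CaseDataset,
    DiagnosisRecord,
    EncounterRecord,
    MandatoryItemCatalog,
    PatientRecord,
    normalize_date,
)
from .terminology import normalize_icd, normalize_orphacode

__all__ = ["SchemaError", "read_pas_csv"]

#: Columns that must exist for rows to be attributable at all.
_MANDATED = ("patient_id", "case_id")


class SchemaError(ValueError):
    """The CSV header does not provide the mandated columns."""


def _cell(row, col: str | None) -> str | None:
    if col is None:
        return None
    value = row.get(col)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_pas_csv(
    source: str | Path | TextIO,
    schema: dict[str, str] | None = None,
    catalog: MandatoryItemCatalog | None = None,
    provenance: str = "EXP",
    total_inpatient_cases: int | None = None,
) -> CaseDataset:
    """Read a pseudonymized PAS export into a :class:`CaseDataset`.

    ``schema`` maps semantic field names (the keys of
    :data:`rddq.config.DEFAULT_CSV_SCHEMA`) to the column headers of the
    concrete export. Patients and encounters are deduplicated by
    identifier; conflicting repeated attributes keep the first-seen value
    and are counted as warnings. Empty cells become absent values.
    """
    schema = dict(DEFAULT_CSV_SCHEMA) | (schema or {})
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source, dtype=str, keep_default_na=True)
    else:
        frame = pd.read_csv(io.StringIO(source.read()), dtype=str, keep_default_na=True)

    header = set(frame.columns)
    cols = {field: (col if col in header else None) for field, col in schema.items()}
    missing = [schema[f] for f in _MANDATED if cols[f] is None]
    if missing:
        raise SchemaError(f"missing mandated columns: {missing}")
    if cols["icd_code"] is None and cols["orphacode"] is None:
        raise SchemaError("need at least one diagnosis code column (icd_code or orphacode)")

    patients: dict[str, PatientRecord] = {}
    encounters: dict[str, EncounterRecord] = {}
    diagnoses: list[DiagnosisRecord] = []
    warnings: list[str] = []

    for idx, row in enumerate(frame.to_dict(orient="records"), start=2):
        patient_id = _cell(row, cols["patient_id"])
        case_id = _cell(row, cols["case_id"])
        if patient_id is None or case_id is None:
            warnings.append(f"row {idx}: missing patient_id/case_id, row skipped")
            continue

        birth = normalize_date(_cell(row, cols["birth_date"]))
        sex = _cell(row, cols["sex"])
        address = {}
        for item in ("address_city", "address_postal_code"):
            value = _cell(row, cols[item])
            if value is not None:
                address[item] = value
        patient = PatientRecord(patient_id, birth_date=birth, sex=sex, address_items=address)
        seen = patients.get(patient_id)
        if seen is None:
            patients[patient_id] = patient
        elif (seen.birth_date, seen.sex) != (birth, sex) and (birth or sex):
            if (birth and seen.birth_date and birth != seen.birth_date) or (
                sex and seen.sex and sex != seen.sex
            ):
                warnings.append(f"row {idx}: conflicting attributes for patient {patient_id}, first-seen kept")
            else:  # fill attributes the first row left empty
                patients[patient_id] = PatientRecord(
                    patient_id,
                    birth_date=seen.birth_date or birth,
                    sex=seen.sex or sex,
                    address_items={**address, **seen.address_items},
                )

        admission = normalize_date(_cell(row, cols["admission_date"]))
        discharge = normalize_date(_cell(row, cols["discharge_date"]))
        enc_class = _cell(row, cols["encounter_class"])
        encounter = EncounterRecord(
            case_id,
            patient_id=patient_id,
            admission_date=admission,
            discharge_date=discharge,
            encounter_class=enc_class,
        )
        seen_enc = encounters.get(case_id)
        if seen_enc is None:
            encounters[case_id] = encounter
        elif (seen_enc.admission_date, seen_enc.discharge_date) != (admission, discharge) and (
            admission or discharge
        ):
            if (admission and seen_enc.admission_date and admission != seen_enc.admission_date) or (
                discharge and seen_enc.discharge_date and discharge != seen_enc.discharge_date
            ):
                warnings.append(f"row {idx}: conflicting dates for case {case_id}, first-seen kept")

        icd, _marker = normalize_icd(_cell(row, cols["icd_code"]) or "")
        raw_orpha = _cell(row, cols["orphacode"])
        try:
            orpha = normalize_orphacode(raw_orpha)
        except ValueError:
            orpha = None
            warnings.append(f"row {idx}: unparseable Orphacode {raw_orpha!r}")
        role = _cell(row, cols["diagnosis_role"])
        if role is not None:
            role = role.lower()
            if role not in ("primary", "secondary"):
                role = None
        if icd is None and orpha is None:
            warnings.append(f"row {idx}: diagnosis without ICD code or Orphacode")
        diagnoses.append(
            DiagnosisRecord(
                case_id=case_id,
                patient_id=patient_id,
                condition_id=_cell(row, cols["diagnosis_id"]),
                icd_code=icd,
                orphacode=orpha,
                diagnosis_date=normalize_date(_cell(row, cols["diagnosis_date"])),
                role=role,
            )
        )

    kwargs = {} if catalog is None else {"item_catalog": catalog}
    return CaseDataset(
        patients=list(patients.values()),
        encounters=list(encounters.values()),
        diagnoses=diagnoses,
        provenance=provenance,
        total_inpatient_cases=total_inpatient_cases,
        warnings=warnings,
        **kwargs,
    )
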