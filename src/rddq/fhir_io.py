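"""FHIR R4 input: NDJSON files and paged REST retrieval.

Only the three MII core-data-set profiles used for rare-disease quality
assessment are consumed — Patient (Person module), Encounter (Treatment
Case) and Condition (Diagnosis). Resources are plain JSON objects; no
StructureDefinition validation is attempted (out of scope), unknown
resource types are counted and skipped.
"""

from __future__ import annotations

import concurrent.futures
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Iterable, TextIO

from .config import ICD10GM_SYSTEM, ORPHANET_SYSTEM
from .model import (
    CaseDataset,
    DiagnosisRecord,
    EncounterRecord,
    MandatoryItemCatalog,
    PatientRecord,
    normalize_date,
)
from .terminology import normalize_icd, normalize_orphacode

__all__ = ["FhirFormatError", "FhirFetchError", "read_fhir_ndjson", "fetch_fhir"]


class FhirFormatError(ValueError):
    """No usable FHIR resources could be extracted from the input."""


class FhirFetchError(RuntimeError):
    """A page could not be retrieved within the retry budget."""


def _ref_id(ref: dict | None) -> str | None:
    """Logical id from a FHIR reference: ``{"reference": "Patient/p1"}`` → ``p1``."""
    if not ref:
        return None
    text = ref.get("reference")
    if not text:
        return None
    return text.rsplit("/", 1)[-1] or None


def _parse_patient(res: dict) -> PatientRecord:
    address = {}
    for addr in res.get("address") or []:
        if "city" in addr and "address_city" not in address:
            address["address_city"] = addr["city"]
        if "postalCode" in addr and "address_postal_code" not in address:
            address["address_postal_code"] = addr["postalCode"]
    return PatientRecord(
        patient_id=res.get("id") or "",
        birth_date=normalize_date(res.get("birthDate")),
        sex=res.get("gender"),
        address_items=address,
    )


def _parse_encounter(res: dict) -> EncounterRecord:
    period = res.get("period") or {}
    klass = res.get("class") or {}
    if isinstance(klass, list):  # R5 shape, tolerated
        klass = (klass[0].get("coding") or [{}])[0] if klass else {}
    return EncounterRecord(
        case_id=res.get("id") or "",
        patient_id=_ref_id(res.get("subject")),
        admission_date=normalize_date(period.get("start")),
        discharge_date=normalize_date(period.get("end")),
        encounter_class=klass.get("code"),
    )


def _parse_condition(res: dict, icd_system: str, orpha_system: str, warnings: list[str]) -> DiagnosisRecord:
    icd = None
    orpha = None
    for coding in (res.get("code") or {}).get("coding") or []:
        system = coding.get("system") or ""
        code = coding.get("code")
        if code is None:
            continue
        if system == icd_system and icd is None:
            icd, _ = normalize_icd(code)
        elif system == orpha_system and orpha is None:
            try:
                orpha = normalize_orphacode(code)
            except ValueError:
                warnings.append(f"Condition {res.get('id')}: unparseable Orphacode {code!r}")
    role = None
    for category in res.get("category") or []:
        for coding in category.get("coding") or []:
            if coding.get("code") in ("primary", "secondary"):
                role = coding["code"]
    return DiagnosisRecord(
        case_id=_ref_id(res.get("encounter")),
        patient_id=_ref_id(res.get("subject")),
        condition_id=res.get("id"),
        icd_code=icd,
        orphacode=orpha,
        diagnosis_date=normalize_date(res.get("recordedDate")),
        role=role,
    )


def _assemble(
    resources: Iterable[dict],
    warnings: list[str],
    icd_system: str,
    orpha_system: str,
    catalog: MandatoryItemCatalog | None,
    provenance: str,
    total_inpatient_cases: int | None,
) -> CaseDataset:
    patients: dict[str, PatientRecord] = {}
    encounters: dict[str, EncounterRecord] = {}
    diagnoses: list[DiagnosisRecord] = []
    skipped: dict[str, int] = {}
    usable = 0
    for res in resources:
        rtype = res.get("resourceType")
        if rtype == "Patient":
            p = _parse_patient(res)
            patients.setdefault(p.patient_id, p)
            usable += 1
        elif rtype == "Encounter":
            e = _parse_encounter(res)
            encounters.setdefault(e.case_id, e)
            usable += 1
        elif rtype == "Condition":
            diagnoses.append(_parse_condition(res, icd_system, orpha_system, warnings))
            usable += 1
        else:
            skipped[str(rtype)] = skipped.get(str(rtype), 0) + 1
    for rtype, count in sorted(skipped.items()):
        warnings.append(f"skipped {count} resources of unknown type {rtype}")
    if usable == 0:
        raise FhirFormatError("no usable Patient/Encounter/Condition resources found")
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


def _iter_ndjson(streams, warnings: list[str]):
    for stream in streams:
        close = False
        if isinstance(stream, (str, Path)):
            name = str(stream)
            stream = open(stream, "r", encoding="utf-8")
            close = True
        else:
            name = getattr(stream, "name", "<stream>")
        try:
            for lineno, line in enumerate(stream, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    warnings.append(f"{name}:{lineno}: unparseable JSON ({exc.msg})")
                    continue
                if obj.get("resourceType") == "Bundle":
                    for entry in obj.get("entry") or []:
                        if entry.get("resource"):
                            yield entry["resource"]
                else:
                    yield obj
        finally:
            if close:
                stream.close()


def read_fhir_ndjson(
    streams: Iterable[str | Path | TextIO] | str | Path | TextIO,
    icd_system: str = ICD10GM_SYSTEM,
    orpha_system: str = ORPHANET_SYSTEM,
    catalog: MandatoryItemCatalog | None = None,
    provenance: str = "FHIR",
    total_inpatient_cases: int | None = None,
) -> CaseDataset:
    """Read newline-delimited FHIR resources (Bundles are unwrapped).

    ``Condition.code`` codings are split by coding-system URL into the ICD
    code and the Orphacode. Unparseable lines are collected as warnings
    with their line number; zero usable resources is a format error.
    """
    if isinstance(streams, (str, Path)) or hasattr(streams, "read"):
        streams = [streams]
    warnings: list[str] = []
    return _assemble(
        _iter_ndjson(streams, warnings),
        warnings,
        icd_system,
        orpha_system,
        catalog,
        provenance,
        total_inpatient_cases,
    )


def _get_json(url: str, token: str | None, timeout: float) -> dict:
    request = urllib.request.Request(url, headers={"Accept": "application/fhir+json"})
    if token:
        request.add_header("Authorization", f"Bearer {token}")
    with urllib.request.urlopen(request, timeout=timeout) as response:
        return json.loads(response.read().decode("utf-8"))


def _fetch_page(url: str, token: str | None, retries: int, timeout: float) -> dict:
    last: Exception | None = None
    for attempt in range(retries + 1):
        try:
            return _get_json(url, token, timeout)
        except (urllib.error.URLError, json.JSONDecodeError, OSError) as exc:
            last = exc
            if attempt < retries:
                time.sleep(0.05 * (attempt + 1))
    raise FhirFetchError(f"page {url} failed after {retries + 1} attempts: {last}")


def fetch_fhir(
    endpoint: str,
    resource_types: tuple[str, ...] = ("Patient", "Encounter", "Condition"),
    query: dict[str, str] | None = None,
    page_size: int = 100,
    workers: int = 1,
    retries: int = 2,
    token: str | None = None,
    timeout: float = 30.0,
    icd_system: str = ICD10GM_SYSTEM,
    orpha_system: str = ORPHANET_SYSTEM,
    catalog: MandatoryItemCatalog | None = None,
    provenance: str = "FHIR",
    total_inpatient_cases: int | None = None,
) -> CaseDataset:
    """Retrieve all pages of the three resource searches from a FHIR server.

    With ``workers > 1`` the remaining pages of each search are fetched
    concurrently by page offset; the merge is keyed by resource id, so the
    result is identical to the strictly sequential ``workers=1`` mode.
    Transient page failures are retried ``retries`` times before a hard
    :class:`FhirFetchError` naming the page.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    base = endpoint.rstrip("/")
    resources: dict[tuple[str, str], dict] = {}
    warnings: list[str] = []

    def page_url(rtype: str, offset: int) -> str:
        params = {"_count": str(page_size), "_getpagesoffset": str(offset)}
        params.update(query or {})
        return f"{base}/{rtype}?{urllib.parse.urlencode(params)}"

    def ingest(bundle: dict) -> int:
        n = 0
        for entry in bundle.get("entry") or []:
            res = entry.get("resource")
            if res:
                resources[(res.get("resourceType", "?"), str(res.get("id")))] = res
                n += 1
        return n

    for rtype in resource_types:
        first = _fetch_page(page_url(rtype, 0), token, retries, timeout)
        got = ingest(first)
        total = first.get("total")
        if total is None:
            # no total: follow next links sequentially
            bundle = first
            while True:
                next_url = next(
                    (l.get("url") for l in bundle.get("link") or [] if l.get("relation") == "next"),
                    None,
                )
                if not next_url:
                    break
                bundle = _fetch_page(next_url, token, retries, timeout)
                got += ingest(bundle)
            continue
        offsets = list(range(page_size, int(total), page_size))
        if workers == 1:
            pages = [_fetch_page(page_url(rtype, off), token, retries, timeout) for off in offsets]
        else:
            with concurrent.futures.ThreadPoolExecutor(max_workers=workers) as pool:
                pages = list(
                    pool.map(lambda off: _fetch_page(page_url(rtype, off), token, retries, timeout), offsets)
                )
        for bundle in pages:
            if bundle.get("total") is not None and int(bundle["total"]) != int(total):
                warnings.append(
                    f"{rtype}: inconsistent total across pages ({bundle['total']} != {total})"
                )
            got += ingest(bundle)
        if got != int(total):
            warnings.append(f"{rtype}: retrieved {got} resources, server reported total {total}")

    ordered = [resources[key] for key in sorted(resources)]
    return _assemble(
        ordered,
        warnings,
        icd_system,
        orpha_system,
        catalog,
        provenance,
        total_inpatient_cases,
    )
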