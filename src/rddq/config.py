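"""Structured run configuration.

Everything a site might need to adapt — CSV column map, coding-system
URLs, the mandatory-item catalog, outlier rules, the k-anonymity
threshold — is carried here; there are no hidden constants in the engine.
Precedence for the CLI is flags > config file > these defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import DEFAULT_CATALOG, MandatoryItem, MandatoryItemCatalog

__all__ = ["OutlierRuleSet", "RunConfig", "load_config", "DEFAULT_CSV_SCHEMA"]

#: Default CSV header → semantic field map for PAS-style exports.
#: Address and encounter-class columns are optional in real exports;
#: absent columns simply yield absent values (item-level findings).
DEFAULT_CSV_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "case_id": "case_id",
    "admission_date": "admission_date",
    "discharge_date": "discharge_date",
    "birth_date": "birth_date",
    "sex": "sex",
    "address_city": "address_city",
    "address_postal_code": "address_postal_code",
    "encounter_class": "encounter_class",
    "diagnosis_id": "diagnosis_id",
    "icd_code": "icd_code",
    "orphacode": "orphacode",
    "diagnosis_date": "diagnosis_date",
    "diagnosis_role": "diagnosis_role",
}

#: German modification ICD-10 code system and Orphanet code system URLs
#: as used in MII core-data-set Condition resources.
ICD10GM_SYSTEM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
ORPHANET_SYSTEM = "http://www.orpha.net"

_RULE_FIELDS = {"age_at_admission", "date_order", "code_characters", "birth_before_reference"}


@dataclass(frozen=True)
class OutlierRuleSet:
    """Range/syntax plausibility rules applied to present values.

    Absent values are never outliers — they are completeness findings.
    """

    max_age_years: int = 130
    check_date_order: bool = True
    #: characters allowed in an ICD code field; anything else is a
    #: special-character finding
    code_allowed_chars: str = r"^[A-Z0-9.!+*\-]+$"
    reference_date: str = "2022-12-31"
    enabled: tuple[str, ...] = (
        "age_at_admission",
        "date_order",
        "code_characters",
        "birth_before_reference",
    )

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - _RULE_FIELDS
        if unknown:
            raise ValueError(f"outlier rules reference unknown fields: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Effective configuration of one assessment run."""

    csv_schema: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CSV_SCHEMA))
    icd_system: str = ICD10GM_SYSTEM
    orpha_system: str = ORPHANET_SYSTEM
    catalog: MandatoryItemCatalog = DEFAULT_CATALOG
    outlier_rules: OutlierRuleSet = field(default_factory=OutlierRuleSet)
    #: k-anonymity threshold for the violations report
    k: int = 5
    #: parallel FHIR page fetch width; 1 = strictly sequential
    workers: int = 1
    #: enable ambiguity rule (b): implausible Orphacode on a multi-Orphacode ICD
    ambiguous_rule_b: bool = True
    total_inpatient_cases: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def fingerprint(self) -> str:
        payload = {
            "csv_schema": self.csv_schema,
            "icd_system": self.icd_system,
            "orpha_system": self.orpha_system,
            "catalog": [[i.module, i.name, i.record_type] for i in self.catalog],
            "outlier_rules": dataclasses.asdict(self.outlier_rules),
            "k": self.k,
            "ambiguous_rule_b": self.ambiguous_rule_b,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _catalog_from_obj(obj) -> MandatoryItemCatalog:
    return MandatoryItemCatalog(
        items=tuple(MandatoryItem(i["module"], i["name"], i["record_type"]) for i in obj)
    )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file over the defaults, then apply overrides.

    Unknown top-level keys are rejected so typos surface as errors.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
    if "catalog" in data:
        data["catalog"] = _catalog_from_obj(data["catalog"])
    if "outlier_rules" in data:
        rules = data["outlier_rules"]
        if "enabled" in rules:
            rules["enabled"] = tuple(rules["enabled"])
        data["outlier_rules"] = OutlierRuleSet(**rules)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
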