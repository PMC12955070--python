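"""Data-quality engine: issue detection, the 13 parameters, the 7 indicators.

Parameters (absolute counts)
    P1  rdCase        treatment cases documented with an Orphacode or a tracer
    P2  orphaCase     cases diagnosed using an Orphacode
    P3  tracerCase    cases diagnosed using a tracer ICD-10-GM code
    P4-6              P1-P3 normalized to 100,000 inpatient cases
    P7  im_misg       mandatory data items missing from the dataset
    P8  vm_misg       mandatory data values missing from individual records
    P9  vo            outlier values (range / syntax plausibility)
    P10 oc_misg       tracer diagnoses lacking an Orphacode
    P11 link_ip       (ICD, Orphacode) pairs not found in the terminology
    P12 rdCase_dup    surplus duplicate case records
    P13 rdCase_amb    RD cases with an ambiguous diagnosis

Indicators (0-100%), grouped into completeness / plausibility / uniqueness:
each is ``100 * (1 - issues / denominator)`` over the population the issue
category draws from; a zero denominator makes the indicator *vacuous* and
it reports 0 with its evaluability flag cleared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .config import OutlierRuleSet, RunConfig
from .model import CaseDataset, MandatoryItemCatalog, item_value, parse_partial_date
from .terminology import AlphaTerminology, TracerSet, check_link, orpha_candidates

import re

__all__ = [
    "DqIssue",
    "DqParameterSet",
    "Indicator",
    "DqIndicatorSet",
    "CaseFlags",
    "classify_cases",
    "relative_frequencies",
    "detect_missing_items",
    "detect_missing_values",
    "detect_outliers",
    "detect_missing_orphacodes",
    "detect_implausible_links",
    "detect_duplicates",
    "detect_ambiguous",
    "compute_indicators",
    "assess",
]

ISSUE_CATEGORIES = (
    "missing_item",
    "missing_value",
    "outlier",
    "missing_orphacode",
    "implausible_link",
    "duplicate_case",
    "ambiguous_case",
)

PARAMETER_NAMES = {
    1: "rdCase",
    2: "orphaCase",
    3: "tracerCase",
    4: "rdCase_rel",
    5: "orphaCase_rel",
    6: "tracerCase_rel",
    7: "im_misg",
    8: "vm_misg",
    9: "vo",
    10: "oc_misg",
    11: "link_ip",
    12: "rdCase_dup",
    13: "rdCase_amb",
}


@dataclass(frozen=True)
class DqIssue:
    """One detected data-quality finding."""

    category: str
    record_type: str
    record_ids: tuple[str, ...]
    detail: str
    #: grouping value for k-anonymous reporting (e.g. the ICD code)
    group_key: str
    patient_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in ISSUE_CATEGORIES:
            raise ValueError(f"unknown issue category {self.category!r}")


@dataclass
class DqParameterSet:
    """The 13 counting parameters plus the denominators the indicators need."""

    rd_cases: int = 0  # P1
    orpha_cases: int = 0  # P2
    tracer_cases: int = 0  # P3
    rd_cases_rel: int | None = None  # P4
    orpha_cases_rel: int | None = None  # P5
    tracer_cases_rel: int | None = None  # P6
    missing_items: int = 0  # P7
    missing_values: int = 0  # P8
    outliers: int = 0  # P9
    missing_orphacodes: int = 0  # P10
    implausible_links: int = 0  # P11
    duplicate_cases: int = 0  # P12
    ambiguous_cases: int = 0  # P13
    # denominators
    n_mandatory_items: int = 0
    n_value_slots: int = 0
    n_checked_values: int = 0
    n_tracer_diagnoses: int = 0
    n_linked_diagnoses: int = 0
    n_case_records: int = 0
    total_inpatient_cases: int | None = None
    #: comparability fingerprint (terminology + tracer set + catalog)
    fingerprint: str | None = None

    def __post_init__(self) -> None:
        counts = [
            self.rd_cases, self.orpha_cases, self.tracer_cases,
            self.missing_items, self.missing_values, self.outliers,
            self.missing_orphacodes, self.implausible_links,
            self.duplicate_cases, self.ambiguous_cases,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("parameter counts must be non-negative")
        if not (max(self.orpha_cases, self.tracer_cases) <= self.rd_cases
                <= self.orpha_cases + self.tracer_cases):
            raise ValueError(
                "inconsistent case counts: max(P2,P3) <= P1 <= P2+P3 must hold"
            )

    def as_vector(self) -> dict[int, int | None]:
        """P-number → value mapping (P4-P6 may be absent)."""
        return {
            1: self.rd_cases,
            2: self.orpha_cases,
            3: self.tracer_cases,
            4: self.rd_cases_rel,
            5: self.orpha_cases_rel,
            6: self.tracer_cases_rel,
            7: self.missing_items,
            8: self.missing_values,
            9: self.outliers,
            10: self.missing_orphacodes,
            11: self.implausible_links,
            12: self.duplicate_cases,
            13: self.ambiguous_cases,
        }

    @property
    def issue_total(self) -> int:
        """Total detected issues, P7 through P13."""
        return (
            self.missing_items + self.missing_values + self.outliers
            + self.missing_orphacodes + self.implausible_links
            + self.duplicate_cases + self.ambiguous_cases
        )


@dataclass(frozen=True)
class Indicator:
    value: float
    evaluable: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"indicator value {self.value} outside [0, 100]")


@dataclass(frozen=True)
class DqIndicatorSet:
    """The seven normalized indicators on the 0-100% scale."""

    dqi_co_ocr: Indicator  # Orphacoding completeness rate
    dqi_co_icr: Indicator  # item completeness rate
    dqi_co_vcr: Indicator  # value completeness rate
    dqi_pl_opr: Indicator  # Orphacoding plausibility rate
    dqi_pl_rpr: Indicator  # range plausibility rate
    dqi_un_cur: Indicator  # RD case unambiguity rate
    dqi_un_cdr: Indicator  # RD case dissimilarity rate

    def as_dict(self) -> dict[str, Indicator]:
        return {
            "dqi_co_ocr": self.dqi_co_ocr,
            "dqi_co_icr": self.dqi_co_icr,
            "dqi_co_vcr": self.dqi_co_vcr,
            "dqi_pl_opr": self.dqi_pl_opr,
            "dqi_pl_rpr": self.dqi_pl_rpr,
            "dqi_un_cur": self.dqi_un_cur,
            "dqi_un_cdr": self.dqi_un_cdr,
        }


@dataclass
class CaseFlags:
    """Per-case RD classification."""

    orpha: set[str] = field(default_factory=set)
    tracer: set[str] = field(default_factory=set)

    @property
    def rd(self) -> set[str]:
        return self.orpha | self.tracer


def _case_patients(ds: CaseDataset) -> dict[str, tuple[str, ...]]:
    by_case: dict[str, set[str]] = {}
    for d in ds.diagnoses:
        if d.case_id and d.patient_id:
            by_case.setdefault(d.case_id, set()).add(d.patient_id)
    return {c: tuple(sorted(p)) for c, p in by_case.items()}


def classify_cases(ds: CaseDataset, tracers: TracerSet) -> CaseFlags:
    """Flag each case as Orpha / tracer / RD from its diagnoses (P1-P3).

    A case is an Orpha case iff at least one of its diagnoses carries an
    Orphacode, a tracer case iff at least one diagnosis ICD is a tracer,
    and an RD case iff either holds. Counting is over distinct case ids;
    diagnoses without a case reference cannot be attributed and are left
    to the orphan-record flagging of the dataset.
    """
    flags = CaseFlags()
    for d in ds.diagnoses:
        if d.case_id is None:
            continue
        if d.orphacode is not None:
            flags.orpha.add(d.case_id)
        if d.icd_code is not None and d.icd_code in tracers:
            flags.tracer.add(d.case_id)
    return flags


def _round_half_up(value: float) -> int:
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def relative_frequencies(
    rd_cases: int, orpha_cases: int, tracer_cases: int, total_inpatient_cases: int
) -> tuple[int, int, int]:
    """P4-P6: case counts per 100,000 inpatient cases, rounded half-up."""
    if total_inpatient_cases <= 0:
        raise ValueError("total_inpatient_cases must be positive")
    return tuple(
        _round_half_up(100_000 * count / total_inpatient_cases)
        for count in (rd_cases, orpha_cases, tracer_cases)
    )


def detect_missing_items(
    ds: CaseDataset, catalog: MandatoryItemCatalog
) -> tuple[list[DqIssue], int]:
    """P7: mandatory items for which *no* record carries any value."""
    records_by_type = {
        "patient": ds.patients,
        "encounter": ds.encounters,
        "diagnosis": ds.diagnoses,
    }
    issues = []
    for item in catalog:
        records = records_by_type[item.record_type]
        if not any(item_value(item, r) is not None for r in records):
            issues.append(
                DqIssue(
                    category="missing_item",
                    record_type=item.record_type,
                    record_ids=(),
                    detail=f"mandatory item '{item.name}' ({item.module}) absent from the dataset",
                    group_key=item.name,
                )
            )
    return issues, len(issues)


def _record_key(record_type: str, record) -> str:
    if record_type == "patient":
        return record.patient_id
    if record_type == "encounter":
        return record.case_id
    return record.condition_id or f"{record.case_id}:{record.icd_code}"


def _record_patients(record_type: str, record) -> tuple[str, ...]:
    pid = record.patient_id if record_type != "patient" else record.patient_id
    return (pid,) if pid else ()


def detect_missing_values(
    ds: CaseDataset, catalog: MandatoryItemCatalog
) -> tuple[list[DqIssue], int, int]:
    """P8: absent values in item-present slots; returns (issues, P8, slots).

    Items that are missing from the dataset altogether (P7) contribute no
    value slots — those are item-level, not value-level, findings.
    """
    item_issues, _ = detect_missing_items(ds, catalog)
    wholly_missing = {i.group_key for i in item_issues}
    records_by_type = {
        "patient": ds.patients,
        "encounter": ds.encounters,
        "diagnosis": ds.diagnoses,
    }
    issues = []
    slots = 0
    for item in catalog:
        if item.name in wholly_missing:
            continue
        for record in records_by_type[item.record_type]:
            slots += 1
            if item_value(item, record) is None:
                issues.append(
                    DqIssue(
                        category="missing_value",
                        record_type=item.record_type,
                        record_ids=(_record_key(item.record_type, record),),
                        detail=f"mandatory value '{item.name}' missing",
                        group_key=item.name,
                        patient_ids=_record_patients(item.record_type, record),
                    )
                )
    return issues, len(issues), slots


def detect_outliers(
    ds: CaseDataset, rules: OutlierRuleSet
) -> tuple[list[DqIssue], int, int]:
    """P9: values violating range/syntax rules; returns (issues, P9, checked).

    Each rule evaluation on present values counts toward the checked-value
    denominator; absent values are never checked.
    """
    issues: list[DqIssue] = []
    checked = 0
    births = {p.patient_id: parse_partial_date(p.birth_date) for p in ds.patients}
    reference = parse_partial_date(rules.reference_date)
    code_pattern = re.compile(rules.code_allowed_chars)

    if "birth_before_reference" in rules.enabled and reference is not None:
        for p in ds.patients:
            birth = births.get(p.patient_id)
            if birth is None:
                continue
            checked += 1
            if birth > reference:
                issues.append(
                    DqIssue(
                        "outlier", "patient", (p.patient_id,),
                        f"birth date {p.birth_date} after reference date {rules.reference_date}",
                        group_key="birth_before_reference",
                        patient_ids=(p.patient_id,),
                    )
                )
    for e in ds.encounters:
        admission = parse_partial_date(e.admission_date)
        discharge = parse_partial_date(e.discharge_date)
        if "age_at_admission" in rules.enabled:
            birth = births.get(e.patient_id) if e.patient_id else None
            if birth is not None and admission is not None:
                checked += 1
                age = (admission - birth).days / 365.25
                if age > rules.max_age_years:
                    issues.append(
                        DqIssue(
                            "outlier", "encounter", (e.case_id,),
                            f"age at admission {age:.0f} exceeds {rules.max_age_years}",
                            group_key="age_at_admission",
                            patient_ids=(e.patient_id,) if e.patient_id else (),
                        )
                    )
        if "date_order" in rules.enabled and admission is not None and discharge is not None:
            checked += 1
            if discharge < admission:
                issues.append(
                    DqIssue(
                        "outlier", "encounter", (e.case_id,),
                        f"discharge {e.discharge_date} before admission {e.admission_date}",
                        group_key="date_order",
                        patient_ids=(e.patient_id,) if e.patient_id else (),
                    )
                )
    if "code_characters" in rules.enabled:
        for d in ds.diagnoses:
            if d.icd_code is None:
                continue
            checked += 1
            if not code_pattern.match(d.icd_code):
                issues.append(
                    DqIssue(
                        "outlier", "diagnosis", (_record_key("diagnosis", d),),
                        f"disallowed characters in code field {d.icd_code!r}",
                        group_key="code_characters",
                        patient_ids=(d.patient_id,) if d.patient_id else (),
                    )
                )
    return issues, len(issues), checked


def detect_missing_orphacodes(
    ds: CaseDataset, tracers: TracerSet
) -> tuple[list[DqIssue], int, int]:
    """P10: tracer diagnoses lacking an Orphacode; returns (issues, P10, n_tracer_dx)."""
    issues = []
    n_tracer = 0
    for d in ds.diagnoses:
        if d.icd_code is None or d.icd_code not in tracers:
            continue
        n_tracer += 1
        if d.orphacode is None:
            issues.append(
                DqIssue(
                    "missing_orphacode", "diagnosis", (_record_key("diagnosis", d),),
                    f"tracer diagnosis {d.icd_code} without Orphacode",
                    group_key=d.icd_code,
                    patient_ids=(d.patient_id,) if d.patient_id else (),
                )
            )
    return issues, len(issues), n_tracer


def detect_implausible_links(
    ds: CaseDataset, term: AlphaTerminology
) -> tuple[list[DqIssue], int, int]:
    """P11: (ICD, Orphacode) pairs absent from the terminology; returns (issues, P11, n_linked)."""
    issues = []
    n_linked = 0
    for d in ds.diagnoses:
        if d.icd_code is None or d.orphacode is None:
            continue
        n_linked += 1
        if check_link(term, d.icd_code, d.orphacode) == "implausible":
            issues.append(
                DqIssue(
                    "implausible_link", "diagnosis", (_record_key("diagnosis", d),),
                    f"combination {d.icd_code} / Orpha:{d.orphacode} not found in terminology",
                    group_key=d.icd_code,
                    patient_ids=(d.patient_id,) if d.patient_id else (),
                )
            )
    return issues, len(issues), n_linked


def detect_duplicates(ds: CaseDataset) -> tuple[list[DqIssue], int]:
    """P12: surplus records among identical (case, patient, ICD, Orphacode) rows.

    Each group of g identical diagnosis-bearing case records contributes
    g - 1 — the number of removable records.
    """
    groups: dict[tuple, list] = {}
    for d in ds.diagnoses:
        key = (d.case_id, d.patient_id, d.icd_code, d.orphacode)
        groups.setdefault(key, []).append(d)
    issues = []
    for key, members in groups.items():
        for surplus in members[1:]:
            issues.append(
                DqIssue(
                    "duplicate_case", "diagnosis",
                    (_record_key("diagnosis", surplus),),
                    f"duplicate case record (case {key[0]}, ICD {key[2]}, Orpha {key[3]})",
                    group_key=str(key[2]),
                    patient_ids=(key[1],) if key[1] else (),
                )
            )
    return issues, len(issues)


def detect_ambiguous(
    ds: CaseDataset,
    term: AlphaTerminology,
    tracers: TracerSet,
    rule_b: bool = True,
) -> tuple[list[DqIssue], int]:
    """P13: RD cases whose diagnoses leave the rare disease ambiguous.

    Rule (a): a tracer diagnosis without an Orphacode whose ICD code has
    more than one candidate Orphacode (the code subsumes several RDs and
    nothing disambiguates them — e.g. F84.2 without Orpha:778/3095).
    Rule (b), switchable: a recorded (ICD, Orphacode) pair on a
    multi-Orphacode ICD where the Orphacode is not among the candidates,
    so the implausible link fails to pin down which RD is meant.
    A case counts once however many diagnoses trigger.
    """
    flags = classify_cases(ds, tracers)
    case_patients = _case_patients(ds)
    ambiguous: dict[str, str] = {}
    for d in ds.diagnoses:
        if d.case_id is None or d.case_id not in flags.rd or d.icd_code is None:
            continue
        candidates = orpha_candidates(term, d.icd_code)
        if len(candidates) <= 1:
            continue
        triggered = False
        if d.orphacode is None and d.icd_code in tracers:
            triggered = True  # rule (a)
        elif rule_b and d.orphacode is not None and d.orphacode not in candidates:
            triggered = True  # rule (b)
        if triggered and d.case_id not in ambiguous:
            ambiguous[d.case_id] = d.icd_code
    issues = [
        DqIssue(
            "ambiguous_case", "encounter", (case_id,),
            f"RD case with ambiguous diagnosis (ICD {icd})",
            group_key=icd,
            patient_ids=case_patients.get(case_id, ()),
        )
        for case_id, icd in sorted(ambiguous.items())
    ]
    return issues, len(issues)


def _ratio_indicator(count: int, denominator: int) -> Indicator:
    if count < 0 or denominator < 0:
        raise ValueError("indicator inputs must be non-negative")
    if denominator == 0:
        return Indicator(0.0, evaluable=False)
    value = 100.0 * (1.0 - count / denominator)
    return Indicator(min(100.0, max(0.0, value)))


def compute_indicators(params: DqParameterSet) -> DqIndicatorSet:
    """Normalize the issue counts into the seven 0-100% indicators.

    A zero denominator (e.g. no tracer diagnoses at all) makes the
    indicator vacuous: value 0, evaluable flag cleared.
    """
    return DqIndicatorSet(
        dqi_co_ocr=_ratio_indicator(params.missing_orphacodes, params.n_tracer_diagnoses),
        dqi_co_icr=_ratio_indicator(params.missing_items, params.n_mandatory_items),
        dqi_co_vcr=_ratio_indicator(params.missing_values, params.n_value_slots),
        dqi_pl_opr=_ratio_indicator(params.implausible_links, params.n_linked_diagnoses),
        dqi_pl_rpr=_ratio_indicator(params.outliers, params.n_checked_values),
        dqi_un_cur=_ratio_indicator(params.ambiguous_cases, params.rd_cases),
        dqi_un_cdr=_ratio_indicator(params.duplicate_cases, params.n_case_records),
    )


def assess(
    ds: CaseDataset,
    term: AlphaTerminology,
    tracers: TracerSet,
    config: RunConfig | None = None,
) -> tuple[DqParameterSet, DqIndicatorSet, list[DqIssue]]:
    """Run the full single-dataset assessment.

    Returns the parameter set, the indicator set and the flat issue list;
    ``len(issues) == P7 + ... + P13`` always holds.
    """
    config = config or RunConfig()
    catalog = ds.item_catalog
    flags = classify_cases(ds, tracers)

    item_issues, p7 = detect_missing_items(ds, catalog)
    value_issues, p8, n_slots = detect_missing_values(ds, catalog)
    outlier_issues, p9, n_checked = detect_outliers(ds, config.outlier_rules)
    orpha_issues, p10, n_tracer_dx = detect_missing_orphacodes(ds, tracers)
    link_issues, p11, n_linked = detect_implausible_links(ds, term)
    dup_issues, p12 = detect_duplicates(ds)
    amb_issues, p13 = detect_ambiguous(ds, term, tracers, rule_b=config.ambiguous_rule_b)

    total = ds.total_inpatient_cases or config.total_inpatient_cases
    if total is not None:
        p4, p5, p6 = relative_frequencies(len(flags.rd), len(flags.orpha), len(flags.tracer), total)
    else:
        p4 = p5 = p6 = None

    import hashlib

    fingerprint = hashlib.sha256(
        f"{term.fingerprint()}|{tracers.fingerprint()}|{catalog.fingerprint()}".encode()
    ).hexdigest()[:16]

    params = DqParameterSet(
        rd_cases=len(flags.rd),
        orpha_cases=len(flags.orpha),
        tracer_cases=len(flags.tracer),
        rd_cases_rel=p4,
        orpha_cases_rel=p5,
        tracer_cases_rel=p6,
        missing_items=p7,
        missing_values=p8,
        outliers=p9,
        missing_orphacodes=p10,
        implausible_links=p11,
        duplicate_cases=p12,
        ambiguous_cases=p13,
        n_mandatory_items=len(catalog),
        n_value_slots=n_slots,
        n_checked_values=n_checked,
        n_tracer_diagnoses=n_tracer_dx,
        n_linked_diagnoses=n_linked,
        n_case_records=len(ds.diagnoses),
        total_inpatient_cases=total,
        fingerprint=fingerprint,
    )
    issues = (
        item_issues + value_issues + outlier_issues + orpha_issues
        + link_issues + dup_issues + amb_issues
    )
    return params, compute_indicators(params), issues
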