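"""Two-sheet DQ report with k-anonymous violation disclosure.

The workbook carries a "DQ Metrics Report" sheet (parameters and
indicators, one labeled row each) and a "DQ Violations Report" sheet (one
row per issue group). Because violation rows can identify patients in
small rare-disease cohorts, any group touching fewer than k distinct
patients is suppressed and folded into one aggregate row. Groups that
reference no patient at all (dataset-level findings such as a missing
mandatory item) disclose nothing and are always reported.

A CSV fallback of both sheets is always written alongside the workbook;
the CSVs are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import csv
from pathlib import Path

from openpyxl import Workbook

from .compare import LostVector
from .engine import PARAMETER_NAMES, DqIndicatorSet, DqIssue, DqParameterSet

__all__ = ["write_reports", "metrics_rows", "violation_rows"]

_INDICATOR_LABELS = {
    "dqi_co_ocr": "Orphacoding Completeness Rate",
    "dqi_co_icr": "Item Completeness Rate",
    "dqi_co_vcr": "Value Completeness Rate",
    "dqi_pl_opr": "Orphacoding Plausibility Rate",
    "dqi_pl_rpr": "Range Plausibility Rate",
    "dqi_un_cur": "RD Case Unambiguity Rate",
    "dqi_un_cdr": "RD Case Dissimilarity Rate",
}

_PARAMETER_LABELS = {
    1: "RD Cases",
    2: "Orpha Cases",
    3: "Tracer Cases",
    4: "RD Case rel. Frequency",
    5: "Orpha Case rel. Frequency",
    6: "Tracer Case rel. Frequency",
    7: "Missing Mandatory Data Items",
    8: "Missing Mandatory Data Values",
    9: "Outliers",
    10: "Missing Orphacodes",
    11: "Implausible Links",
    12: "Duplicated RD Cases",
    13: "Ambiguous RD Cases",
}


def metrics_rows(params: DqParameterSet, indicators: DqIndicatorSet) -> list[list]:
    rows: list[list] = [["kind", "no", "name", "abbreviation", "value", "note"]]
    vector = params.as_vector()
    for i in range(1, 14):
        value = vector[i]
        note = "" if value is not None else "not computable (no inpatient total)"
        rows.append(["parameter", f"P{i}", _PARAMETER_LABELS[i], PARAMETER_NAMES[i],
                     "" if value is None else value, note])
    for abbrev, indicator in indicators.as_dict().items():
        note = "" if indicator.evaluable else "vacuous denominator"
        rows.append(["indicator", "", _INDICATOR_LABELS[abbrev], abbrev,
                     round(indicator.value, 2), note])
    denominators = [
        ("mandatory items", params.n_mandatory_items),
        ("mandatory value slots", params.n_value_slots),
        ("range-checked values", params.n_checked_values),
        ("tracer diagnoses", params.n_tracer_diagnoses),
        ("linked diagnoses", params.n_linked_diagnoses),
        ("case records", params.n_case_records),
        ("total inpatient cases", params.total_inpatient_cases or ""),
    ]
    for name, value in denominators:
        rows.append(["denominator", "", name, "", value, ""])
    return rows


def violation_rows(issues: list[DqIssue], k: int) -> list[list]:
    """Group issues for disclosure, applying k-anonymity suppression."""
    if k < 1:
        raise ValueError("k must be >= 1")
    groups: dict[tuple[str, str], list[DqIssue]] = {}
    for issue in issues:
        groups.setdefault((issue.category, issue.group_key), []).append(issue)
    rows: list[list] = [["category", "group", "issue_count", "affected_patients", "example"]]
    suppressed_issues = 0
    suppressed_groups = 0
    for (category, group_key), members in sorted(groups.items()):
        patients = {p for m in members for p in m.patient_ids}
        if patients and len(patients) < k:
            suppressed_issues += len(members)
            suppressed_groups += 1
            continue
        rows.append([category, group_key, len(members), len(patients), members[0].detail])
    if suppressed_groups:
        rows.append([
            f"suppressed (<{k})", f"{suppressed_groups} group(s)",
            suppressed_issues, "", "groups below the k-anonymity threshold",
        ])
    return rows


def comparison_rows(vector: LostVector) -> list[list]:
    rows: list[list] = [["no", "name", "reference", "transformed", "lost", "sign_rule", "classification"]]
    for entry in vector.entries:
        rows.append([
            f"P{entry.index}", entry.name,
            "" if entry.p_ref is None else entry.p_ref,
            "" if entry.p_transformed is None else entry.p_transformed,
            "" if entry.lost is None else entry.lost,
            entry.sign_rule, entry.classification,
        ])
    return rows


def _write_csv(path: Path, rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        csv.writer(handle, lineterminator="\n").writerows(rows)


def write_reports(
    params: DqParameterSet,
    indicators: DqIndicatorSet,
    issues: list[DqIssue],
    k: int,
    out: str | Path,
    comparison: LostVector | None = None,
    basename: str = "dq_report",
) -> dict[str, Path]:
    """Write the workbook and its CSV fallbacks into directory ``out``.

    Returns the paths written, keyed ``workbook`` / ``metrics_csv`` /
    ``violations_csv`` (and ``comparison_csv`` when a comparison is given).
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    m_rows = metrics_rows(params, indicators)
    v_rows = violation_rows(issues, k)

    workbook = Workbook()
    metrics_sheet = workbook.active
    metrics_sheet.title = "DQ Metrics Report"
    for row in m_rows:
        metrics_sheet.append(row)
    violations_sheet = workbook.create_sheet("DQ Violations Report")
    for row in v_rows:
        violations_sheet.append(row)

    paths = {
        "workbook": out / f"{basename}.xlsx",
        "metrics_csv": out / f"{basename}_metrics.csv",
        "violations_csv": out / f"{basename}_violations.csv",
    }
    _write_csv(paths["metrics_csv"], m_rows)
    _write_csv(paths["violations_csv"], v_rows)
    if comparison is not None:
        c_rows = comparison_rows(comparison)
        comparison_sheet = workbook.create_sheet("DQ Comparison Report")
        for row in c_rows:
            comparison_sheet.append(row)
        paths["comparison_csv"] = out / f"{basename}_comparison.csv"
        _write_csv(paths["comparison_csv"], c_rows)
    workbook.save(paths["workbook"])
    return paths
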