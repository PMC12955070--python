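"""Comparative assessment of two datasets from the same source.

A direct export (reference) and a FAIRified/transformed rendition of the
same patient population are assessed separately; the per-parameter
difference Pi_lost then quantifies what the transformation pipeline lost.
Because P7-P9 count *issues* (more is worse) while the other parameters
count *present* observation units, the sign flips for i = 7, 8, 9:

    Pi_lost = Pi_transformed - Pi_reference   for i in {7, 8, 9}
    Pi_lost = Pi_reference - Pi_transformed   otherwise

A positive loss is not automatically a defect: fewer outliers (P9) or
duplicates (P12) after transformation may be intentional curation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import PARAMETER_NAMES, DqParameterSet

__all__ = ["LostEntry", "LostVector", "LostSummary", "ComparabilityError",
           "lost_parameters", "summarize_lost"]

#: parameters counting issues: their loss sign is inverted
ISSUE_PARAMETERS = frozenset({7, 8, 9})
#: losses here may reflect intentional curation rather than damage
POSSIBLY_INTENTIONAL = frozenset({9, 12})
#: positive losses here count as completeness issues introduced by the pipeline
COMPLETENESS_PARAMETERS = frozenset({1, 7, 8, 10})


class ComparabilityError(ValueError):
    """The two parameter sets were not computed under the same rule set."""


@dataclass(frozen=True)
class LostEntry:
    index: int
    name: str
    p_ref: int | None
    p_transformed: int | None
    lost: int | None
    sign_rule: str  # "transformed-minus-ref" | "ref-minus-transformed"
    classification: str  # "issue" | "possibly-intentional" | "neutral"


@dataclass(frozen=True)
class LostVector:
    entries: tuple[LostEntry, ...]

    def __getitem__(self, index: int) -> LostEntry:
        for e in self.entries:
            if e.index == index:
                return e
        raise KeyError(index)

    def lost(self, index: int) -> int | None:
        return self[index].lost


@dataclass(frozen=True)
class LostSummary:
    """Issue bookkeeping for the transformed dataset.

    ``completeness_loss_total`` sums the positive losses among the
    completeness parameters (P1, P7, P8, P10): issues introduced by the
    pipeline. ``shared_missing_items`` are the transformed dataset's
    missing items not attributable to the pipeline (they are missing in
    the reference too). ``grand_total`` is the number of distinct issues
    in the transformed dataset under this decomposition:
    completeness losses + ambiguous cases + shared missing items.
    """

    completeness_loss_total: int
    transformed_ambiguous: int
    shared_missing_items: int
    grand_total: int
    breakdown: tuple[tuple[str, int], ...]


def lost_parameters(ref: DqParameterSet, transformed: DqParameterSet) -> LostVector:
    """Apply the piecewise Pi_lost rule to all 13 parameters.

    Both sets must stem from the same terminology, tracer set and item
    catalog (compared by fingerprint when both carry one). Relative
    parameters (P4-P6) are compared only when both totals are known and
    equal; otherwise their entries carry ``None``.
    """
    if ref.fingerprint and transformed.fingerprint and ref.fingerprint != transformed.fingerprint:
        raise ComparabilityError(
            "parameter sets computed under different terminology/tracers/catalog "
            f"({ref.fingerprint} != {transformed.fingerprint})"
        )
    ref_vec = ref.as_vector()
    tra_vec = transformed.as_vector()
    comparable_rel = (
        ref.total_inpatient_cases is not None
        and ref.total_inpatient_cases == transformed.total_inpatient_cases
    )
    entries = []
    for i in range(1, 14):
        a, b = ref_vec[i], tra_vec[i]
        if i in (4, 5, 6) and not comparable_rel:
            a = b = None
        if a is None or b is None:
            lost = None
        elif i in ISSUE_PARAMETERS:
            lost = b - a
        else:
            lost = a - b
        sign_rule = "transformed-minus-ref" if i in ISSUE_PARAMETERS else "ref-minus-transformed"
        if lost is not None and lost > 0:
            classification = "possibly-intentional" if i in POSSIBLY_INTENTIONAL else "issue"
        else:
            classification = "neutral"
        entries.append(LostEntry(i, PARAMETER_NAMES[i], a, b, lost, sign_rule, classification))
    return LostVector(tuple(entries))


def summarize_lost(
    vector: LostVector, transformed: DqParameterSet | None = None
) -> LostSummary:
    """Total the losses into the issue decomposition of the transformed dataset.

    The completeness-loss total sums positive losses among P1 (lost RD
    cases), P7 (items), P8 (values) and P10 (Orphacodes). The grand total
    adds the transformed dataset's ambiguous cases (P13) and its missing
    items that the reference shares (P7_transformed minus the positive
    P7 loss). When ``transformed`` is omitted the per-parameter values
    stored in the vector are used.
    """
    completeness = 0
    breakdown = []
    for i in sorted(COMPLETENESS_PARAMETERS):
        entry = vector[i]
        if entry.lost is not None and entry.lost > 0:
            completeness += entry.lost
            breakdown.append((f"lost_{entry.name}", entry.lost))
    p7_entry = vector[7]
    p7_transformed = (
        transformed.missing_items if transformed is not None
        else (p7_entry.p_transformed or 0)
    )
    p7_lost = max(p7_entry.lost or 0, 0)
    shared_items = max(p7_transformed - p7_lost, 0)
    p13_transformed = (
        transformed.ambiguous_cases if transformed is not None
        else (vector[13].p_transformed or 0)
    )
    grand = completeness + p13_transformed + shared_items
    breakdown.append(("transformed_ambiguous_cases", p13_transformed))
    breakdown.append(("shared_missing_items", shared_items))
    return LostSummary(
        completeness_loss_total=completeness,
        transformed_ambiguous=p13_transformed,
        shared_missing_items=shared_items,
        grand_total=grand,
        breakdown=tuple(breakdown),
    )
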