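"""Alpha-ID-SE-style terminology handling.

The German BfArM maintains the Alpha-ID-SE terminology: an alphabetical
index of diagnostic terms, each carrying a stable identifier (Alpha-ID),
the ICD-10-GM code(s) of the term, and — since the SE extension — an
optional Orphanet identifier (Orphacode) for rare-disease terms.

This module parses such pipe-delimited terminology files, derives the set
of *tracer diagnoses* (ICD-10-GM codes whose every diagnostic term carries
an Orphacode, i.e. codes that exclusively encode rare diseases) and
answers link-plausibility and ambiguity queries against the terminology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "AlphaIdEntry",
    "AlphaTerminology",
    "TracerSet",
    "AlphaDialect",
    "ParseError",
    "AlphaFormatError",
    "normalize_icd",
    "normalize_orphacode",
    "parse_alpha_id_se",
    "serialize_alpha_id_se",
    "derive_tracers",
    "load_curated_tracers",
    "check_link",
    "orpha_candidates",
]

#: ICD-10-GM code shape: letter + two digits, optional "." + 1-2 alphanumerics.
ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")

#: Trailing usage markers carried by ICD codes in German claims data
#: (exclamation = optional additional code, dagger/asterisk = etiology/
#: manifestation cross markers). Stripped on normalization, kept aside.
USAGE_MARKERS = "!+*"


class AlphaFormatError(ValueError):
    """The stream does not look like a terminology file in the given dialect."""


@dataclass(frozen=True)
class ParseError:
    """One line that failed to parse, kept for audit instead of being dropped."""

    line_number: int
    reason: str
    line: str


def normalize_icd(raw: str) -> tuple[str | None, str | None]:
    """Normalize an ICD-10-GM code: uppercase, dot notation, markers split off.

    Returns ``(code, marker)``; ``(None, None)`` for empty input. The code is
    *not* validated here — callers decide whether a malformed code is an
    error (terminology parsing) or a data-quality finding (case data).
    """
    text = (raw or "").strip().upper()
    if not text:
        return None, None
    marker = None
    if text and text[-1] in USAGE_MARKERS:
        marker = text[-1]
        text = text[:-1].strip()
    return (text or None), marker


def normalize_orphacode(raw: str | int | None) -> int | None:
    """Parse an Orphacode, accepting and stripping ``ORPHA:``-style prefixes.

    Raises :class:`ValueError` for a non-empty value that is not a positive
    integer after prefix stripping.
    """
    if raw is None:
        return None
    if isinstance(raw, int):
        value = raw
    else:
        text = str(raw).strip()
        if not text:
            return None
        text = re.sub(r"^orpha(code)?\s*:?\s*", "", text, flags=re.IGNORECASE)
        value = int(text)
    if value <= 0:
        raise ValueError(f"Orphacode must be a positive integer, got {raw!r}")
    return value


@dataclass(frozen=True)
class AlphaIdEntry:
    """One diagnostic term of the terminology."""

    alpha_id: str
    valid: bool
    icd_primary: str
    icd_star: str | None = None
    orphacode: int | None = None
    label: str = ""
    icd_marker: str | None = None


@dataclass(frozen=True)
class AlphaDialect:
    """0-based field positions of the pipe-delimited terminology layout.

    The default mirrors the BfArM column order
    ``validity|alpha_id|icd_primary|icd_star|icd_additional|orphacode|label``;
    releases with different layouts are absorbed by remapping positions.
    """

    valid: int = 0
    alpha_id: int = 1
    icd_primary: int = 2
    icd_star: int = 3
    orphacode: int = 5
    label: int = 6
    delimiter: str = "|"

    @property
    def min_fields(self) -> int:
        return 1 + max(
            self.valid, self.alpha_id, self.icd_primary,
            self.icd_star, self.orphacode, self.label,
        )


class AlphaTerminology:
    """Indexed collection of Alpha-ID entries.

    Per the terminology's own semantics, only ``valid`` entries participate
    in tracer derivation, link checking and ambiguity queries; invalid
    (retired) entries are retained for audit.
    """

    def __init__(self, entries: Iterable[AlphaIdEntry], parse_errors: Iterable[ParseError] = ()):
        self.entries: list[AlphaIdEntry] = list(entries)
        self.parse_errors: list[ParseError] = list(parse_errors)
        seen: set[str] = set()
        for e in self.entries:
            if not e.alpha_id:
                raise ValueError("alpha_id must be non-empty")
            if e.alpha_id in seen:
                raise ValueError(f"duplicate alpha_id {e.alpha_id!r}")
            seen.add(e.alpha_id)
        # index over all entries; link queries restrict to valid ones
        self.icd_index: dict[str, list[AlphaIdEntry]] = {}
        self.link_set: set[tuple[str, int]] = set()
        for e in self.entries:
            self.icd_index.setdefault(e.icd_primary, []).append(e)
            if e.valid and e.orphacode is not None:
                self.link_set.add((e.icd_primary, e.orphacode))

    def __len__(self) -> int:
        return len(self.entries)

    def valid_entries(self, icd: str) -> list[AlphaIdEntry]:
        return [e for e in self.icd_index.get(icd, []) if e.valid]

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for e in sorted(self.entries, key=lambda e: e.alpha_id):
            h.update(f"{e.alpha_id}|{e.valid}|{e.icd_primary}|{e.orphacode}".encode())
        return h.hexdigest()[:16]


def parse_alpha_id_se(
    stream: TextIO | Iterable[str],
    dialect: AlphaDialect | None = None,
) -> AlphaTerminology:
    """Parse a pipe-delimited terminology stream into an :class:`AlphaTerminology`.

    Malformed lines are collected as :class:`ParseError` records, not
    silently dropped. If more than half of the non-empty lines are
    malformed the stream is rejected outright with an
    :class:`AlphaFormatError` naming the first offending line.
    """
    dialect = dialect or AlphaDialect()
    entries: list[AlphaIdEntry] = []
    errors: list[ParseError] = []
    n_lines = 0
    for lineno, raw_line in enumerate(stream, start=1):
        line = raw_line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        n_lines += 1
        fields = line.split(dialect.delimiter)
        if len(fields) < dialect.min_fields:
            errors.append(ParseError(lineno, f"expected >= {dialect.min_fields} fields, got {len(fields)}", line))
            continue
        validity = fields[dialect.valid].strip()
        alpha_id = fields[dialect.alpha_id].strip()
        icd, marker = normalize_icd(fields[dialect.icd_primary])
        icd_star, _ = normalize_icd(fields[dialect.icd_star])
        label = fields[dialect.label].strip()
        if not alpha_id:
            errors.append(ParseError(lineno, "empty alpha_id", line))
            continue
        if icd is None or not ICD_PATTERN.match(icd):
            errors.append(ParseError(lineno, f"invalid ICD-10-GM code {fields[dialect.icd_primary]!r}", line))
            continue
        try:
            orpha = normalize_orphacode(fields[dialect.orphacode])
        except ValueError:
            errors.append(ParseError(lineno, f"invalid Orphacode {fields[dialect.orphacode]!r}", line))
            continue
        entries.append(
            AlphaIdEntry(
                alpha_id=alpha_id,
                valid=validity not in ("0", "false", "False"),
                icd_primary=icd,
                icd_star=icd_star,
                orphacode=orpha,
                label=label,
                icd_marker=marker,
            )
        )
    if n_lines and len(errors) * 2 > n_lines:
        raise AlphaFormatError(
            f"{len(errors)}/{n_lines} lines malformed; first offending line {errors[0].line_number}: {errors[0].reason}"
        )
    return AlphaTerminology(entries, errors)


def serialize_alpha_id_se(term: AlphaTerminology, dialect: AlphaDialect | None = None) -> str:
    """Render a terminology back to the pipe-delimited dialect.

    Round-trip guarantee: re-parsing the output under the same dialect
    yields an identical entry set (unused positional fields are emitted
    empty).
    """
    dialect = dialect or AlphaDialect()
    lines = []
    for e in term.entries:
        fields = [""] * dialect.min_fields
        fields[dialect.valid] = "1" if e.valid else "0"
        fields[dialect.alpha_id] = e.alpha_id
        fields[dialect.icd_primary] = e.icd_primary + (e.icd_marker or "")
        fields[dialect.icd_star] = e.icd_star or ""
        fields[dialect.orphacode] = "" if e.orphacode is None else str(e.orphacode)
        fields[dialect.label] = e.label
        lines.append(dialect.delimiter.join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class TracerSet:
    """A set of tracer-diagnosis ICD-10-GM codes with its provenance.

    ``alpha_derived`` tracers come from the all-terms-have-Orphacode rule;
    ``curated`` tracers come from an expert-maintained reference list.
    """

    codes: frozenset[str]
    provenance: str  # "alpha_derived" | "curated"
    excluded: tuple[str, ...] = field(default=())

    def __contains__(self, code: object) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256("|".join(sorted(self.codes)).encode()).hexdigest()[:16]


def derive_tracers(term: AlphaTerminology) -> TracerSet:
    """Derive the tracer set: codes where *every* valid term has an Orphacode.

    A code with zero valid entries is not a tracer. Entry order is
    irrelevant by construction.
    """
    codes = set()
    for icd in term.icd_index:
        valid = term.valid_entries(icd)
        if valid and all(e.orphacode is not None for e in valid):
            codes.add(icd)
    return TracerSet(frozenset(codes), provenance="alpha_derived")


def load_curated_tracers(stream: TextIO | Iterable[str]) -> TracerSet:
    """Load a curated tracer list: one ICD-10-GM code per line, ``#`` comments.

    Codes are normalized and deduplicated; tokens failing the ICD pattern
    are excluded and reported on the returned set's ``excluded`` tuple.
    """
    codes: set[str] = set()
    excluded: list[str] = []
    for raw_line in stream:
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        code, _ = normalize_icd(line)
        if code and ICD_PATTERN.match(code):
            codes.add(code)
        else:
            excluded.append(line)
    return TracerSet(frozenset(codes), provenance="curated", excluded=tuple(excluded))


def check_link(term: AlphaTerminology, icd: str, orpha: int) -> str:
    """Assess an (ICD-10-GM, Orphacode) combination against the terminology.

    Returns ``"plausible"`` iff some valid entry carries exactly this pair,
    else ``"implausible"`` (e.g. G71.2 paired with an Orphacode that none
    of its terms carries).
    """
    return "plausible" if (icd, orpha) in term.link_set else "implausible"


def orpha_candidates(term: AlphaTerminology, icd: str) -> frozenset[int]:
    """All distinct Orphacodes attached to valid entries of ``icd``."""
    return frozenset(
        e.orphacode for e in term.valid_entries(icd) if e.orphacode is not None
    )
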