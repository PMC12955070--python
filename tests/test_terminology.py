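"""Terminology parsing, tracer derivation and link/ambiguity queries."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddq.terminology import (
    AlphaDialect,
    AlphaFormatError,
    AlphaIdEntry,
    AlphaTerminology,
    check_link,
    derive_tracers,
    load_curated_tracers,
    normalize_icd,
    orpha_candidates,
    parse_alpha_id_se,
    serialize_alpha_id_se,
)
from tests.conftest import DEFAULT_DIALECT_LINES, SIX_FIELD_DIALECT


class TestParsing:
    def test_six_field_layout_example(self):
        term = parse_alpha_id_se(
            io.StringIO("1|I128560|Q87.5||2097|Grant syndrome\n"),
            dialect=SIX_FIELD_DIALECT,
        )
        (entry,) = term.entries
        assert entry.alpha_id == "I128560"
        assert entry.icd_primary == "Q87.5"
        assert entry.orphacode == 2097
        assert entry.valid

    def test_default_dialect_full_file(self, small_terminology):
        assert len(small_terminology) == 8
        assert not small_terminology.parse_errors

    def test_empty_stream(self):
        term = parse_alpha_id_se(io.StringIO(""))
        assert len(term) == 0 and not term.parse_errors

    def test_malformed_line_collected_not_dropped(self):
        text = (
            "1|I000001|Q87.5|||2097|ok\n"
            "not a terminology line\n"
            "1|I000002|E84.0|||586|ok too\n"
        )
        term = parse_alpha_id_se(io.StringIO(text))
        assert len(term) == 2
        assert len(term.parse_errors) == 1
        assert term.parse_errors[0].line_number == 2

    def test_mostly_malformed_stream_is_format_error(self):
        text = "garbage one\ngarbage two\n1|I000001|Q87.5|||2097|ok\n"
        with pytest.raises(AlphaFormatError, match="line 1"):
            parse_alpha_id_se(io.StringIO(text))

    def test_empty_orphacode_field_means_absent(self, small_terminology):
        entry = next(e for e in small_terminology.entries if e.alpha_id == "I200005")
        assert entry.orphacode is None

    def test_usage_marker_stripped(self):
        term = parse_alpha_id_se(io.StringIO("1|I000001|G71.2!|||777|marked\n"))
        assert term.entries[0].icd_primary == "G71.2"
        assert term.entries[0].icd_marker == "!"

    def test_duplicate_alpha_id_rejected(self):
        entry = AlphaIdEntry("I1", True, "Q87.5")
        with pytest.raises(ValueError, match="duplicate"):
            AlphaTerminology([entry, entry])

    def test_round_trip_preserves_entry_set(self, small_terminology):
        text = serialize_alpha_id_se(small_terminology)
        reparsed = parse_alpha_id_se(io.StringIO(text))
        assert set(reparsed.entries) == set(small_terminology.entries)
        assert not reparsed.parse_errors


class TestTracerDerivation:
    def test_fully_annotated_code_is_tracer(self, small_terminology):
        tracers = derive_tracers(small_terminology)
        assert "Q87.5" in tracers
        assert tracers.provenance == "alpha_derived"

    def test_code_with_unannotated_term_is_not_tracer(self, small_terminology):
        # E84.0 has a valid term without an Orphacode
        assert "E84.0" not in derive_tracers(small_terminology)

    def test_invalid_entries_do_not_block_derivation(self):
        # the only unannotated E84.0-style term is retired -> code qualifies
        text = "1|I1|E84.0|||586|active annotated\n0|I2|E84.0||||retired unannotated\n"
        assert "E84.0" in derive_tracers(parse_alpha_id_se(io.StringIO(text)))

    def test_code_with_only_invalid_entries_is_not_tracer(self):
        text = "0|I1|E84.0|||586|retired\n"
        assert len(derive_tracers(parse_alpha_id_se(io.StringIO(text)))) == 0

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_terminology(self, seed):
        rng = random.Random(seed)
        entries = []
        codes = [f"A{10 + i}.{i % 10}" for i in range(20)]
        for i in range(rng.randint(1, 60)):
            entries.append(
                AlphaIdEntry(
                    alpha_id=f"I{i:06d}",
                    valid=rng.random() < 0.8,
                    icd_primary=rng.choice(codes),
                    orphacode=rng.randint(1, 500) if rng.random() < 0.7 else None,
                )
            )
        term = AlphaTerminology(entries)
        # brute force: scan all entries grouped by code
        expected = set()
        for code in codes:
            group = [e for e in entries if e.icd_primary == code and e.valid]
            if group and all(e.orphacode is not None for e in group):
                expected.add(code)
        assert derive_tracers(term).codes == frozenset(expected)

    def test_invariant_under_entry_reordering(self, small_terminology):
        shuffled = list(small_terminology.entries)
        random.Random(1).shuffle(shuffled)
        assert derive_tracers(AlphaTerminology(shuffled)).codes == derive_tracers(small_terminology).codes

    def test_tracers_have_candidates(self, small_terminology):
        for code in derive_tracers(small_terminology).codes:
            assert orpha_candidates(small_terminology, code)


class TestCuratedTracers:
    def test_normalized_and_deduplicated(self):
        tracers = load_curated_tracers(io.StringIO("e84.0\nE84.0\n"))
        assert tracers.codes == frozenset({"E84.0"})
        assert tracers.provenance == "curated"

    def test_empty_file(self):
        assert len(load_curated_tracers(io.StringIO(""))) == 0

    def test_invalid_tokens_excluded_and_counted(self):
        text = "E84.0\nQ87.5\nnot-a-code\nG71.2\nF84.2\n"
        tracers = load_curated_tracers(io.StringIO(text))
        assert len(tracers) == 4
        assert tracers.excluded == ("not-a-code",)

    def test_comments_ignored(self):
        tracers = load_curated_tracers(io.StringIO("# header\nE84.0  # cystic fibrosis\n"))
        assert tracers.codes == frozenset({"E84.0"})


class TestLinkQueries:
    def test_unknown_pair_is_implausible(self, small_terminology):
        assert check_link(small_terminology, "G71.2", 777) == "implausible"

    def test_known_pair_is_plausible(self, small_terminology):
        assert check_link(small_terminology, "Q87.5", 2097) == "plausible"

    def test_empty_terminology_everything_implausible(self):
        term = parse_alpha_id_se(io.StringIO(""))
        assert check_link(term, "Q87.5", 2097) == "implausible"

    def test_retired_entry_does_not_make_link_plausible(self, small_terminology):
        assert check_link(small_terminology, "E84.0", 12345) == "implausible"

    def test_candidates_for_multi_rd_code(self, small_terminology):
        assert orpha_candidates(small_terminology, "F84.2") == frozenset({778, 3095})

    def test_candidates_unknown_code_empty(self, small_terminology):
        assert orpha_candidates(small_terminology, "Z99.9") == frozenset()

    def test_plausible_implies_candidate(self, small_terminology):
        for icd, orpha in small_terminology.link_set:
            assert orpha in orpha_candidates(small_terminology, icd)


def test_icd_normalization():
    assert normalize_icd("q87.5") == ("Q87.5", None)
    assert normalize_icd("G71.2+") == ("G71.2", "+")
    assert normalize_icd("") == (None, None)
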