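"""Scrubber pattern builders and application semantics."""

from __future__ import annotations

import datetime
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deident.scrub import (ScrubberConfig,
                           ScrubberConfigError, ScrubSourceValue,
                           assemble_scrubber, build_code_pattern,
                           build_date_patterns, build_nonspecific_patterns,
                           build_number_pattern, build_phrase_pattern,
                           build_word_patterns, chunks_of, scrub_text)

CFG = ScrubberConfig()


def scrub(values, text, cfg=CFG):
    return assemble_scrubber(values, cfg).scrub(text)


def patient(raw, method):
    return ScrubSourceValue(raw, method, "patient")


# ---------------------------------------------------------------------------
# words

class TestWords:
    def test_each_chunk_scrubbed(self):
        # "John Al'Rahem" splits on non-alphanumerics into John/Al/Rahem,
        # all of length >= 2, so each is masked independently.
        out = scrub([patient("John Al'Rahem", "words")],
                    "seen John today with Al and Rahem")
        assert out == "seen [___] today with [___] and [___]"

    def test_suffix_permits_possessive_misspelling(self):
        assert scrub([patient("Robert", "words")], "Roberts") == "[___]"

    def test_one_typo_tolerated_above_length_threshold(self):
        assert scrub([patient("Jakob", "words")], "Jacob") == "[___]"

    def test_short_names_do_not_fuzzy_match(self):
        # "Ian" is below the length-4 typo threshold: "in" must survive.
        out = scrub([patient("Ian", "words")], "Ian put it in the box")
        assert out == "[___] put it in the box"

    def test_chunks_below_min_string_length_dropped(self):
        cfg = ScrubberConfig(min_string_length=3)
        assert build_word_patterns("Al B Ceefax", cfg) \
            == build_word_patterns("Ceefax", cfg)

    def test_whitelisted_chunk_never_produces_pattern(self):
        cfg = ScrubberConfig(whitelist=frozenset({"road"}))
        out = scrub([patient("29 Acacia Road", "words")],
                    "29 Acacia Road on the road", cfg)
        assert out == "[___] [___] Road on the road"

    def test_case_insensitive(self):
        assert scrub([patient("Jakob", "words")], "JAKOB jakob JaKoB") \
            == "[___] [___] [___]"


# ---------------------------------------------------------------------------
# phrase

class TestPhrase:
    def test_matches_sequence_with_any_separators(self):
        v = [patient("4 Privet Drive", "phrase")]
        assert scrub(v, "lives at 4, Privet Drive now") \
            == "lives at [___] now"
        assert scrub(v, "4  Privet - Drive") == "[___]"

    def test_does_not_scrub_dose_information(self):
        out = scrub([patient("4 Privet Drive", "phrase")],
                    "risperidone 4 mg/day")
        assert out == "risperidone 4 mg/day"

    def test_partial_address_not_matched_by_phrase_but_by_words(self):
        text = "29 Acacia Avenue"
        assert scrub([patient("29 Acacia Road", "phrase")], text) == text
        assert scrub([patient("29 Acacia Road", "words")], text) \
            == "[___] [___] Avenue"

    def test_single_chunk_phrase_is_boundary_anchored_literal(self):
        v = [patient("Cambridge", "phrase")]
        assert scrub(v, "in Cambridge today") == "in [___] today"
        assert scrub(v, "Cambridgeshire") == "Cambridgeshire"


# ---------------------------------------------------------------------------
# number

class TestNumber:
    @pytest.mark.parametrize("text,expected", [
        ("M123456", "M[___]"),
        ("NHS#123456", "NHS#[___]"),
        ("123 456", "[___]"),
        ("(123) 456", "([___]"),
        ("123456", "[___]"),
    ])
    def test_digit_string_scrubbed_regardless_of_format(self, text, expected):
        assert scrub([patient("123 456", "number")], text) == expected

    @pytest.mark.parametrize("text", ["0123456", "1234567"])
    def test_lookaround_guard_blocks_longer_runs(self, text):
        assert scrub([patient("123 456", "number")], text) == text

    def test_phone_number_normalized_to_digits(self):
        out = scrub([patient("(01223) 123456", "number")],
                    "tel: 01223-123456")
        assert out == "tel: [___]"

    def test_too_few_digits_yields_no_pattern(self):
        assert build_number_pattern("7", ScrubberConfig()) is None

    @settings(max_examples=150, derandomize=True)
    @given(digits=st.text("0123456789", min_size=2, max_size=4),
           text=st.text("01 -x", min_size=0, max_size=8))
    def test_agrees_with_bruteforce_lookaround_semantics(self, digits, text):
        # Independent oracle: a substring masks iff its word characters are
        # exactly the digit sequence, separated only by non-word characters,
        # and it is not flanked by further digits.
        pattern = build_number_pattern(digits, CFG)
        assert pattern is not None
        found = re.search(pattern, text) is not None
        expected = False
        n = len(text)
        for i in range(n):
            for j in range(i + 1, n + 1):
                sub = text[i:j]
                if not (sub[0].isdigit() and sub[-1].isdigit()):
                    continue   # a match starts and ends on the digits
                if re.sub(r"\W", "", sub) != digits:
                    continue   # wrong digits, or word chars interleaved
                if i > 0 and text[i - 1].isdigit():
                    continue   # left lookaround guard
                if j < n and text[j].isdigit():
                    continue   # right lookaround guard
                expected = True
        assert found == expected


# ---------------------------------------------------------------------------
# code

class TestCode:
    @pytest.mark.parametrize("text,expected", [
        ("CB123DE", "[___]"),
        ("CB12-3DE", "[___]"),
        ("CB12 3DE", "[___]"),
    ])
    def test_alphanumeric_sequence_scrubbed(self, text, expected):
        assert scrub([patient("CB12 3DE", "code")], text) == expected

    def test_boundary_anchoring_blocks_embedded_match(self):
        assert scrub([patient("CB12 3DE", "code")], "XCB123DE") == "XCB123DE"

    def test_below_min_length_no_pattern(self):
        assert build_code_pattern("X", ScrubberConfig()) is None


# ---------------------------------------------------------------------------
# date

DATE_FORMS_7JAN2013 = [
    "07 Jan 2013", "7 January 13", "7/1/13", "1/7/13", "Jan 7 2013",
    "2013/01/07", "2013-01-07", "7th January 13", "Jan 7th 13",
    "07.01.13", "7.1.2013", "20130107T0123", "20130107",
]


class TestDate:
    @pytest.mark.parametrize("form", DATE_FORMS_7JAN2013)
    def test_all_written_forms_of_a_date_masked(self, form):
        out = scrub([patient(datetime.date(2013, 1, 7), "date")], form)
        assert "[___]" in out
        assert not re.search(r"2013|0107", out)

    @pytest.mark.parametrize("form", ["31 Dec 2016", "Dec 31st 16",
                                      "2016-12-31"])
    def test_order_variants(self, form):
        assert scrub([patient(datetime.date(2016, 12, 31), "date")],
                     form) == "[___]"

    def test_indirect_date_reference_missed(self):
        # Dates are simple points in time; no temporal inference.
        text = "he was born on Easter Day in 1950"
        assert scrub([patient(datetime.date(1950, 4, 9), "date")],
                     text) == text

    def test_iso_string_source_accepted(self):
        assert scrub([patient("2013-01-07", "date")], "7/1/13") == "[___]"

    def test_invalid_date_rejected(self):
        with pytest.raises(ScrubberConfigError):
            build_date_patterns("not a date at all", CFG)


# ---------------------------------------------------------------------------
# nonspecific

class TestNonspecific:
    def test_digit_run_lengths(self):
        cfg = ScrubberConfig(nonspecific_number_lengths=(10, 11))
        s = assemble_scrubber([], cfg)
        assert s.scrub("ring 07700 900123 now") == "ring [~~~] now"
        assert s.scrub("nhs no 4857773456") == "nhs no [~~~]"
        assert s.scrub("short 123456") == "short 123456"

    @pytest.mark.parametrize("pc", ["CB2 0QQ", "CB23 3DE", "W1A 1AA",
                                    "EC1A 1BB", "M1 1AE", "cb2 0qq"])
    def test_uk_postcode_shapes(self, pc):
        cfg = ScrubberConfig(scrub_uk_postcodes=True)
        assert assemble_scrubber([], cfg).scrub(pc) == "[~~~]"

    def test_empty_configuration_empty_list(self):
        assert build_nonspecific_patterns(ScrubberConfig()) == []

    def test_blacklist_is_nonspecific_and_applied_first(self):
        cfg = ScrubberConfig(blacklist=("restricted",))
        s = assemble_scrubber([patient("Jakob", "words")], cfg)
        assert s.scrub("restricted note on Jakob") == "[~~~] note on [___]"


# ---------------------------------------------------------------------------
# assembly and application

class TestScrubber:
    def test_empty_values_match_nothing(self):
        s = assemble_scrubber([], CFG)
        text = "plain text 123 stays"
        assert s.scrub(text) == text

    def test_digest_deterministic(self):
        v = [patient("Jakob", "words"), patient("123 456", "number")]
        assert assemble_scrubber(v, CFG).digest \
            == assemble_scrubber(v, CFG).digest

    def test_digest_changes_with_values(self):
        a = assemble_scrubber([patient("Jakob", "words")], CFG)
        b = assemble_scrubber([patient("Jakub", "words")], CFG)
        assert a.digest != b.digest

    def test_category_placeholders(self):
        s = assemble_scrubber(
            [patient("Jakob", "words"),
             ScrubSourceValue("Mira", "words", "thirdparty")], CFG)
        assert s.scrub("Jakob and Mira") == "[___] and […]"

    def test_empty_text(self):
        assert scrub_text("", assemble_scrubber([], CFG)) == ""

    def test_unknown_method_rejected(self):
        with pytest.raises(ScrubberConfigError):
            ScrubSourceValue("x", "telepathy", "patient")

    def test_placeholder_with_word_characters_rejected(self):
        with pytest.raises(ScrubberConfigError):
            ScrubberConfig(placeholder_patient="[XXX]")

    def test_max_typos_above_one_rejected(self):
        with pytest.raises(ScrubberConfigError):
            ScrubberConfig(max_typos=2)

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="abcdef 123.", max_size=60))
    def test_idempotent_on_arbitrary_text(self, text):
        s = assemble_scrubber(
            [patient("Jakob Fairweather", "words"),
             patient("123 456", "number"),
             ScrubSourceValue("Mira", "words", "thirdparty")],
            ScrubberConfig(blacklist=("cab",)))
        once = s.scrub(text)
        assert s.scrub(once) == once


# ---------------------------------------------------------------------------
# fuzzy-matching contract against a brute-force edit-distance oracle

def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@settings(max_examples=300, derandomize=True)
@given(chunk=st.text("abcd", min_size=2, max_size=6),
       candidate=st.text("abcd", min_size=1, max_size=7))
def test_fuzzy_contract_matches_edit_distance_oracle(chunk, candidate):
    """Chunks of length >= 4 mask exactly the edit-distance-<=1
    neighbourhood; shorter chunks mask only exact (plus suffix) matches."""
    cfg = ScrubberConfig(word_suffixes=())      # suffixes tested separately
    patterns = build_word_patterns(chunk, cfg)
    assert len(patterns) == 1
    masked = re.fullmatch(patterns[0], candidate, re.IGNORECASE) is not None
    if len(chunk) >= cfg.min_word_length_for_typos:
        expected = levenshtein(chunk, candidate) <= 1
    else:
        expected = candidate == chunk
    assert masked == expected


@settings(max_examples=100, derandomize=True)
@given(chunk=st.text("abcd", min_size=4, max_size=6),
       candidate=st.text("abcd", min_size=1, max_size=7))
def test_suffix_applies_on_top_of_fuzzy_match(chunk, candidate):
    cfg = ScrubberConfig(word_suffixes=("s",), suffixes_with_typos=True)
    pattern = build_word_patterns(chunk, cfg)[0]
    masked = re.fullmatch(pattern, candidate, re.IGNORECASE) is not None
    core = levenshtein(chunk, candidate) <= 1
    suffixed = candidate.endswith("s") and \
        levenshtein(chunk, candidate[:-1]) <= 1
    assert masked == (core or suffixed)


def test_suffix_under_fuzzy_can_be_disabled():
    cfg = ScrubberConfig(word_suffixes=("s",), suffixes_with_typos=False)
    pattern = build_word_patterns("jakob", cfg)[0]
    # With suffixes disabled for fuzzy chunks, "jacobs" (1 typo + suffix)
    # must not match, while the plain 1-typo form still does.
    assert re.fullmatch(pattern, "jacob", re.IGNORECASE)
    assert not re.fullmatch(pattern, "jacobs", re.IGNORECASE)


def test_chunking_splits_on_all_non_alphanumerics():
    assert chunks_of("John Al'Rahem-Smith (Jr)") \
        == ["John", "Al", "Rahem", "Smith", "Jr"]
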