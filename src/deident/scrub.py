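"""Regex scrubber construction and application — the de-identification core.

Free text is masked using regular expressions generated from each patient's
structured identifiers. Five builder methods are provided:

* **words** — each alphanumeric chunk of the source value is masked wherever
  it occurs, optionally with configured suffixes (``Robert`` → ``Roberts``)
  and with tolerance for typographical errors (one character inserted,
  deleted, or substituted), so ``Jakob`` also masks ``Jacob``;
* **phrase** — the chunk sequence is masked only when the chunks occur in
  order, with arbitrary non-alphanumeric separators between them;
* **number** — the value is reduced to its digit string, which is masked
  regardless of interleaved spacing/punctuation, guarded by digit
  lookarounds so ``123 456`` does not fire inside ``1234567``;
* **code** — as number, but over the full alphanumeric sequence (postcodes);
* **date** — the date is decomposed into day/month/year and masked in
  numeric, named-month, two/four-digit-year, ordinal-suffixed, compact and
  timestamp-prefixed forms, in day-month-year, month-day-year and
  year-month-day orders.

Patterns are agglomerated per category into a *personalized scrubber*:
patient-identifying patterns, third-party patterns, and patient-independent
*nonspecific* patterns (fixed-length digit runs, UK postcode shapes,
blacklisted words). Application order is fixed — nonspecific, then patient,
then third party — and all matching is case-insensitive.

Typo tolerance is implemented by explicit enumeration of the edit-distance-1
neighbourhood as a regex alternation; ``max_typos`` therefore supports 0 or 1
(1 is the default and the conventional setting).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import re
from calendar import month_abbr, month_name
from dataclasses import dataclass, field
from typing import Iterable, Sequence

# Alphanumeric = word character minus underscore. Chunking splits source
# values on everything else; fuzzy substitution/insertion draws from this
# class so that generated patterns can never match placeholder underscores.
ALNUM = r"[^\W_]"
_CHUNK_RE = re.compile(r"[^\W_]+", re.UNICODE)


class ScrubberConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class ScrubberConfig:
    """Tunable scrubbing behaviour.

    Defaults follow conventional conservative settings: suffix "s", one
    typo allowed on chunks of >= 4 characters, minimum scrubbable string
    length 2, words/codes/dates/phrases anchored at word boundaries but
    numbers guarded by digit lookarounds only.
    """
    whitelist: frozenset[str] = frozenset()
    blacklist: tuple[str, ...] = ()
    word_suffixes: tuple[str, ...] = ("s",)
    max_typos: int = 1
    min_word_length_for_typos: int = 4
    min_string_length: int = 2
    suffixes_with_typos: bool = True
    nonspecific_number_lengths: tuple[int, ...] = ()
    scrub_uk_postcodes: bool = False
    anchor_words_at_boundaries: bool = True
    anchor_numbers_at_boundaries: bool = False
    placeholder_patient: str = "[___]"
    placeholder_thirdparty: str = "[…]"
    placeholder_nonspecific: str = "[~~~]"

    def __post_init__(self):
        if self.min_string_length < 1:
            raise ScrubberConfigError("min_string_length must be >= 1")
        if self.max_typos < 0:
            raise ScrubberConfigError("max_typos must be >= 0")
        if self.max_typos > 1:
            raise ScrubberConfigError(
                "max_typos > 1 is not supported by the edit-distance "
                "alternation construction")
        ph = (self.placeholder_patient, self.placeholder_thirdparty,
              self.placeholder_nonspecific)
        if len(set(ph)) != 3:
            raise ScrubberConfigError("placeholders must be pairwise distinct")
        for p in ph:
            if _CHUNK_RE.search(p) or re.search(r"\d", p):
                raise ScrubberConfigError(
                    f"placeholder {p!r} contains alphanumeric characters; "
                    "scrubbing would not be idempotent")

    def normalized_whitelist(self) -> frozenset[str]:
        return frozenset(w.lower() for w in self.whitelist)


def chunks_of(source: str) -> list[str]:
    """Split a source value into alphanumeric chunks."""
    return _CHUNK_RE.findall(source)


# ---------------------------------------------------------------------------
# Pattern builders (return regex source strings, compiled at assembly)

def _edit1_alternation(chunk: str) -> str:
    """Regex alternation matching every string within edit distance <= 1
    of *chunk* (over alphanumeric characters)."""
    esc = [re.escape(c) for c in chunk]
    alts = ["".join(esc)]                                  # exact
    for i in range(len(esc)):                              # substitution
        alts.append("".join(esc[:i]) + ALNUM + "".join(esc[i + 1:]))
    for i in range(len(esc)):                              # deletion
        alts.append("".join(esc[:i]) + "".join(esc[i + 1:]))
    for i in range(len(esc) + 1):                          # insertion
        alts.append("".join(esc[:i]) + ALNUM + "".join(esc[i:]))
    # Dedupe, preserving order (substitution i==exact overlap etc.)
    seen: dict[str, None] = {}
    for a in alts:
        seen.setdefault(a, None)
    return "|".join(seen)


def _suffix_group(cfg: ScrubberConfig) -> str:
    if not cfg.word_suffixes:
        return ""
    alts = "|".join(re.escape(s) for s in
                    sorted(cfg.word_suffixes, key=len, reverse=True))
    return f"(?:{alts})?"


def build_word_patterns(source: str, cfg: ScrubberConfig) -> list[str]:
    """One pattern per retained chunk of *source*.

    Chunks shorter than ``min_string_length`` or on the whitelist are
    dropped. Chunks of length >= ``min_word_length_for_typos`` (when
    ``max_typos`` is 1) match their whole edit-distance-1 neighbourhood.
    """
    wl = cfg.normalized_whitelist()
    b = r"\b" if cfg.anchor_words_at_boundaries else ""
    patterns = []
    for chunk in chunks_of(source):
        if len(chunk) < cfg.min_string_length or chunk.lower() in wl:
            continue
        fuzzy = cfg.max_typos >= 1 and len(chunk) >= cfg.min_word_length_for_typos
        core = f"(?:{_edit1_alternation(chunk)})" if fuzzy else re.escape(chunk)
        suffix = _suffix_group(cfg) if (not fuzzy or cfg.suffixes_with_typos) else ""
        patterns.append(f"{b}{core}{suffix}{b}")
    return patterns


def build_phrase_pattern(source: str, cfg: ScrubberConfig) -> str | None:
    """Single pattern matching the chunk sequence in order, any
    non-alphanumeric separators between chunks."""
    chunks = chunks_of(source)
    if not chunks or sum(map(len, chunks)) < cfg.min_string_length:
        return None
    b = r"\b" if cfg.anchor_words_at_boundaries else ""
    body = r"\W+".join(re.escape(c) for c in chunks)
    return f"{b}{body}{b}"


def build_number_pattern(source: "str | int", cfg: ScrubberConfig) -> str | None:
    """Pattern for the digit string of *source*, punctuation-insensitive,
    digit-lookaround guarded (or \\b-anchored if so configured)."""
    digits = re.sub(r"\D", "", str(source))
    if len(digits) < cfg.min_string_length:
        return None
    body = r"\W*".join(digits)
    if cfg.anchor_numbers_at_boundaries:
        return rf"\b{body}\b"
    return rf"(?<!\d){body}(?!\d)"


def build_code_pattern(source: str, cfg: ScrubberConfig) -> str | None:
    """Pattern for the alphanumeric sequence of *source*; no semantic rules."""
    chars = "".join(chunks_of(str(source)))
    if len(chars) < cfg.min_string_length:
        return None
    b = r"\b" if cfg.anchor_words_at_boundaries else ""
    body = r"\W*".join(re.escape(c) for c in chars)
    return f"{b}{body}{b}"


def _month_alternation(month: int) -> str:
    full = month_name[month]        # "January"
    abbr = month_abbr[month]        # "Jan"
    name = re.escape(abbr)
    if len(full) > len(abbr):
        name += f"(?:{re.escape(full[len(abbr):])})?"
    return f"(?:0*{month}|{name})"


def build_date_patterns(source: "datetime.date | datetime.datetime | str",
                        cfg: ScrubberConfig) -> list[str]:
    """Patterns masking a calendar date in its many written forms.

    Day-month-year, month-day-year and year-month-day orders; numeric or
    named month (3-letter or full); two- or four-digit year; optional
    ordinal suffix on the day; arbitrary non-word separators including
    none (compact ``20130107``); optional compact timestamp suffix
    (``20130107T0123``).
    """
    if isinstance(source, str):
        try:
            source = datetime.date.fromisoformat(source.strip())
        except ValueError:
            from dateutil import parser as _dtparser
            try:
                source = _dtparser.parse(source, dayfirst=True).date()
            except (ValueError, OverflowError) as e:
                raise ScrubberConfigError(
                    f"invalid date {source!r}: {e}") from None
    if isinstance(source, datetime.datetime):
        source = source.date()
    if not isinstance(source, datetime.date):
        raise ScrubberConfigError(f"not a date: {source!r}")
    day = rf"0*{source.day}(?:st|nd|rd|th)?"
    month = _month_alternation(source.month)
    century, yy = divmod(source.year, 100)
    year = rf"(?:{century:02d})?{yy:02d}"
    b = r"\b" if cfg.anchor_words_at_boundaries else ""
    sep = r"\W*"
    return [
        f"{b}{day}{sep}{month}{sep}{year}{b}",
        f"{b}{month}{sep}{day}{sep}{year}{b}",
        rf"{b}{year}{sep}{month}{sep}{day}(?:T\d+)?{b}",
    ]


# The six UK postcode layouts: A9 9AA, A99 9AA, AA9 9AA, AA99 9AA,
# A9A 9AA, AA9A 9AA.
UK_POSTCODE_PATTERNS: tuple[str, ...] = (
    r"\b[A-Z][0-9]\s*[0-9][A-Z][A-Z]\b",
    r"\b[A-Z][0-9][0-9]\s*[0-9][A-Z][A-Z]\b",
    r"\b[A-Z][A-Z][0-9]\s*[0-9][A-Z][A-Z]\b",
    r"\b[A-Z][A-Z][0-9][0-9]\s*[0-9][A-Z][A-Z]\b",
    r"\b[A-Z][0-9][A-Z]\s*[0-9][A-Z][A-Z]\b",
    r"\b[A-Z][A-Z][0-9][A-Z]\s*[0-9][A-Z][A-Z]\b",
)


def build_nonspecific_patterns(cfg: ScrubberConfig) -> list[str]:
    """Patient-independent patterns: fixed-length digit runs (with optional
    intervening horizontal whitespace), UK postcode shapes, blacklist words."""
    patterns = []
    for n in cfg.nonspecific_number_lengths:
        if n >= 1:
            body = r"[ \t]*".join(["[0-9]"] * n)
            patterns.append(rf"(?<!\d){body}(?!\d)")
    if cfg.scrub_uk_postcodes:
        patterns.extend(UK_POSTCODE_PATTERNS)
    for word in cfg.blacklist:
        chunks = chunks_of(word)
        if chunks:
            patterns.append(r"\b" + r"\W+".join(map(re.escape, chunks)) + r"\b")
    return patterns


# ---------------------------------------------------------------------------
# Scrub-source values and scrubber assembly

@dataclass(frozen=True)
class ScrubSourceValue:
    """One structured identifier value, its scrub method, and whether it
    identifies the patient or a third party."""
    raw: "str | int | datetime.date"
    method: str            # words | phrase | number | code | date
    kind: str              # patient | thirdparty

    def __post_init__(self):
        if self.kind not in ("patient", "thirdparty"):
            raise ScrubberConfigError(f"unknown scrub-source kind {self.kind!r}")
        if self.method not in ("words", "phrase", "number", "code", "date"):
            raise ScrubberConfigError(f"unknown scrub method {self.method!r}")


def patterns_for_value(value: ScrubSourceValue, cfg: ScrubberConfig) -> list[str]:
    raw = value.raw
    if value.method == "words":
        return build_word_patterns(str(raw), cfg)
    if value.method == "phrase":
        p = build_phrase_pattern(str(raw), cfg)
        return [p] if p else []
    if value.method == "number":
        p = build_number_pattern(raw, cfg)
        return [p] if p else []
    if value.method == "code":
        p = build_code_pattern(str(raw), cfg)
        return [p] if p else []
    return build_date_patterns(raw, cfg)


@dataclass
class PersonalizedScrubber:
    """The agglomerated patterns for one patient.

    Application order is fixed: (1) nonspecific, (2) patient, (3) third
    party; within the latter two, pattern order follows the data
    dictionary. All matching is case-insensitive.
    """
    cfg: ScrubberConfig
    nonspecific_sources: list[str] = field(default_factory=list)
    patient_sources: list[str] = field(default_factory=list)
    thirdparty_sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        flags = re.IGNORECASE | re.UNICODE
        self._nonspecific = [re.compile(p, flags) for p in self.nonspecific_sources]
        self._patient = self._agglomerate(self.patient_sources, flags)
        self._thirdparty = self._agglomerate(self.thirdparty_sources, flags)
        wl = self.cfg.normalized_whitelist()
        self._whitelist = wl

    @staticmethod
    def _agglomerate(sources: Sequence[str], flags: int) -> "re.Pattern | None":
        if not sources:
            return None
        return re.compile("|".join(f"(?:{p})" for p in sources), flags)

    @property
    def digest(self) -> str:
        """Content hash of the scrubber, for incremental change detection."""
        payload = json.dumps({
            "nonspecific": self.nonspecific_sources,
            "patient": self.patient_sources,
            "thirdparty": self.thirdparty_sources,
            "placeholders": [self.cfg.placeholder_nonspecific,
                             self.cfg.placeholder_patient,
                             self.cfg.placeholder_thirdparty],
        }, sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()

    def _replace(self, pattern: "re.Pattern", text: str, placeholder: str,
                 guard_whitelist: bool) -> str:
        if guard_whitelist and self._whitelist:
            wl = self._whitelist

            def sub(m: "re.Match") -> str:
                if m.group(0).lower() in wl:
                    return m.group(0)
                return placeholder
            return pattern.sub(sub, text)
        return pattern.sub(placeholder, text)

    def _pass(self, text: str) -> str:
        for pat in self._nonspecific:
            text = self._replace(pat, text, self.cfg.placeholder_nonspecific,
                                 guard_whitelist=False)
        if self._patient is not None:
            text = self._replace(self._patient, text,
                                 self.cfg.placeholder_patient,
                                 guard_whitelist=True)
        if self._thirdparty is not None:
            text = self._replace(self._thirdparty, text,
                                 self.cfg.placeholder_thirdparty,
                                 guard_whitelist=True)
        return text

    def scrub(self, text: str) -> str:
        """Mask all matches (leftmost, non-overlapping within a pattern).

        The category passes are repeated until the text stops changing:
        masking can bring previously separated fragments of another
        identifier into adjacency (placeholders contain no alphanumerics,
        so flexible-separator patterns may span them), and iterating to the
        fixpoint makes scrubbing idempotent. Termination is guaranteed
        because every replacement removes at least one alphanumeric
        character and inserts none.
        """
        if not text:
            return text
        while True:
            new = self._pass(text)
            if new == text:
                return new
            text = new


def assemble_scrubber(values: Iterable[ScrubSourceValue],
                      cfg: ScrubberConfig,
                      nonspecific: Sequence[str] | None = None
                      ) -> PersonalizedScrubber:
    """Compile scrub-source values (already in data-dictionary order) into a
    personalized scrubber. *nonspecific* lets a prebuilt shared pattern pool
    be reused across patients; by default it is built from the config."""
    if nonspecific is None:
        nonspecific = build_nonspecific_patterns(cfg)
    patient: list[str] = []
    thirdparty: list[str] = []
    for value in values:
        target = patient if value.kind == "patient" else thirdparty
        for p in patterns_for_value(value, cfg):
            if p not in target:        # dedupe, preserving order
                target.append(p)
    return PersonalizedScrubber(cfg=cfg,
                                nonspecific_sources=list(nonspecific),
                                patient_sources=patient,
                                thirdparty_sources=thirdparty)


def scrub_text(text: str, scrubber: PersonalizedScrubber) -> str:
    """Functional form of :meth:`PersonalizedScrubber.scrub`."""
    return scrubber.scrub(text)
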