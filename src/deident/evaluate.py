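"""Scoring de-identification output against gold annotations.

Signal-detection framing: a *target* is a word of the source text that a
human judged to require removal in context; a *positive* response is
masking. A **hit** is the correct masking of a target, a **miss** a target
left in the clear, a **false alarm** the masking of a non-target, and a
**correct rejection** a non-target left alone. Sensitivity (recall) is
hits/(hits+misses); precision (positive predictive value) is
hits/(hits+false alarms).

Words are counted conventionally for the source and each mask counts as
one word, so a multi-word identifier masked by a single placeholder is one
hit, while one masked per-word is several; a partially masked multi-word
identifier scores one hit per masked word and one miss per unmasked word.

Identifiers are stratified into *known* (recorded in structured source
fields, hence available to the scrubber) and *unknown* (present only in
free text — nicknames, misfiled records). Hits and false alarms do not
depend on the stratum, so precision is identical between the known and
all-identifier strata; only misses/correct rejections move.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Iterable, Sequence

DEFAULT_PLACEHOLDERS = ("[___]", "[…]", "[~~~]")

STRATA = ("known", "all")


class AlignmentError(ValueError):
    """Scrubbed text is not derivable from the raw text by placeholder
    substitution alone."""


class UndefinedMetricError(ZeroDivisionError):
    pass


# ---------------------------------------------------------------------------
# Gold annotations

@dataclass(frozen=True)
class GoldSpan:
    """A gold identifier span in a raw document (character offsets)."""
    doc_id: str
    start: int
    end: int
    subclass: str = "known"      # known | unknown
    necessity: bool = True       # did context require removal?

    def __post_init__(self):
        if self.subclass not in ("known", "unknown"):
            raise ValueError(f"bad subclass {self.subclass!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")


def parse_gold_tsv(text: str) -> list[GoldSpan]:
    spans = []
    lines = text.splitlines()
    if not lines:
        return spans
    header = lines[0].split("\t")
    expected = ["doc_id", "start", "end", "subclass", "necessity"]
    if header != expected:
        raise ValueError(f"gold TSV header must be {expected}")
    for line in lines[1:]:
        if not line.strip():
            continue
        doc_id, start, end, subclass, necessity = line.split("\t")
        spans.append(GoldSpan(doc_id, int(start), int(end), subclass,
                              necessity == "Y"))
    return spans


def write_gold_tsv(spans: Iterable[GoldSpan]) -> str:
    lines = ["doc_id\tstart\tend\tsubclass\tnecessity"]
    for s in spans:
        lines.append(f"{s.doc_id}\t{s.start}\t{s.end}\t{s.subclass}\t"
                     f"{'Y' if s.necessity else ''}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Confusion counts

@dataclass
class ConfusionCounts:
    n_words: int = 0
    hits: int = 0
    misses: int = 0
    false_alarms: int = 0
    correct_rejections: int = 0

    def __post_init__(self):
        self.check()

    def check(self) -> None:
        total = (self.hits + self.misses + self.false_alarms +
                 self.correct_rejections)
        if total != self.n_words:
            raise ValueError(
                f"cells sum to {total}, but n_words={self.n_words}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            n_words=self.n_words + other.n_words,
            hits=self.hits + other.hits,
            misses=self.misses + other.misses,
            false_alarms=self.false_alarms + other.false_alarms,
            correct_rejections=self.correct_rejections +
            other.correct_rejections)


def sensitivity(counts: ConfusionCounts) -> float:
    """P(hit | target) = hits / (hits + misses)."""
    denom = counts.hits + counts.misses
    if denom == 0:
        raise UndefinedMetricError("no targets: sensitivity undefined")
    return counts.hits / denom


def precision(counts: ConfusionCounts) -> float:
    """P(hit | positive) = hits / (hits + false alarms)."""
    denom = counts.hits + counts.false_alarms
    if denom == 0:
        raise UndefinedMetricError("no positives: precision undefined")
    return counts.hits / denom


# ---------------------------------------------------------------------------
# Document scoring

def _mask_spans(raw: str, scrubbed: str,
                placeholders: Sequence[str]) -> list[tuple[int, int]]:
    """Character spans of *raw* that were replaced by placeholders.

    Uses a character-level alignment of raw and scrubbed; each placeholder
    occurrence maps to one raw span (one mask = one word). Raises
    AlignmentError if the scrubbed text contains inserted material other
    than placeholders.
    """
    if raw == scrubbed:
        return []
    ph_re = re.compile("|".join(re.escape(p) for p in
                                sorted(placeholders, key=len, reverse=True)))
    sm = SequenceMatcher(None, raw, scrubbed, autojunk=False)
    opcodes = sm.get_opcodes()
    # Map scrubbed char position -> raw interval, for replaced regions.
    spans: list[tuple[int, int]] = []
    for m in ph_re.finditer(scrubbed):
        j1, j2 = m.span()
        raw_lo, raw_hi = None, None
        for tag, i1, i2, jj1, jj2 in opcodes:
            if jj2 <= j1 or jj1 >= j2:
                continue
            if tag == "equal":
                raise AlignmentError(
                    "placeholder text overlaps an unchanged region")
            raw_lo = i1 if raw_lo is None else min(raw_lo, i1)
            raw_hi = i2 if raw_hi is None else max(raw_hi, i2)
        if raw_lo is None:
            raise AlignmentError("placeholder not alignable to raw text")
        spans.append((raw_lo, raw_hi))
    # Any replaced/inserted scrubbed region must consist of placeholders;
    # separator whitespace/punctuation may end up inside a replace block
    # when the matcher lumps adjacent masks together, but inserted *word*
    # characters outside a placeholder mean the pair is not a scrub result.
    covered = [False] * len(scrubbed)
    for m in ph_re.finditer(scrubbed):
        for k in range(*m.span()):
            covered[k] = True
    for tag, i1, i2, j1, j2 in opcodes:
        if tag in ("replace", "insert"):
            for k in range(j1, j2):
                if not covered[k] and re.match(r"\w", scrubbed[k]):
                    raise AlignmentError(
                        f"scrubbed text contains non-placeholder insertion "
                        f"at position {k}: {scrubbed[j1:j2]!r}")
    # Merge spans that map to the same raw region (adjacent placeholders
    # from one replacement share opcodes); keep one mask per placeholder.
    return spans


def _overlaps(lo: int, hi: int, spans: Iterable[GoldSpan]) -> "GoldSpan | None":
    for s in spans:
        if lo < s.end and s.start < hi:
            return s
    return None


def score_document(raw: str, scrubbed: str, gold: Sequence[GoldSpan],
                   placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS
                   ) -> dict[str, ConfusionCounts]:
    """Score one raw/scrubbed pair against its gold spans.

    Returns counts for both strata: ``"known"`` treats only known-subclass
    spans as targets (unknown identifiers become correct rejections when
    unmasked); ``"all"`` treats every necessary span as a target.
    """
    targets = [s for s in gold if s.necessity]
    known_targets = [s for s in targets if s.subclass == "known"]
    masks = _mask_spans(raw, scrubbed, placeholders)

    tokens = [(m.start(), m.end()) for m in re.finditer(r"\S+", raw)]
    consumed = []
    for lo, hi in tokens:
        if any(lo < mhi and mlo < hi for mlo, mhi in masks):
            continue                       # token participates in a mask
        consumed.append((lo, hi))

    out = {}
    for stratum, stratum_targets in (("known", known_targets),
                                     ("all", targets)):
        hits = fas = misses = crs = 0
        for mlo, mhi in masks:
            # Hits/false alarms are stratum-independent: a masked word is a
            # hit iff it was (any-subclass) identifying material.
            if _overlaps(mlo, mhi, targets):
                hits += 1
            else:
                fas += 1
        for lo, hi in consumed:
            if _overlaps(lo, hi, stratum_targets):
                misses += 1
            else:
                crs += 1
        out[stratum] = ConfusionCounts(
            n_words=len(masks) + len(consumed), hits=hits, misses=misses,
            false_alarms=fas, correct_rejections=crs)
    return out


def score_corpus(documents: Iterable[tuple[str, str, Sequence[GoldSpan]]],
                 placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS
                 ) -> dict[str, ConfusionCounts]:
    """Aggregate score over (raw, scrubbed, gold) documents."""
    totals = {s: ConfusionCounts() for s in STRATA}
    for raw, scrubbed, gold in documents:
        counts = score_document(raw, scrubbed, gold, placeholders)
        for s in STRATA:
            totals[s] = totals[s] + counts[s]
    return totals


def condition_report(totals: dict[str, ConfusionCounts],
                     label: str = "condition") -> str:
    """Format aggregated counts and metrics as a stratified TSV table."""
    lines = [f"metric\t{label}"]
    any_stratum = totals["all"]
    lines.append(f"n_words\t{any_stratum.n_words}")
    lines.append(f"hits\t{any_stratum.hits}")
    lines.append(f"false_alarms\t{any_stratum.false_alarms}")
    for s in STRATA:
        c = totals[s]
        lines.append(f"{s}:misses\t{c.misses}")
        lines.append(f"{s}:correct_rejections\t{c.correct_rejections}")
        try:
            lines.append(f"{s}:sensitivity\t{sensitivity(c):.3f}")
        except UndefinedMetricError:
            lines.append(f"{s}:sensitivity\tNA")
        try:
            lines.append(f"{s}:precision\t{precision(c):.3f}")
        except UndefinedMetricError:
            lines.append(f"{s}:precision\tNA")
    return "\n".join(lines) + "\n"
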