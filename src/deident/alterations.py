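"""Per-column content alterations applied on the way to the destination.

The data dictionary attaches an ordered alteration chain to each column:
omission, scrubbing, truncating dates to the first of the month (so that
approximate age survives but the exact birthday does not), stripping HTML
tags/escapes, extracting text from a referenced document, and skipping
whole rows on inclusion/exclusion values. NULLs pass through every
alteration unchanged.

Document text extraction is a pluggable registry; plain text and HTML are
built in, and handlers for binary office formats can be registered by
deployments that need them.
"""

from __future__ import annotations

import datetime
import html
import re
from html.parser import HTMLParser
from io import StringIO
from typing import Callable

from dateutil import parser as dtparser

from .datadict import Alteration
from .scrub import PersonalizedScrubber


class RowSkipped(Exception):
    """Raised when a skip_row alteration excludes the whole row."""


class ExtractorUnavailableError(RuntimeError):
    pass


class _TagStripper(HTMLParser):
    def __init__(self):
        super().__init__(convert_charrefs=True)
        self._out = StringIO()

    def handle_data(self, data: str) -> None:
        self._out.write(data)

    def text(self) -> str:
        return self._out.getvalue()


def strip_html(value: str) -> str:
    """Remove HTML tags and decode character entities, yielding plain text."""
    stripper = _TagStripper()
    stripper.feed(value)
    stripper.close()
    return stripper.text()


_BACKSLASH_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", '"': '"', "'": "'",
                      "\\": "\\", "0": ""}


def strip_escapes(value: str) -> str:
    """Decode HTML entities and common backslash escape sequences."""
    value = html.unescape(value)
    return re.sub(r"\\(.)",
                  lambda m: _BACKSLASH_ESCAPES.get(m.group(1), m.group(1)),
                  value)


def parse_date(value: str) -> "datetime.date":
    """ISO dates exactly; otherwise flexible day-first parsing."""
    try:
        return datetime.date.fromisoformat(value.strip())
    except ValueError:
        return dtparser.parse(value, dayfirst=True).date()


def truncate_date(value: str) -> str:
    """Map any parseable date to the first of its month (ISO format)."""
    return parse_date(value).replace(day=1).isoformat()


# -- document text extraction -------------------------------------------------

TextExtractor = Callable[[str], str]

_EXTRACTORS: dict[str, TextExtractor] = {
    "txt": lambda v: v,
    "html": strip_html,
    "htm": strip_html,
    "xml": strip_html,
}


def register_extractor(fmt: str, fn: TextExtractor) -> None:
    _EXTRACTORS[fmt.lower().lstrip(".")] = fn


def extract_text(value: str, fmt: str = "txt",
                 on_unavailable: str = "error") -> "str | None":
    """Extract plain text from document content of the given format.

    Binary formats have no built-in handler; *on_unavailable* chooses
    between a hard error and skip-with-warning (returns NULL).
    """
    fn = _EXTRACTORS.get(fmt.lower().lstrip("."))
    if fn is None:
        if on_unavailable == "skip":
            import warnings
            warnings.warn(f"no text extractor for format {fmt!r}; "
                          "value dropped", stacklevel=2)
            return None
        raise ExtractorUnavailableError(f"no text extractor for {fmt!r}")
    return fn(value)


# -- the chain ----------------------------------------------------------------

def apply_alterations(value: "str | None",
                      alterations: "tuple[Alteration, ...]",
                      scrubber: "PersonalizedScrubber | None" = None,
                      doc_format: str = "txt",
                      on_extractor_unavailable: str = "error") -> "str | None":
    """Apply an alteration chain left to right; NULL passes untouched.

    Raises :class:`RowSkipped` when a skip_row alteration excludes the row
    (skip_row consults the value even when it is NULL).
    """
    for alt in alterations:
        if alt.kind == "skip_row":
            v = "" if value is None else value
            if alt.include_values and v not in alt.include_values:
                raise RowSkipped(v)
            if alt.exclude_values and v in alt.exclude_values:
                raise RowSkipped(v)
            continue
        if alt.kind == "omit":
            return None
        if value is None:
            continue
        if alt.kind == "scrub":
            if scrubber is None:
                raise ValueError("scrub alteration needs a scrubber")
            value = scrubber.scrub(value)
        elif alt.kind == "truncate_date":
            value = truncate_date(value)
        elif alt.kind == "strip_html":
            value = strip_html(value)
        elif alt.kind == "strip_escapes":
            value = strip_escapes(value)
        elif alt.kind == "extract_text":
            value = extract_text(value, doc_format,
                                 on_unavailable=on_extractor_unavailable)
    return value
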