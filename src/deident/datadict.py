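"""The data dictionary: one TSV row per source column, driving the engine.

The dictionary tells the engine, for every column of every source table,
where the column goes in the destination, whether its values are used to
build scrubbing patterns (*scrub-source* columns), which scrub method those
values take (words / phrase / number / code / date), which column carries
the patient ID, and which content alterations (omission, scrubbing, date
truncation, HTML stripping, row skipping, ...) apply on the way through.

Dictionaries can be parsed from and written to TSV, auto-drafted from a
source schema by configurable column-name heuristics, and incrementally
merged when the source schema changes. A drafted or merged dictionary
carries ``draft_flag=True`` and is refused by the engine until a human
review step clears the flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

# ---------------------------------------------------------------------------
# Vocabulary

SCRUB_SRC_KINDS = ("none", "patient", "thirdparty")
SCRUB_METHODS = ("words", "phrase", "number", "code", "date")
INDEX_KINDS = ("none", "normal", "fulltext")
ALTERATION_KINDS = ("omit", "scrub", "truncate_date", "strip_html",
                    "strip_escapes", "extract_text", "skip_row")

# Canonical TSV header. Unknown columns are rejected so that dictionaries
# stay self-describing; missing columns raise a format error naming them.
HEADER = (
    "src_db", "src_table", "src_field", "src_datatype",
    "scrub_src_kind", "scrub_method",
    "is_pid", "is_mpid", "is_pk", "is_master_pid_column",
    "alterations",
    "dest_table", "dest_field", "dest_datatype",
    "index_kind", "removed",
)

DRAFT_MARKER = "#draft"


class DataDictionaryFormatError(ValueError):
    """Malformed TSV: wrong header, bad flag value, unparseable alteration."""


class DataDictionaryValidationError(ValueError):
    """Structurally well-formed dictionary violating a semantic invariant."""


# ---------------------------------------------------------------------------
# Rows

@dataclass(frozen=True)
class Alteration:
    """A single content alteration; include/exclude values only for skip_row."""
    kind: str
    include_values: tuple[str, ...] = ()
    exclude_values: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ALTERATION_KINDS:
            raise DataDictionaryFormatError(f"unknown alteration {self.kind!r}")
        if self.kind != "skip_row" and (self.include_values or self.exclude_values):
            raise DataDictionaryFormatError(
                f"alteration {self.kind!r} takes no include/exclude values")

    def serialize(self) -> str:
        if self.kind != "skip_row":
            return self.kind
        parts = []
        if self.include_values:
            parts.append("include:" + "|".join(self.include_values))
        if self.exclude_values:
            parts.append("exclude:" + "|".join(self.exclude_values))
        return "skip_row(%s)" % ";".join(parts)


_SKIP_ROW_RE = re.compile(r"^skip_row\((.*)\)$")


def parse_alterations(text: str) -> tuple[Alteration, ...]:
    if not text:
        return ()
    out = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _SKIP_ROW_RE.match(token)
        if m:
            include: tuple[str, ...] = ()
            exclude: tuple[str, ...] = ()
            for clause in filter(None, m.group(1).split(";")):
                if clause.startswith("include:"):
                    include = tuple(clause[len("include:"):].split("|"))
                elif clause.startswith("exclude:"):
                    exclude = tuple(clause[len("exclude:"):].split("|"))
                else:
                    raise DataDictionaryFormatError(
                        f"bad skip_row clause {clause!r}")
            out.append(Alteration("skip_row", include, exclude))
        else:
            out.append(Alteration(token))
    return tuple(out)


@dataclass(frozen=True)
class DataDictionaryRow:
    src_db: str
    src_table: str
    src_field: str
    src_datatype: str = ""
    scrub_src_kind: str = "none"
    scrub_method: str = ""
    is_pid: bool = False
    is_mpid: bool = False
    is_pk: bool = False
    is_master_pid_column: bool = False
    alterations: tuple[Alteration, ...] = ()
    dest_table: str = ""
    dest_field: str = ""
    dest_datatype: str = ""
    index_kind: str = "none"
    removed: bool = False

    def __post_init__(self):
        if self.scrub_src_kind not in SCRUB_SRC_KINDS:
            raise DataDictionaryValidationError(
                f"{self._where()}: bad scrub_src_kind {self.scrub_src_kind!r}")
        if self.index_kind not in INDEX_KINDS:
            raise DataDictionaryValidationError(
                f"{self._where()}: bad index_kind {self.index_kind!r}")
        if self.scrub_src_kind == "none":
            if self.scrub_method:
                raise DataDictionaryValidationError(
                    f"{self._where()}: scrub_method set without scrub_src_kind")
        else:
            if self.scrub_method not in SCRUB_METHODS:
                raise DataDictionaryValidationError(
                    f"{self._where()}: scrub-source column needs a valid "
                    f"scrub_method, got {self.scrub_method!r}")
        if self.is_master_pid_column and not self.is_pid:
            raise DataDictionaryValidationError(
                f"{self._where()}: is_master_pid_column implies is_pid")
        if self.omitted:
            if self.dest_table or self.dest_field:
                raise DataDictionaryValidationError(
                    f"{self._where()}: omitted column must have no destination")
        elif not self.removed and not (self.dest_table and self.dest_field):
            raise DataDictionaryValidationError(
                f"{self._where()}: column needs dest_table and dest_field "
                "(or the 'omit' alteration)")
        if self.is_pid and self.scrubbed:
            raise DataDictionaryValidationError(
                f"{self._where()}: a patient-ID column cannot itself be scrubbed")

    def _where(self) -> str:
        return f"{self.src_db}.{self.src_table}.{self.src_field}"

    @property
    def omitted(self) -> bool:
        return any(a.kind == "omit" for a in self.alterations)

    @property
    def scrubbed(self) -> bool:
        return any(a.kind == "scrub" for a in self.alterations)

    @property
    def is_scrub_source(self) -> bool:
        return self.scrub_src_kind != "none"

    # -- TSV (de)serialization ------------------------------------------------

    def to_tsv_dict(self) -> dict[str, str]:
        b = lambda v: "Y" if v else ""
        return {
            "src_db": self.src_db, "src_table": self.src_table,
            "src_field": self.src_field, "src_datatype": self.src_datatype,
            "scrub_src_kind": "" if self.scrub_src_kind == "none" else self.scrub_src_kind,
            "scrub_method": self.scrub_method,
            "is_pid": b(self.is_pid), "is_mpid": b(self.is_mpid),
            "is_pk": b(self.is_pk),
            "is_master_pid_column": b(self.is_master_pid_column),
            "alterations": ",".join(a.serialize() for a in self.alterations),
            "dest_table": self.dest_table, "dest_field": self.dest_field,
            "dest_datatype": self.dest_datatype,
            "index_kind": "" if self.index_kind == "none" else self.index_kind,
            "removed": b(self.removed),
        }

    @classmethod
    def from_tsv_dict(cls, d: dict[str, str]) -> "DataDictionaryRow":
        def b(name: str) -> bool:
            v = (d.get(name) or "").strip()
            if v in ("", "N", "0"):
                return False
            if v in ("Y", "1"):
                return True
            raise DataDictionaryFormatError(f"bad boolean {v!r} in {name}")
        return cls(
            src_db=d["src_db"], src_table=d["src_table"],
            src_field=d["src_field"], src_datatype=d.get("src_datatype", ""),
            scrub_src_kind=(d.get("scrub_src_kind") or "none"),
            scrub_method=d.get("scrub_method", ""),
            is_pid=b("is_pid"), is_mpid=b("is_mpid"), is_pk=b("is_pk"),
            is_master_pid_column=b("is_master_pid_column"),
            alterations=parse_alterations(d.get("alterations", "")),
            dest_table=d.get("dest_table", ""), dest_field=d.get("dest_field", ""),
            dest_datatype=d.get("dest_datatype", ""),
            index_kind=(d.get("index_kind") or "none"),
            removed=b("removed"),
        )


# ---------------------------------------------------------------------------
# The dictionary

@dataclass
class DataDictionary:
    rows: list[DataDictionaryRow] = field(default_factory=list)
    draft_flag: bool = False

    # -- queries --------------------------------------------------------------

    def rows_for_table(self, src_table: str) -> list[DataDictionaryRow]:
        return [r for r in self.rows if r.src_table == src_table and not r.removed]

    def source_tables(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            if not r.removed:
                seen.setdefault(r.src_table, None)
        return list(seen)

    def patient_tables(self) -> list[str]:
        return [t for t in self.source_tables()
                if any(r.is_pid for r in self.rows_for_table(t))]

    def pid_row(self, src_table: str) -> DataDictionaryRow | None:
        for r in self.rows_for_table(src_table):
            if r.is_pid:
                return r
        return None

    def master_pid_row(self) -> DataDictionaryRow | None:
        for r in self.rows:
            if r.is_master_pid_column and not r.removed:
                return r
        return None

    def pk_row(self, src_table: str) -> DataDictionaryRow | None:
        for r in self.rows_for_table(src_table):
            if r.is_pk:
                return r
        return None

    def scrub_source_rows(self) -> list[DataDictionaryRow]:
        """Scrub-source rows in dictionary order (the scrubber application order)."""
        return [r for r in self.rows if r.is_scrub_source and not r.removed]

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        seen_dest: dict[tuple[str, str], str] = {}
        for r in self.rows:
            if r.removed or r.omitted:
                continue
            key = (r.dest_table, r.dest_field)
            if key in seen_dest:
                raise DataDictionaryValidationError(
                    f"duplicate destination {key[0]}.{key[1]} "
                    f"({seen_dest[key]} and {r._where()})")
            seen_dest[key] = r._where()

        for table in self.source_tables():
            trows = self.rows_for_table(table)
            n_pid = sum(r.is_pid for r in trows)
            if any(r.scrubbed for r in trows) and n_pid != 1:
                raise DataDictionaryValidationError(
                    f"table {table!r} has scrubbed columns but {n_pid} "
                    "patient-ID rows (need exactly 1)")
            if n_pid > 1:
                raise DataDictionaryValidationError(
                    f"table {table!r} has {n_pid} patient-ID rows")

        masters = [r for r in self.rows if r.is_master_pid_column and not r.removed]
        if any(r.is_pid for r in self.rows if not r.removed):
            if len(masters) != 1:
                raise DataDictionaryValidationError(
                    f"dictionary must flag exactly one master patient-ID "
                    f"column, found {len(masters)}")

    def assert_engine_ready(self) -> None:
        """A dictionary is usable only after validation and human review."""
        if self.draft_flag:
            raise DataDictionaryValidationError(
                "data dictionary is a draft pending human review; "
                "inspect it and clear the draft flag (accept-dd) first")
        self.validate()
        if self.master_pid_row() is None and self.patient_tables():
            raise DataDictionaryValidationError("no master patient-ID column")


# ---------------------------------------------------------------------------
# TSV parse / write

def parse_data_dictionary(tsv_text: str) -> DataDictionary:
    lines = tsv_text.splitlines()
    draft = False
    while lines and lines[0].startswith("#"):
        if lines[0].strip() == DRAFT_MARKER:
            draft = True
        lines.pop(0)
    if not lines:
        raise DataDictionaryFormatError("empty data dictionary (no header row)")
    header = lines[0].rstrip("\r").split("\t")
    missing = [c for c in HEADER if c not in header]
    if missing:
        raise DataDictionaryFormatError(
            "data dictionary header is missing column(s): " + ", ".join(missing))
    unknown = [c for c in header if c not in HEADER]
    if unknown:
        raise DataDictionaryFormatError(
            "data dictionary header has unknown column(s): " + ", ".join(unknown))
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        values = line.split("\t")
        if len(values) != len(header):
            raise DataDictionaryFormatError(
                f"line {lineno}: {len(values)} fields, expected {len(header)}")
        try:
            rows.append(DataDictionaryRow.from_tsv_dict(dict(zip(header, values))))
        except (DataDictionaryFormatError, DataDictionaryValidationError) as e:
            raise type(e)(f"line {lineno}: {e}") from None
    dd = DataDictionary(rows=rows, draft_flag=draft)
    dd.validate()
    return dd


def write_data_dictionary(dd: DataDictionary) -> str:
    out = []
    if dd.draft_flag:
        out.append(DRAFT_MARKER)
    out.append("\t".join(HEADER))
    for r in dd.rows:
        d = r.to_tsv_dict()
        out.append("\t".join(d[c] for c in HEADER))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Auto-drafting from a source schema

# A source schema is {table_name: [(column_name, declared_datatype), ...]}.
SourceSchema = dict[str, list[tuple[str, str]]]


@dataclass(frozen=True)
class HeuristicRule:
    """Column-name pattern mapped to draft scrub settings."""
    pattern: str                 # case-insensitive regex searched in the name
    scrub_src_kind: str = "none"
    scrub_method: str = ""
    is_pid: bool = False
    is_mpid: bool = False
    alteration: str = ""         # draft alteration for the column ('' = copy)


DEFAULT_HEURISTICS: tuple[HeuristicRule, ...] = (
    HeuristicRule(r"(?:^|_)(?:patient_?id|pid)(?:$|_)", is_pid=True),
    HeuristicRule(r"nhs|mpid|master_?id", "patient", "number",
                  is_mpid=True, alteration="omit"),
    HeuristicRule(r"forename|first_?name|given", "patient", "words",
                  alteration="omit"),
    HeuristicRule(r"surname|last_?name|family", "patient", "words",
                  alteration="omit"),
    HeuristicRule(r"alias|aka|nick", "patient", "words", alteration="omit"),
    HeuristicRule(r"dob|birth", "patient", "date", alteration="truncate_date"),
    HeuristicRule(r"post_?code|zip", "patient", "code", alteration="omit"),
    HeuristicRule(r"addr|street", "patient", "words", alteration="omit"),
    HeuristicRule(r"phone|mobile|tel|fax", "patient", "number",
                  alteration="omit"),
    HeuristicRule(r"e_?mail", "patient", "code", alteration="omit"),
    HeuristicRule(r"national_?insurance|ni_?number|nino", "patient", "code",
                  alteration="omit"),
    HeuristicRule(r"relative|carer|next_?of_?kin|kin_|contact_?name|third",
                  "thirdparty", "words", alteration="omit"),
)

_LONG_TEXT_RE = re.compile(r"text|clob|n?varchar\s*\(\s*(?:max|[0-9]{3,})\s*\)",
                           re.IGNORECASE)
_PID_NAME_RE = re.compile(DEFAULT_HEURISTICS[0].pattern, re.IGNORECASE)


def _is_long_text(datatype: str) -> bool:
    return bool(_LONG_TEXT_RE.search(datatype or ""))


def _draft_row(table: str, col: str, datatype: str,
               heuristics: Sequence[HeuristicRule],
               table_has_pid: bool, src_db: str) -> DataDictionaryRow:
    rule = next((h for h in heuristics
                 if re.search(h.pattern, col, re.IGNORECASE)), None)
    kw: dict = dict(src_db=src_db, src_table=table, src_field=col,
                    src_datatype=datatype, dest_table=table, dest_field=col,
                    dest_datatype=datatype)
    if rule is not None and table_has_pid:
        kw.update(scrub_src_kind=rule.scrub_src_kind,
                  scrub_method=rule.scrub_method,
                  is_pid=rule.is_pid, is_mpid=rule.is_mpid)
        if rule.is_pid:
            kw.update(dest_field="rid")
        if rule.alteration == "omit":
            kw.update(alterations=(Alteration("omit"),),
                      dest_table="", dest_field="")
        elif rule.alteration:
            kw.update(alterations=(Alteration(rule.alteration),))
    elif table_has_pid and _is_long_text(datatype):
        # Long text in a patient table defaults to scrubbing.
        kw.update(alterations=(Alteration("scrub"),), index_kind="fulltext")
    if col.lower() == "id" or col.lower() == f"{table.lower()}_id":
        kw.update(is_pk=True)
    return DataDictionaryRow(**kw)


def draft_data_dictionary(schema: SourceSchema,
                          heuristics: Sequence[HeuristicRule] = DEFAULT_HEURISTICS,
                          src_db: str = "source") -> DataDictionary:
    """Auto-draft a dictionary from a source schema.

    Tables with a patient-ID-like column get scrub-source/scrub defaults;
    tables without one are drafted as plain copies (lookup tables). The
    result always carries ``draft_flag=True`` and must be reviewed by a
    human before the engine will accept it.
    """
    if not schema:
        raise DataDictionaryValidationError("empty source schema")
    rows: list[DataDictionaryRow] = []
    patient_tables = {t for t, cols in schema.items()
                      if any(_PID_NAME_RE.search(c) for c, _ in cols)}
    for table in schema:
        for col, datatype in schema[table]:
            rows.append(_draft_row(table, col, datatype, heuristics,
                                   table in patient_tables, src_db))
    dd = DataDictionary(rows=rows, draft_flag=True)
    # Flag the master patient-ID column: the patient table with the most
    # scrub-source columns enumerates the patients (tie: alphabetical).
    if patient_tables:
        def richness(t: str) -> tuple[int, str]:
            return (-sum(r.is_scrub_source for r in dd.rows_for_table(t)), t)
        master = min(patient_tables, key=richness)
        dd.rows = [replace(r, is_master_pid_column=True)
                   if r.src_table == master and r.is_pid else r
                   for r in dd.rows]
    dd.validate()
    return dd


def schema_of(dd: DataDictionary, src_db: str | None = None) -> SourceSchema:
    """Recover the source schema described by a dictionary (for merging)."""
    schema: SourceSchema = {}
    for r in dd.rows:
        if r.removed or (src_db is not None and r.src_db != src_db):
            continue
        schema.setdefault(r.src_table, []).append((r.src_field, r.src_datatype))
    return schema


def merge_incremental(old: DataDictionary, new_schema: SourceSchema,
                      heuristics: Sequence[HeuristicRule] = DEFAULT_HEURISTICS,
                      src_db: str = "source") -> DataDictionary:
    """Merge a changed source schema into an existing dictionary.

    Rows for unchanged columns are preserved verbatim; new columns are
    appended as drafted rows; columns that disappeared from the source are
    flagged ``removed`` (not silently deleted) so human review sees them.
    The merged dictionary is always a draft.
    """
    old.validate()
    new_cols = {(t, c): dt for t, cols in new_schema.items() for c, dt in cols}
    patient_tables = {t for t, cols in new_schema.items()
                      if any(_PID_NAME_RE.search(c) for c, _ in cols)}
    out_rows: list[DataDictionaryRow] = []
    seen: set[tuple[str, str]] = set()
    for r in old.rows:
        key = (r.src_table, r.src_field)
        if key in new_cols:
            seen.add(key)
            out_rows.append(replace(r, removed=False))
        else:
            out_rows.append(replace(r, removed=True))
    for table, cols in new_schema.items():
        for col, datatype in cols:
            if (table, col) not in seen:
                out_rows.append(_draft_row(table, col, datatype, heuristics,
                                           table in patient_tables, src_db))
    return DataDictionary(rows=out_rows, draft_flag=True)
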