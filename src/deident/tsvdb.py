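"""File-based relational dialect: a database is a directory of TSV tables.

One ``<table>.tsv`` per table, UTF-8, tab-delimited, mandatory header row.
Values are stored as text; SQL NULL is encoded as the literal token ``\\N``
(MySQL LOAD DATA convention) so that NULL and the empty string remain
distinct. Embedded tabs/newlines are quote-escaped by the csv module.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path
from typing import Iterable, Sequence

NULL_TOKEN = r"\N"

Row = dict[str, "str | None"]


class TableNotFoundError(KeyError):
    pass


def _encode(value: str | None) -> str:
    return NULL_TOKEN if value is None else value


def _decode(value: str) -> str | None:
    return None if value == NULL_TOKEN else value


class TsvDatabase:
    """A directory of TSV tables addressed by table name."""

    def __init__(self, path: str | os.PathLike, create: bool = False):
        self.path = Path(path)
        if create:
            self.path.mkdir(parents=True, exist_ok=True)
        if not self.path.is_dir():
            raise FileNotFoundError(f"not a database directory: {self.path}")

    def _file(self, table: str) -> Path:
        if "/" in table or table.startswith("."):
            raise ValueError(f"bad table name: {table!r}")
        return self.path / f"{table}.tsv"

    def table_names(self) -> list[str]:
        return sorted(p.stem for p in self.path.glob("*.tsv"))

    def has_table(self, table: str) -> bool:
        return self._file(table).exists()

    def columns(self, table: str) -> list[str]:
        f = self._file(table)
        if not f.exists():
            raise TableNotFoundError(table)
        with f.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, dialect="excel-tab")
            try:
                return next(reader)
            except StopIteration:
                return []

    def read_rows(self, table: str) -> list[Row]:
        f = self._file(table)
        if not f.exists():
            raise TableNotFoundError(table)
        with f.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, dialect="excel-tab")
            return [{k: _decode(v) for k, v in row.items()} for row in reader]

    def write_rows(self, table: str, fieldnames: Sequence[str],
                   rows: Iterable[Row]) -> None:
        f = self._file(table)
        with f.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(fieldnames),
                                    dialect="excel-tab", lineterminator="\n")
            writer.writeheader()
            for row in rows:
                writer.writerow({k: _encode(row.get(k)) for k in fieldnames})

    def drop_table(self, table: str) -> None:
        f = self._file(table)
        if f.exists():
            f.unlink()

    def schema(self) -> dict[str, list[str]]:
        return {name: self.columns(name) for name in self.table_names()}
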