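"""Anonymisation runs: copy a source database to a de-identified destination.

The engine walks the source database(s) under the instructions of a
reviewed data dictionary:

1. non-patient tables are copied without scrubbing;
2. one shared nonspecific scrubber is built from the configuration;
3. the master patient-ID column enumerates the patients;
4. for each patient, the scrub-source fields are agglomerated into a
   personalized scrubber (patient and third-party pattern sets);
5. every row of every patient table passes through its patient's scrubber
   and the column alteration chains, keyed in the destination by the
   patient's transient research ID (TRID), with the research ID (RID)
   stored unless pseudonym storage is suppressed.

Incremental runs reuse destination rows whose source content hash and
patient scrubber hash are unchanged, delete rows that disappeared from the
source, and rework a patient in full when their scrubber changed; the
result is identical to a fresh full run. Opted-out patients are skipped
and can be retrospectively wiped.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .alterations import RowSkipped, apply_alterations
from .datadict import (DataDictionary, DataDictionaryRow,
                       DataDictionaryValidationError, parse_data_dictionary)
from .pseudonym import KeyConfig, SecretStore, content_hash
from .scrub import (PersonalizedScrubber, ScrubberConfig, ScrubSourceValue,
                    assemble_scrubber, build_nonspecific_patterns)
from .tsvdb import TsvDatabase

ROW_HASH_TABLE = "_row_hashes"
TRID_COLUMN = "trid"


class EngineError(RuntimeError):
    pass


class MissingHashStateError(EngineError):
    """Incremental run requested without previous row-hash state."""


def _sort_key(value: "str | None"):
    if value is None:
        return (2, "")
    v = value.strip()
    if v.lstrip("-").isdigit():
        return (0, int(v), "")
    return (1, 0, v)


# ---------------------------------------------------------------------------
# Job configuration

@dataclass(frozen=True)
class JobConfig:
    """Everything one anonymisation run needs."""
    sources: dict[str, str]          # source db name -> TSV directory
    dest: str                        # destination TSV directory
    secret_store: str                # path of the secret mapping file
    dd: "DataDictionary | str"       # dictionary object or path to its TSV
    keys: KeyConfig = None           # type: ignore[assignment]
    scrubber: ScrubberConfig = field(default_factory=ScrubberConfig)
    mode: str = "full"               # full | incremental
    workers: int = 1
    optout_files: tuple[str, ...] = ()
    optout_table: "tuple[str, str, str] | None" = None        # db, table, field
    optout_field: "tuple[str, str, str, tuple[str, ...]] | None" = None
    store_rid_in_dest: bool = True
    debug_limit: "int | None" = None
    immutable_tables: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.workers < 1:
            raise EngineError("workers must be >= 1")
        if self.mode not in ("full", "incremental"):
            raise EngineError(f"unknown mode {self.mode!r}")
        if self.keys is None:
            raise EngineError("keys (KeyConfig) is required")


@dataclass
class TableReport:
    rows_src: int = 0
    rows_dest: int = 0
    rows_transformed: int = 0
    rows_reused: int = 0
    rows_skipped: int = 0
    rows_deleted: int = 0


@dataclass
class RunReport:
    mode: str
    tables: dict[str, TableReport] = field(default_factory=dict)
    patients_total: int = 0
    patients_processed: int = 0
    patients_reworked: int = 0
    optouts_skipped: int = 0

    def table(self, name: str) -> TableReport:
        return self.tables.setdefault(name, TableReport())

    def to_tsv(self) -> str:
        cols = ("table", "rows_src", "rows_dest", "rows_transformed",
                "rows_reused", "rows_skipped", "rows_deleted")
        lines = ["\t".join(cols)]
        for name in sorted(self.tables):
            t = self.tables[name]
            lines.append("\t".join(map(str, (
                name, t.rows_src, t.rows_dest, t.rows_transformed,
                t.rows_reused, t.rows_skipped, t.rows_deleted))))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# The engine

class Engine:
    def __init__(self, job: JobConfig):
        self.job = job
        if isinstance(job.dd, DataDictionary):
            self.dd = job.dd
        else:
            self.dd = parse_data_dictionary(
                Path(job.dd).read_text(encoding="utf-8"))
        self.dd.assert_engine_ready()
        self.sources = {name: TsvDatabase(path)
                        for name, path in job.sources.items()}
        self.dest = TsvDatabase(job.dest, create=True)
        self.store = SecretStore(job.secret_store)
        self.cfg = job.scrubber
        self.keys = job.keys
        self._nonspecific = build_nonspecific_patterns(self.cfg)
        self._scrubber_cache: dict[str, PersonalizedScrubber] = {}
        self._table_rows_cache: dict[tuple[str, str], list[dict]] = {}

    # -- source access --------------------------------------------------------

    def _source(self, db: str) -> TsvDatabase:
        try:
            return self.sources[db]
        except KeyError:
            raise EngineError(f"data dictionary references unknown source "
                              f"database {db!r}") from None

    def _src_rows(self, db: str, table: str) -> list[dict]:
        key = (db, table)
        if key not in self._table_rows_cache:
            self._table_rows_cache[key] = self._source(db).read_rows(table)
        return self._table_rows_cache[key]

    def _tables(self) -> list[tuple[str, str, list[DataDictionaryRow]]]:
        """(src_db, src_table, dd rows) for every active source table."""
        out = []
        seen = set()
        for r in self.dd.rows:
            if r.removed:
                continue
            key = (r.src_db, r.src_table)
            if key not in seen:
                seen.add(key)
                out.append((r.src_db, r.src_table,
                            self.dd.rows_for_table(r.src_table)))
        return out

    # -- patients and opt-outs ------------------------------------------------

    def resolve_optouts(self) -> set[str]:
        pids: set[str] = set()
        for path in self.job.optout_files:
            for line in Path(path).read_text(encoding="utf-8").splitlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    pids.add(line)
        if self.job.optout_table is not None:
            db, table, fld = self.job.optout_table
            for row in self._src_rows(db, table):
                v = row.get(fld)
                if v:
                    pids.add(v)
        if self.job.optout_field is not None:
            db, table, fld, true_values = self.job.optout_field
            pid_row = self.dd.pid_row(table)
            if pid_row is None:
                raise EngineError(f"opt-out marker table {table!r} has no "
                                  "patient-ID column in the dictionary")
            for row in self._src_rows(db, table):
                if (row.get(fld) or "") in true_values and row.get(pid_row.src_field):
                    pids.add(row[pid_row.src_field])
        # Patients flagged opted-out in a previous run stay suppressed even
        # if their source rows reappear.
        for rec in self.store.records():
            if rec.opted_out:
                pids.add(rec.pid)
        return pids

    def master_patients(self) -> list[tuple[str, "str | None"]]:
        """(pid, mpid) pairs from the master patient table, PID-sorted."""
        master = self.dd.master_pid_row()
        if master is None:
            return []
        mpid_row = next((r for r in self.dd.rows_for_table(master.src_table)
                         if r.is_mpid), None)
        pairs: dict[str, "str | None"] = {}
        for row in self._src_rows(master.src_db, master.src_table):
            pid = row.get(master.src_field)
            if pid:
                pairs.setdefault(
                    pid, row.get(mpid_row.src_field) if mpid_row else None)
        return sorted(pairs.items(), key=lambda kv: _sort_key(kv[0]))

    # -- scrubbers ------------------------------------------------------------

    def collect_scrub_values(self, pid: str) -> list[ScrubSourceValue]:
        """Scrub-source values for one patient, in data-dictionary order
        (which fixes the within-category scrubber application order)."""
        values: list[ScrubSourceValue] = []
        for ddr in self.dd.scrub_source_rows():
            pid_row = self.dd.pid_row(ddr.src_table)
            if pid_row is None:
                raise DataDictionaryValidationError(
                    f"scrub-source table {ddr.src_table!r} has no "
                    "patient-ID column")
            for row in self._src_rows(ddr.src_db, ddr.src_table):
                if row.get(pid_row.src_field) != pid:
                    continue
                raw = row.get(ddr.src_field)
                if raw is None or raw == "":
                    continue
                values.append(ScrubSourceValue(raw=raw, method=ddr.scrub_method,
                                               kind=ddr.scrub_src_kind))
        return values

    def scrubber_for(self, pid: str) -> PersonalizedScrubber:
        scr = self._scrubber_cache.get(pid)
        if scr is None:
            scr = assemble_scrubber(self.collect_scrub_values(pid), self.cfg,
                                    nonspecific=self._nonspecific)
            self._scrubber_cache[pid] = scr
        return scr

    # -- row transformation ---------------------------------------------------

    def _dest_columns(self, trows: Sequence[DataDictionaryRow],
                      patient_table: bool) -> list[str]:
        cols = []
        if patient_table:
            cols.append(TRID_COLUMN)
        for r in trows:
            if r.omitted or not r.dest_field:
                continue
            if (r.is_pid or r.is_mpid) and not self.job.store_rid_in_dest:
                continue
            cols.append(r.dest_field)
        return cols

    def transform_row(self, trows: Sequence[DataDictionaryRow],
                      row: dict, scrubber: "PersonalizedScrubber | None",
                      rec=None) -> "dict | None":
        """Apply alteration chains to one source row; None if skipped."""
        out: dict[str, "str | None"] = {}
        if rec is not None:
            out[TRID_COLUMN] = str(rec.trid)
        try:
            for r in trows:
                value = row.get(r.src_field)
                if r.is_pid and rec is not None:
                    transformed: "str | None" = rec.rid
                    # skip_row alterations still apply to the raw value
                    apply_alterations(value, tuple(
                        a for a in r.alterations if a.kind == "skip_row"))
                elif r.is_mpid and rec is not None and not r.omitted:
                    transformed = rec.mrid
                else:
                    transformed = apply_alterations(value, r.alterations,
                                                    scrubber)
                if r.omitted or not r.dest_field:
                    continue
                if (r.is_pid or r.is_mpid) and not self.job.store_rid_in_dest:
                    continue
                out[r.dest_field] = transformed
        except RowSkipped:
            return None
        return out

    def _row_hash(self, trows: Sequence[DataDictionaryRow], row: dict) -> str:
        return content_hash([row.get(r.src_field) for r in trows],
                            self.keys.effective_hash_key)

    # -- hash state -----------------------------------------------------------

    def _load_row_hashes(self) -> dict[tuple[str, str], str]:
        if not self.dest.has_table(ROW_HASH_TABLE):
            return {}
        return {(r["dest_table"], r["src_pk"]): r["content_digest"]
                for r in self.dest.read_rows(ROW_HASH_TABLE)}

    def _save_row_hashes(self, hashes: dict[tuple[str, str], str]) -> None:
        rows = [{"dest_table": t, "src_pk": pk, "content_digest": d}
                for (t, pk), d in sorted(
                    hashes.items(),
                    key=lambda kv: (kv[0][0], _sort_key(kv[0][1])))]
        self.dest.write_rows(ROW_HASH_TABLE,
                             ("dest_table", "src_pk", "content_digest"), rows)

    # -- runs -----------------------------------------------------------------

    def run_full(self) -> RunReport:
        return self._run("full")

    def run_incremental(self) -> RunReport:
        return self._run("incremental")

    def run(self) -> RunReport:
        return self._run(self.job.mode)

    def _run(self, mode: str) -> RunReport:
        job = self.job
        incremental = mode == "incremental"
        prev_hashes = self._load_row_hashes()
        if incremental and not prev_hashes:
            raise MissingHashStateError(
                "no previous row-hash state in the destination; "
                "run a full anonymisation first")
        if not incremental:
            # Full rebuild: wipe the destination and the TRID mapping.
            for name in self.dest.table_names():
                self.dest.drop_table(name)
            self.store.rebuild_trids(job.keys.trid_seed)
            prev_hashes = {}

        report = RunReport(mode=mode)
        optouts = self.resolve_optouts()
        patients = self.master_patients()
        report.patients_total = len(patients)

        allowed: list[tuple[str, "str | None"]] = []
        for pid, mpid in patients:
            if pid in optouts:
                report.optouts_skipped += 1
                continue
            allowed.append((pid, mpid))
        if job.debug_limit is not None:
            allowed = allowed[:job.debug_limit]
        allowed_pids = {pid for pid, _ in allowed}

        # Register pseudonyms in sorted PID order; TRIDs are derived from
        # per-patient seeded generators, so allocation is reproducible and
        # independent of sharding or of which patients already exist.
        recs = {pid: self.store.register(pid, job.keys, mpid=mpid)
                for pid, mpid in allowed}

        # Scrubber change detection.
        changed_scrubber: set[str] = set()
        for pid, _ in allowed:
            digest = self.scrubber_for(pid).digest
            if incremental and self.store.scrubber_hash(pid) != digest:
                changed_scrubber.add(pid)
            self.store.set_scrubber_hash(pid, digest)
        if incremental:
            report.patients_reworked = len(changed_scrubber)
        report.patients_processed = len(allowed)

        new_hashes: dict[tuple[str, str], str] = {}
        for db, table, trows in self._tables():
            pid_row = self.dd.pid_row(table)
            self._process_table(db, table, trows, pid_row, incremental,
                                prev_hashes, new_hashes, allowed_pids, recs,
                                changed_scrubber, report)

        deleted = set(prev_hashes) - set(new_hashes)
        for t, _pk in deleted:
            report.table(t).rows_deleted += 1
        self._save_row_hashes(new_hashes)
        self._write_index_ddl()
        self.store.save()
        return report

    # -- per-table processing -------------------------------------------------

    def _process_table(self, db: str, table: str,
                       trows: Sequence[DataDictionaryRow],
                       pid_row: "DataDictionaryRow | None",
                       incremental: bool,
                       prev_hashes: dict, new_hashes: dict,
                       allowed_pids: set[str], recs: dict,
                       changed_scrubber: set[str],
                       report: RunReport) -> None:
        patient_table = pid_row is not None
        dest_table = next((r.dest_table for r in trows if r.dest_table), None)
        if dest_table is None:
            return                        # every column omitted
        src_rows = self._src_rows(db, table)
        trep = report.table(dest_table)
        trep.rows_src = len(src_rows)

        pk_row = self.dd.pk_row(table)
        use_hashes = (pk_row is not None
                      and table not in self.job.immutable_tables)

        if patient_table and self.job.workers > 1:
            # Work distribution: shard rows by integer PID across workers,
            # processed shard by shard; the canonical PK sort below is the
            # deterministic merge, so output is worker-count independent.
            def shard(row: dict) -> int:
                pid = row.get(pid_row.src_field) or ""
                import zlib
                return (int(pid) if pid.lstrip("-").isdigit()
                        else zlib.crc32(pid.encode())) % self.job.workers
            indexed = list(enumerate(src_rows))
            indexed.sort(key=lambda ir: (shard(ir[1]), ir[0]))
            src_rows = [r for _, r in indexed]

        # Existing destination rows keyed by destination PK value, for reuse.
        existing: dict[str, dict] = {}
        if incremental and use_hashes and self.dest.has_table(dest_table):
            dest_pk_field = (pk_row.dest_field
                             if not pk_row.omitted else None)
            if dest_pk_field:
                for drow in self.dest.read_rows(dest_table):
                    existing[drow.get(dest_pk_field) or ""] = drow

        out_rows: list[dict] = []
        for row in src_rows:
            rec = None
            scrubber = None
            if patient_table:
                pid = row.get(pid_row.src_field)
                if pid not in allowed_pids:
                    trep.rows_skipped += 1
                    continue
                rec = recs[pid]
                scrubber = self.scrubber_for(pid)

            pk_value = row.get(pk_row.src_field) if pk_row else None
            if use_hashes:
                digest = self._row_hash(trows, row)
                key = (dest_table, pk_value or "")
                reuse = (incremental
                         and prev_hashes.get(key) == digest
                         and not (patient_table and
                                  row.get(pid_row.src_field) in changed_scrubber))
                if reuse:
                    dest_pk = (str(rec.rid) if (pk_row.is_pid and rec)
                               else pk_value)
                    cached = existing.get(dest_pk or "")
                    if cached is not None:
                        out_rows.append(cached)
                        new_hashes[key] = digest
                        trep.rows_reused += 1
                        continue

            out = self.transform_row(trows, row, scrubber, rec)
            if out is None:
                trep.rows_skipped += 1
                continue
            out_rows.append(out)
            trep.rows_transformed += 1
            if use_hashes:
                new_hashes[(dest_table, pk_value or "")] = \
                    self._row_hash(trows, row)

        # Canonical destination order: by PK when there is one (numeric
        # aware), else source order. Makes full and incremental runs, and
        # any worker count, byte-identical.
        if pk_row is not None and not pk_row.omitted and pk_row.dest_field:
            out_rows.sort(key=lambda r: _sort_key(r.get(pk_row.dest_field)))
        columns = self._dest_columns(trows, patient_table)
        self.dest.write_rows(dest_table, columns, out_rows)
        trep.rows_dest = len(out_rows)

    def _write_index_ddl(self) -> None:
        stmts = []
        for r in self.dd.rows:
            if r.removed or r.omitted or r.index_kind == "none":
                continue
            if not (r.dest_table and r.dest_field):
                continue
            if r.index_kind == "fulltext":
                stmts.append(f"CREATE FULLTEXT INDEX ft_{r.dest_table}_"
                             f"{r.dest_field} ON {r.dest_table} "
                             f"({r.dest_field});")
            else:
                stmts.append(f"CREATE INDEX idx_{r.dest_table}_{r.dest_field} "
                             f"ON {r.dest_table} ({r.dest_field});")
        (Path(self.job.dest) / "_indexes.sql").write_text(
            "\n".join(stmts) + ("\n" if stmts else ""), encoding="utf-8")

    # -- opt-out wiping -------------------------------------------------------

    def wipe_optouts(self) -> dict[str, int]:
        """Remove every destination row of opted-out patients; flag them in
        the secret store so later runs keep them suppressed."""
        optouts = self.resolve_optouts()
        removed: dict[str, int] = {}
        trids = set()
        for pid in optouts:
            rec = self.store.get(pid)
            if rec is not None:
                trids.add(str(rec.trid))
            self.store.mark_opted_out(pid)
        hashes = self._load_row_hashes()
        for db, table, trows in self._tables():
            pid_row = self.dd.pid_row(table)
            if pid_row is None:
                continue
            dest_table = next((r.dest_table for r in trows if r.dest_table),
                              None)
            if dest_table is None or not self.dest.has_table(dest_table):
                continue
            pk_row = self.dd.pk_row(table)
            dest_pk = (pk_row.dest_field
                       if pk_row and not pk_row.omitted else None)
            kept, n_removed = [], 0
            for drow in self.dest.read_rows(dest_table):
                if drow.get(TRID_COLUMN) in trids:
                    n_removed += 1
                    if dest_pk:
                        hashes.pop((dest_table, drow.get(dest_pk) or ""), None)
                else:
                    kept.append(drow)
            if n_removed:
                self.dest.write_rows(dest_table,
                                     self.dest.columns(dest_table), kept)
                removed[dest_table] = n_removed
        self._save_row_hashes(hashes)
        self.store.save()
        return removed

    # -- audit sampling -------------------------------------------------------

    def sample_comparison(self, n: int, seed: int,
                          out_dir: "str | Path") -> list[tuple[Path, Path]]:
        """Export n seeded-random raw/scrubbed document pairs for human
        before-and-after comparison with a diff tool."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        candidates: list[tuple[str, str, str, str, str]] = []
        for db, table, trows in self._tables():
            pid_row = self.dd.pid_row(table)
            pk_row = self.dd.pk_row(table)
            if pid_row is None or pk_row is None or pk_row.omitted:
                continue
            scrub_fields = [r for r in trows if r.scrubbed and r.dest_field]
            if not scrub_fields:
                continue
            dest_table = scrub_fields[0].dest_table
            if not self.dest.has_table(dest_table):
                continue
            dest_rows = {r.get(pk_row.dest_field) or "": r
                         for r in self.dest.read_rows(dest_table)}
            for row in self._src_rows(db, table):
                pk = row.get(pk_row.src_field) or ""
                drow = dest_rows.get(pk)
                if drow is None:
                    continue
                for f in scrub_fields:
                    raw = row.get(f.src_field)
                    scrubbed = drow.get(f.dest_field)
                    if raw:
                        candidates.append((dest_table, pk, f.dest_field,
                                           raw, scrubbed or ""))
        candidates.sort(key=lambda c: (c[0], _sort_key(c[1]), c[2]))
        if n >= len(candidates):
            if n > len(candidates):
                import warnings
                warnings.warn(f"requested {n} samples but only "
                              f"{len(candidates)} documents exist")
            chosen = candidates
        else:
            chosen = random.Random(seed).sample(candidates, n)
            chosen.sort(key=lambda c: (c[0], _sort_key(c[1]), c[2]))
        pairs = []
        for table, pk, fld, raw, scrubbed in chosen:
            raw_path = out / f"{table}__{pk}__{fld}.raw.txt"
            scr_path = out / f"{table}__{pk}__{fld}.scrubbed.txt"
            raw_path.write_text(raw, encoding="utf-8")
            scr_path.write_text(scrubbed, encoding="utf-8")
            pairs.append((raw_path, scr_path))
        return pairs


# ---------------------------------------------------------------------------
# Convenience wrappers

def run_full(job: JobConfig) -> RunReport:
    return Engine(job).run_full()


def run_incremental(job: JobConfig) -> RunReport:
    return Engine(job).run_incremental()


def wipe_optouts(job: JobConfig) -> dict[str, int]:
    return Engine(job).wipe_optouts()


def sample_comparison(job: JobConfig, n: int, seed: int,
                      out_dir: "str | Path") -> list[tuple[Path, Path]]:
    return Engine(job).sample_comparison(n, seed, out_dir)
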