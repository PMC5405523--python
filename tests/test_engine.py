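"""Engine orchestration: full runs, incremental equivalence, opt-outs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pytest

from deident.datadict import DataDictionaryValidationError
from deident.engine import Engine, MissingHashStateError
from deident.evaluate import DEFAULT_PLACEHOLDERS, score_document
from deident.scrub import ScrubberConfig
from deident.synthetic import expected_destination, load_destination
from deident.tsvdb import TsvDatabase

from conftest import destination_bytes, fresh_job


class TestFullRun:
    def test_end_to_end_against_oracle(self, corpus_factory, keys):
        bundle, job = corpus_factory(n_patients=4, notes=2)
        Engine(job).run_full()
        expected = expected_destination(bundle.source_dir, job.dd,
                                        ScrubberConfig(), keys)
        assert load_destination(job.dest) == expected

    def test_lookup_table_copied_verbatim(self, corpus_factory):
        bundle, job = corpus_factory(n_patients=2, notes=1)
        Engine(job).run_full()
        src = TsvDatabase(bundle.source_dir).read_rows("lookup")
        dst = TsvDatabase(job.dest).read_rows("lookup")
        assert dst == src

    def test_draft_dictionary_refused(self, corpus_factory):
        _, job = corpus_factory(n_patients=2, notes=1)
        draft = dataclasses.replace(job)
        draft.dd.draft_flag = True
        with pytest.raises(DataDictionaryValidationError, match="draft"):
            Engine(draft)

    def test_debug_limit_processes_first_n_patients(self, corpus_factory):
        _, job = corpus_factory(n_patients=5, notes=2,
                                debug_limit=1)
        report = Engine(job).run_full()
        assert report.patients_processed == 1
        assert report.tables["notes"].rows_dest == 2

    def test_pseudonym_columns_populated(self, corpus_factory, keys):
        from deident.pseudonym import make_rid
        _, job = corpus_factory(n_patients=3, notes=1)
        Engine(job).run_full()
        rows = TsvDatabase(job.dest).read_rows("patients")
        assert {r["rid"] for r in rows} == \
            {make_rid(pid, keys.pid_key) for pid in (1001, 1002, 1003)}
        assert all(r["trid"] and r["mrid"] for r in rows)

    def test_rid_storage_can_be_suppressed(self, corpus_factory):
        # Anonymisation (irreversible) instead of pseudonymisation.
        _, job = corpus_factory(n_patients=2, notes=1,
                                store_rid_in_dest=False)
        Engine(job).run_full()
        db = TsvDatabase(job.dest)
        assert "rid" not in db.columns("patients")
        assert "mrid" not in db.columns("patients")
        assert "rid" not in db.columns("notes")
        assert "trid" in db.columns("notes")

    def test_null_preservation(self, corpus_factory):
        bundle, job = corpus_factory(n_patients=6, notes=1)
        # Patients without an alias carry NULL in the source.
        src_null = {r["pid"] for r in
                    TsvDatabase(bundle.source_dir).read_rows("patients")
                    if r["alias"] is None}
        assert src_null, "fixture should include NULL aliases"
        Engine(job).run_full()
        # The relatives table of a patient with no third parties is simply
        # absent; NULLs appear in copied columns when the source has them.
        dst = TsvDatabase(job.dest)
        for row in dst.read_rows("notes"):
            assert row["note_text"] is not None

    def test_trid_rid_one_to_one_after_run(self, corpus_factory):
        _, job = corpus_factory(n_patients=6, notes=1)
        engine = Engine(job)
        engine.run_full()
        recs = list(engine.store.records())
        assert len({r.trid for r in recs}) == len(recs)
        assert len({r.rid for r in recs}) == len(recs)

    def test_index_declarations_emitted(self, corpus_factory):
        _, job = corpus_factory(n_patients=2, notes=1)
        Engine(job).run_full()
        ddl = (Path(job.dest) / "_indexes.sql").read_text()
        assert "CREATE FULLTEXT INDEX ft_notes_note_text" in ddl
        assert "CREATE INDEX idx_patients_rid" in ddl


def _mutate_new_note(src: TsvDatabase) -> None:
    rows = src.read_rows("notes")
    rows.append({"note_id": str(max(int(r["note_id"]) for r in rows) + 1),
                 "pid": rows[0]["pid"], "note_date": "2020-01-01",
                 "note_text": "routine follow up no concerns"})
    src.write_rows("notes", src.columns("notes"), rows)


def _mutate_changed_note(src: TsvDatabase) -> None:
    rows = src.read_rows("notes")
    rows[0]["note_text"] = (rows[0]["note_text"] or "") + " amended entry"
    src.write_rows("notes", src.columns("notes"), rows)


def _mutate_deleted_note(src: TsvDatabase) -> None:
    rows = src.read_rows("notes")
    src.write_rows("notes", src.columns("notes"), rows[1:])


def _mutate_new_alias(src: TsvDatabase) -> None:
    # "William, known as Bill": confidential data changed, so every row of
    # that patient must be reworked.
    rows = src.read_rows("patients")
    rows[1]["alias"] = "Willibald"
    src.write_rows("patients", src.columns("patients"), rows)


def _mutate_new_patient(src: TsvDatabase) -> None:
    rows = src.read_rows("patients")
    new = dict(rows[0])
    new.update(pid="1000", forename="Ottoline", surname="Quenby",
               alias=None, nhs_number="9434765919",
               email="ottoline.quenby@example.org")
    src.write_rows("patients", src.columns("patients"), rows + [new])


MUTATIONS = {
    "new_row": _mutate_new_note,
    "changed_row": _mutate_changed_note,
    "deleted_row": _mutate_deleted_note,
    "new_alias": _mutate_new_alias,
    "new_patient": _mutate_new_patient,
}


class TestIncremental:
    def test_requires_previous_hash_state(self, corpus_factory):
        _, job = corpus_factory(n_patients=2, notes=1)
        with pytest.raises(MissingHashStateError):
            Engine(job).run_incremental()

    def test_unchanged_source_rewrites_nothing(self, corpus_factory):
        _, job = corpus_factory(n_patients=4, notes=2)
        Engine(job).run_full()
        before = destination_bytes(job.dest)
        report = Engine(job).run_incremental()
        assert destination_bytes(job.dest) == before
        for table in ("notes", "patients", "relatives", "lookup"):
            assert report.tables[table].rows_transformed == 0
        assert report.patients_reworked == 0

    @pytest.mark.parametrize("mutation", sorted(MUTATIONS))
    def test_single_mutation_equals_fresh_full_run(self, corpus_factory,
                                                   mutation):
        bundle, job = corpus_factory(n_patients=4, notes=2)
        Engine(job).run_full()
        MUTATIONS[mutation](TsvDatabase(bundle.source_dir))
        Engine(job).run_incremental()
        reference = fresh_job(job, mutation)
        Engine(reference).run_full()
        assert destination_bytes(job.dest) == \
            destination_bytes(reference.dest)

    def test_optout_added_after_full_run(self, corpus_factory, tmp_path):
        bundle, job = corpus_factory(n_patients=4, notes=2)
        Engine(job).run_full()
        optout = tmp_path / "optouts.txt"
        optout.write_text("1002\n")
        job_oo = dataclasses.replace(job, optout_files=(str(optout),))
        Engine(job_oo).run_incremental()
        reference = fresh_job(job_oo, "optout")
        Engine(reference).run_full()
        assert destination_bytes(job_oo.dest) == \
            destination_bytes(reference.dest)

    def test_alias_change_reworks_only_that_patient(self, corpus_factory):
        bundle, job = corpus_factory(n_patients=4, notes=3)
        Engine(job).run_full()
        _mutate_new_alias(TsvDatabase(bundle.source_dir))
        report = Engine(job).run_incremental()
        assert report.patients_reworked == 1
        assert report.tables["notes"].rows_transformed == 3
        assert report.tables["notes"].rows_reused == 9

    def test_deleted_source_row_deleted_downstream(self, corpus_factory):
        bundle, job = corpus_factory(n_patients=3, notes=2)
        Engine(job).run_full()
        n_before = len(TsvDatabase(job.dest).read_rows("notes"))
        _mutate_deleted_note(TsvDatabase(bundle.source_dir))
        report = Engine(job).run_incremental()
        assert len(TsvDatabase(job.dest).read_rows("notes")) == n_before - 1
        assert report.tables["notes"].rows_deleted == 1


class TestOptouts:
    def test_opted_out_patient_never_processed(self, corpus_factory,
                                               tmp_path):
        optout = tmp_path / "optouts.txt"
        optout.write_text("# comment line\n1001\n")
        _, job = corpus_factory(n_patients=3, notes=2,
                                optout_files=(str(optout),))
        report = Engine(job).run_full()
        assert report.optouts_skipped == 1
        assert report.patients_processed == 2

    def test_wipe_removes_rows_and_flags_store(self, corpus_factory,
                                               tmp_path):
        bundle, job = corpus_factory(n_patients=3, notes=2)
        Engine(job).run_full()
        before = {t: TsvDatabase(job.dest).read_rows(t)
                  for t in ("notes", "patients")}
        optout = tmp_path / "optouts.txt"
        optout.write_text("1003\n")
        job_oo = dataclasses.replace(job, optout_files=(str(optout),))
        engine = Engine(job_oo)
        removed = engine.wipe_optouts()
        assert removed["notes"] == 2 and removed["patients"] == 1
        assert engine.store.is_opted_out("1003")
        # remaining patients' rows byte-identical to before
        wiped_trid = str(engine.store.get("1003").trid)
        after = TsvDatabase(job.dest).read_rows("notes")
        assert after == [r for r in before["notes"]
                         if r["trid"] != wiped_trid]

    def test_wipe_unknown_pid_is_noop(self, corpus_factory, tmp_path):
        _, job = corpus_factory(n_patients=2, notes=1)
        Engine(job).run_full()
        before = destination_bytes(job.dest)
        optout = tmp_path / "optouts.txt"
        optout.write_text("999999\n")
        job_oo = dataclasses.replace(job, optout_files=(str(optout),))
        assert Engine(job_oo).wipe_optouts() == {}
        assert destination_bytes(job.dest) == before

    def test_optout_marker_field_in_source(self, corpus_factory):
        bundle, job = corpus_factory(n_patients=3, notes=1)
        src = TsvDatabase(bundle.source_dir)
        rows = src.read_rows("patients")
        cols = src.columns("patients") + ["optout"]
        for r in rows:
            r["optout"] = "Y" if r["pid"] == "1002" else ""
        src.write_rows("patients", cols, rows)
        job_oo = dataclasses.replace(
            job, optout_field=("source", "patients", "optout", ("Y",)))
        report = Engine(job_oo).run_full()
        assert report.optouts_skipped == 1


class TestParallelism:
    def test_destination_identical_across_worker_counts(self,
                                                        corpus_factory):
        _, job1 = corpus_factory(n_patients=5, notes=2, seed=21)
        Engine(job1).run_full()
        job4 = dataclasses.replace(fresh_job(job1, "w4"), workers=4)
        Engine(job4).run_full()
        assert destination_bytes(job1.dest) == destination_bytes(job4.dest)


class TestSampling:
    def test_seeded_sample_reproducible(self, corpus_factory, tmp_path):
        _, job = corpus_factory(n_patients=4, notes=3)
        engine = Engine(job)
        engine.run_full()
        a = engine.sample_comparison(5, seed=1, out_dir=tmp_path / "a")
        b = engine.sample_comparison(5, seed=1, out_dir=tmp_path / "b")
        assert [p.name for p, _ in a] == [p.name for p, _ in b]
        assert len(a) == 5

    def test_pairs_differ_only_at_placeholders(self, corpus_factory,
                                               tmp_path):
        _, job = corpus_factory(n_patients=3, notes=2, density=0.1)
        engine = Engine(job)
        engine.run_full()
        pairs = engine.sample_comparison(4, seed=2, out_dir=tmp_path / "s")
        for raw_path, scrubbed_path in pairs:
            raw = raw_path.read_text()
            scrubbed = scrubbed_path.read_text()
            # alignment succeeds iff the only insertions are placeholders
            score_document(raw, scrubbed, [], DEFAULT_PLACEHOLDERS)

    def test_oversized_request_returns_all_with_warning(self, corpus_factory,
                                                        tmp_path):
        _, job = corpus_factory(n_patients=2, notes=1)
        engine = Engine(job)
        engine.run_full()
        with pytest.warns(UserWarning, match="samples"):
            pairs = engine.sample_comparison(99, seed=0,
                                             out_dir=tmp_path / "s")
        assert len(pairs) == 2

    def test_zero_request_empty(self, corpus_factory, tmp_path):
        _, job = corpus_factory(n_patients=2, notes=1)
        engine = Engine(job)
        engine.run_full()
        assert engine.sample_comparison(0, seed=0,
                                        out_dir=tmp_path / "s") == []
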