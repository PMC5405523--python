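"""Shared fixtures: small synthetic corpora and anonymisation jobs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pytest

from deident.engine import Engine, JobConfig
from deident.pseudonym import KeyConfig
from deident.synthetic import (CorpusSpec, fixture_data_dictionary,
                               generate_corpus, generate_patients)
from deident.tsvdb import TsvDatabase


@pytest.fixture
def keys() -> KeyConfig:
    return KeyConfig(pid_key="unit-test-pid-key",
                     mpid_key="unit-test-mpid-key",
                     algorithm="HMAC-SHA-256", trid_seed=42)


@pytest.fixture
def corpus_factory(tmp_path, keys):
    """Build a corpus + job in a temp dir; returns (bundle, job)."""

    counter = {"n": 0}

    def build(n_patients=5, notes=3, words=80, density=0.08, typo=0.0,
              unknown=0.0, misfile=0.0, seed=7, **job_kw):
        counter["n"] += 1
        root = tmp_path / f"c{counter['n']}"
        spec = CorpusSpec(n_patients=n_patients, notes_per_patient=notes,
                          words_per_note=words, identifier_density=density,
                          typo_rate=typo, unknown_identifier_rate=unknown,
                          misfile_rate=misfile, seed=seed)
        patients = generate_patients(n_patients, seed)
        bundle = generate_corpus(patients, spec, root / "src")
        job = JobConfig(sources={"source": str(root / "src")},
                        dest=str(root / "dst"),
                        secret_store=str(root / "secret.tsv"),
                        dd=fixture_data_dictionary(), keys=keys, **job_kw)
        return bundle, job

    return build


def run_and_score(bundle, job):
    """Run a full anonymisation and score the notes against gold."""
    from deident.evaluate import score_corpus

    Engine(job).run_full()
    src = TsvDatabase(Path(job.sources["source"]))
    dst = TsvDatabase(Path(job.dest))
    raw = {r["note_id"]: r["note_text"] for r in src.read_rows("notes")}
    scrubbed = {r["note_id"]: r["note_text"] for r in dst.read_rows("notes")}
    by_doc: dict[str, list] = {}
    for s in bundle.gold:
        by_doc.setdefault(s.doc_id, []).append(s)
    docs = [(raw[i] or "", scrubbed[i] or "", by_doc.get(i, []))
            for i in sorted(raw, key=int)]
    return score_corpus(docs)


def destination_bytes(dest_dir: "str | Path") -> dict[str, bytes]:
    """Byte content of every destination table, for equality checks."""
    return {p.name: p.read_bytes()
            for p in sorted(Path(dest_dir).glob("*.tsv"))}


def fresh_job(job: JobConfig, tag: str) -> JobConfig:
    """The same job aimed at a fresh destination and secret store."""
    dest = Path(job.dest)
    return dataclasses.replace(
        job, dest=str(dest.parent / f"dst-{tag}"),
        secret_store=str(dest.parent / f"secret-{tag}.tsv"))
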