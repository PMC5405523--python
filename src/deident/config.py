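"""INI-style master configuration for anonymisation jobs.

Sections::

    [source]           name = path     (one entry per source database)
    [destination]      path, secret_store
    [dictionary]       path
    [keys]             pid_key, mpid_key, algorithm, trid_seed, hash_key
    [scrubber]         every ScrubberConfig field; whitelist_file /
                       blacklist_file point at one-word-per-line files
    [job]              mode, workers, debug_limit, store_rid_in_dest,
                       optout_files, optout_table, optout_field,
                       immutable_tables
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .engine import JobConfig
from .pseudonym import KeyConfig
from .scrub import ScrubberConfig


def _words_from_file(path: Path) -> frozenset[str]:
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def _split(value: str) -> tuple[str, ...]:
    return tuple(v.strip() for v in value.replace("\n", ",").split(",")
                 if v.strip())


def load_scrubber_config(cp: configparser.ConfigParser,
                         base: Path) -> ScrubberConfig:
    if not cp.has_section("scrubber"):
        return ScrubberConfig()
    s = cp["scrubber"]
    kwargs: dict = {}
    if "whitelist_file" in s:
        kwargs["whitelist"] = _words_from_file(base / s["whitelist_file"])
    elif "whitelist" in s:
        kwargs["whitelist"] = frozenset(_split(s["whitelist"]))
    if "blacklist_file" in s:
        kwargs["blacklist"] = tuple(sorted(
            _words_from_file(base / s["blacklist_file"])))
    elif "blacklist" in s:
        kwargs["blacklist"] = _split(s["blacklist"])
    for name in ("max_typos", "min_word_length_for_typos",
                 "min_string_length"):
        if name in s:
            kwargs[name] = s.getint(name)
    for name in ("scrub_uk_postcodes", "anchor_words_at_boundaries",
                 "anchor_numbers_at_boundaries", "suffixes_with_typos"):
        if name in s:
            kwargs[name] = s.getboolean(name)
    if "word_suffixes" in s:
        kwargs["word_suffixes"] = _split(s["word_suffixes"])
    if "nonspecific_number_lengths" in s:
        kwargs["nonspecific_number_lengths"] = tuple(
            int(v) for v in _split(s["nonspecific_number_lengths"]))
    for name in ("placeholder_patient", "placeholder_thirdparty",
                 "placeholder_nonspecific"):
        if name in s:
            kwargs[name] = s[name]
    return ScrubberConfig(**kwargs)


def load_key_config(cp: configparser.ConfigParser) -> KeyConfig:
    k = cp["keys"]
    seed = k.getint("trid_seed") if "trid_seed" in k else None
    return KeyConfig(pid_key=k["pid_key"], mpid_key=k["mpid_key"],
                     algorithm=k.get("algorithm", "HMAC-SHA-256"),
                     trid_seed=seed, hash_key=k.get("hash_key", ""))


def load_job_config(path: "str | Path") -> JobConfig:
    path = Path(path)
    base = path.parent
    cp = configparser.ConfigParser()
    with path.open(encoding="utf-8") as fh:
        cp.read_file(fh)

    sources = {name: str(base / p) for name, p in cp["source"].items()}
    dest = cp["destination"]
    job = cp["job"] if cp.has_section("job") else {}

    optout_table = None
    if "optout_table" in job:
        db, table, fld = job["optout_table"].split(".")
        optout_table = (db, table, fld)
    optout_field = None
    if "optout_field" in job:
        spec, values = job["optout_field"].split("=", 1)
        db, table, fld = spec.strip().split(".")
        optout_field = (db, table, fld, _split(values))

    def getint(key):
        v = job.get(key)
        return int(v) if v not in (None, "") else None

    return JobConfig(
        sources=sources,
        dest=str(base / dest["path"]),
        secret_store=str(base / dest["secret_store"]),
        dd=str(base / cp["dictionary"]["path"]),
        keys=load_key_config(cp),
        scrubber=load_scrubber_config(cp, base),
        mode=job.get("mode", "full"),
        workers=getint("workers") or 1,
        optout_files=tuple(str(base / p)
                           for p in _split(job.get("optout_files", ""))),
        optout_table=optout_table,
        optout_field=optout_field,
        store_rid_in_dest=str(job.get("store_rid_in_dest", "true")
                              ).lower() not in ("false", "0", "no"),
        debug_limit=getint("debug_limit"),
        immutable_tables=frozenset(_split(job.get("immutable_tables", ""))),
    )
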