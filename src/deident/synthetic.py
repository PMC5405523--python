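"""Synthetic EMR generation: fictional patients, notes with embedded
identifiers, and gold annotations.

The generator emulates the identifier inventory of a psychiatric EMR —
local patient numbers, 10-digit health numbers with a mod-11 checksum
digit, names and recorded aliases, dates of birth, addresses and
postcodes, phone numbers, e-mail addresses, and named third-party contacts
— and produces a source database in the TSV dialect (patient master table,
third-party contacts table, free-text notes table, and a non-patient
lookup table) together with exact gold spans for every embedded identifier
occurrence.

Controlled imperfections mirror how real free text defeats
structured-identifier scrubbing: typographical errors (edit distance 1) in
identifier occurrences, *unknown* identifiers (nicknames never recorded in
structured fields — chosen so that no scrubber pattern can match them),
and notes misfiled into the wrong patient's record.

All lexicons are fictional and pairwise disjoint from the filler
vocabulary, so on a clean corpus (no typos, no unknowns, no misfiling)
every masking decision is attributable to configured behaviour.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .datadict import (Alteration, DataDictionary, DataDictionaryRow)
from .evaluate import GoldSpan, write_gold_tsv
from .pseudonym import KeyConfig, make_mrid, make_rid
from .scrub import (ScrubberConfig, ScrubSourceValue, assemble_scrubber,
                    chunks_of)
from .tsvdb import TsvDatabase

# ---------------------------------------------------------------------------
# Fictional lexicons (disjoint from each other and from FILLER_WORDS)

FORENAMES = (
    "Araminta", "Benedek", "Casimir", "Dorotea", "Evander", "Fenella",
    "Gaspard", "Hestia", "Ignatius", "Jolanda", "Kasimir", "Leopolda",
    "Mirabel", "Nikolaus", "Ottilie", "Peregrin", "Quintus", "Rosalind",
    "Sigmund", "Theodora", "Ulrich", "Valentina", "Wilhelmina", "Xanthe",
    "Yevgenia", "Zebediah", "Alaric", "Bronwen", "Cosimo", "Delphine",
    "Emeric", "Floriana", "Gideon", "Henrietta", "Isidore", "Jessamine",
    "Konstantin", "Lavinia", "Maximilian", "Nerissa",
)
SURNAMES = (
    "Abernathy", "Bellweather", "Crampton", "Dunholme", "Eastergate",
    "Fairweather", "Garraway", "Hollingsworth", "Inglewood", "Jorgensen",
    "Kettleburn", "Lockwood", "Mandeville", "Netherfield", "Oakhurst",
    "Pemberton", "Quillfeather", "Ravenscroft", "Silverwood", "Thackeray",
    "Underhill", "Vanterpool", "Wetherby", "Yardley", "Zellweger",
    "Ashcombe", "Birtwhistle", "Coldstream", "Darlington", "Eversley",
    "Fothergill", "Greystoke", "Harrowgate", "Iremonger", "Juniperton",
    "Kingsmead", "Larkspur", "Mossbourne", "Nightingale", "Ollerton",
)
NICKNAMES = (
    "Buzby", "Chippo", "Dinky", "Flapjacko", "Giggsy", "Humbuggo",
    "Jinxy", "Krumpet", "Loopylou", "Muffino", "Noodler", "Pipsqueako",
    "Quibbles", "Ruffler", "Scampino", "Tatty", "Umpty", "Wiggler",
    "Yoyo", "Zippo",
)
STREET_NAMES = (
    "Acacia", "Birchwood", "Cedarfield", "Damson", "Elderflower",
    "Foxglove", "Gorsebank", "Hawthorn", "Ivybridge", "Juniper",
    "Kestrel", "Lilacside", "Mulberry", "Nettlefold", "Primrose",
    "Quarry", "Rowanberry", "Sycamore",
)
STREET_TYPES = ("Road", "Street", "Avenue", "Drive", "Close", "Lane")
TOWNS = (
    "Wexbridge", "Thornmarket", "Ashendale", "Pellingham", "Crowhaven",
    "Marleford", "Dunswick", "Eldermoor",
)
RELATIONSHIPS = ("mother", "father", "sister", "brother", "carer",
                 "daughter", "son", "partner")
FILLER_WORDS = (
    "patient", "reports", "ongoing", "low", "mood", "with", "poor",
    "sleep", "and", "reduced", "appetite", "seen", "today", "in",
    "clinic", "for", "review", "of", "medication", "dose", "unchanged",
    "at", "present", "no", "thoughts", "harm", "denies", "suicidal",
    "ideation", "continues", "to", "attend", "weekly", "therapy",
    "sessions", "engaging", "well", "some", "improvement", "noted",
    "since", "last", "appointment", "remains", "anxious", "about",
    "work", "situation", "discussed", "coping", "strategies", "plan",
    "continue", "current", "treatment", "follow", "up", "weeks",
    "bloods", "taken", "results", "awaited", "risk", "assessment",
    "completed", "rated", "as", "stable", "family", "supportive",
    "attended", "alone", "appearance", "kempt", "speech", "normal",
    "rate", "tone", "affect", "reactive", "cognition", "grossly",
    "intact", "insight", "good", "concordant", "side", "effects",
    "mild", "nausea", "settling", "advised", "gradual", "increase",
    "activity", "levels", "referred", "community", "team", "letter",
    "copied", "general", "practitioner", "next", "month",
)

LOOKUP_ROWS = (
    ("F20", "schizophrenia"), ("F25", "schizoaffective disorder"),
    ("F31", "bipolar affective disorder"), ("F32", "depressive episode"),
    ("F33", "recurrent depressive disorder"), ("F41", "anxiety disorders"),
    ("F43", "stress-related disorders"), ("F60", "personality disorders"),
)


# ---------------------------------------------------------------------------
# Health-number checksum (public modulus-11 convention: 9 value digits,
# weights 10..2, check digit = 11 - (sum mod 11), 11 -> 0, 10 -> invalid)

def mpid_check_digit(first9: str) -> "int | None":
    total = sum(int(d) * (10 - i) for i, d in enumerate(first9))
    r = 11 - (total % 11)
    if r == 11:
        return 0
    if r == 10:
        return None
    return r


def mpid_checksum_ok(number: str) -> bool:
    return (len(number) == 10 and number.isdigit()
            and mpid_check_digit(number[:9]) == int(number[9]))


def _make_mpid(rng: random.Random) -> str:
    while True:
        first9 = "".join(str(rng.randrange(10)) for _ in range(9))
        check = mpid_check_digit(first9)
        if check is not None:
            return first9 + str(check)


# ---------------------------------------------------------------------------
# Patients

@dataclass(frozen=True)
class SyntheticPatient:
    pid: int
    mpid: str                    # 10-digit health-number-like identifier
    forename: str
    surname: str
    alias: "str | None"
    dob: datetime.date
    address: str                 # "23 Juniper Road, Wexbridge"
    postcode: str
    phone: str                   # 11-digit UK-style number
    email: str
    third_parties: tuple[tuple[str, str], ...]   # (name, relationship)

    def identifier_chunks(self) -> set[str]:
        """Lower-case alphanumeric chunks of every structured identifier
        (what the scrubber can know about this patient)."""
        chunks: set[str] = set()
        for value in (self.forename, self.surname, self.alias or "",
                      self.address, self.postcode,
                      *(name for name, _ in self.third_parties)):
            chunks.update(c.lower() for c in chunks_of(value))
        return chunks


def generate_patients(n: int, seed: int) -> list[SyntheticPatient]:
    """Deterministic fictional patients with valid-checksum health numbers."""
    rng = random.Random(seed)
    patients = []
    for i in range(n):
        forename = rng.choice(FORENAMES)
        surname = rng.choice(SURNAMES)
        alias = rng.choice([a for a in FORENAMES if a != forename]) \
            if rng.random() < 0.3 else None
        dob = datetime.date(1930, 1, 1) + datetime.timedelta(
            days=rng.randrange(365 * 75))
        street = rng.choice(STREET_NAMES)
        town = rng.choice(TOWNS)
        address = f"{rng.randrange(10, 99)} {street} " \
                  f"{rng.choice(STREET_TYPES)}, {town}"
        postcode = (rng.choice("ABCDEFGHJKLMN") + rng.choice("ABCDEFGHJKLMN")
                    + str(rng.randrange(1, 9)) + " " + str(rng.randrange(1, 9))
                    + rng.choice("PQRSTUVWXYZ") + rng.choice("PQRSTUVWXYZ"))
        phone = "0" + "".join(str(rng.randrange(10)) for _ in range(10))
        email = f"{forename.lower()}.{surname.lower()}@example.org"
        third_parties = tuple(
            (f"{rng.choice([f for f in FORENAMES if f != forename])} "
             f"{rng.choice([s for s in SURNAMES if s != surname])}",
             rng.choice(RELATIONSHIPS))
            for _ in range(rng.randrange(3)))
        patients.append(SyntheticPatient(
            pid=1001 + i, mpid=_make_mpid(rng), forename=forename,
            surname=surname, alias=alias, dob=dob, address=address,
            postcode=postcode, phone=phone, email=email,
            third_parties=third_parties))
    return patients


# ---------------------------------------------------------------------------
# Corpus specification

@dataclass(frozen=True)
class CorpusSpec:
    """Corpus shape and imperfection rates.

    The size defaults mirror a conventional large-scale timing corpus
    (1000 patients x 100 notes x 1000 words); tests and examples pass
    smaller sizes explicitly. Rates are fractions of note words:
    ``identifier_density`` known-identifier insertions, ``typo_rate`` the
    chance an eligible name occurrence is misspelled by one character,
    ``unknown_identifier_rate`` nickname insertions absent from structured
    data, and ``misfile_rate`` the fraction of notes filed under the wrong
    patient.
    """
    n_patients: int = 1000
    notes_per_patient: int = 100
    words_per_note: int = 1000
    identifier_density: float = 0.03
    typo_rate: float = 0.0
    unknown_identifier_rate: float = 0.0
    misfile_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("identifier_density", "typo_rate",
                     "unknown_identifier_rate", "misfile_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_patients, self.notes_per_patient,
               self.words_per_note) < 0:
            raise ValueError("counts must be >= 0")


# ---------------------------------------------------------------------------
# Identifier rendering

_ORDINALS = {1: "st", 2: "nd", 3: "rd", 21: "st", 22: "nd", 23: "rd",
             31: "st"}
_MONTHS = ("January", "February", "March", "April", "May", "June", "July",
           "August", "September", "October", "November", "December")


def _ordinal(day: int) -> str:
    return f"{day}{_ORDINALS.get(day, 'th')}"


def date_variants(d: datetime.date) -> list[str]:
    """The written date forms the generator embeds in notes."""
    mon, month = _MONTHS[d.month - 1][:3], _MONTHS[d.month - 1]
    y2 = f"{d.year % 100:02d}"
    return [
        f"{d.day:02d} {mon} {d.year}",
        f"{d.day} {month} {y2}",
        f"{d.day}/{d.month}/{y2}",
        f"{d.month}/{d.day}/{y2}",
        f"{mon} {d.day} {d.year}",
        f"{d.year}/{d.month:02d}/{d.day:02d}",
        f"{d.year}-{d.month:02d}-{d.day:02d}",
        f"{_ordinal(d.day)} {month} {y2}",
        f"{mon} {_ordinal(d.day)} {y2}",
        f"{d.day:02d}.{d.month:02d}.{y2}",
        f"{d.day}.{d.month}.{d.year}",
        f"{d.year}{d.month:02d}{d.day:02d}",
    ]


def _phone_variants(phone: str) -> list[str]:
    return [phone, f"{phone[:5]} {phone[5:]}", f"({phone[:5]}) {phone[5:]}"]


def _mpid_variants(mpid: str) -> list[str]:
    return [mpid, f"{mpid[:3]} {mpid[3:6]} {mpid[6:]}"]


def _postcode_variants(pc: str) -> list[str]:
    compact = pc.replace(" ", "")
    return [pc, compact, pc.replace(" ", "-")]


def _levenshtein(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _inject_typo(word: str, rng: random.Random) -> str:
    """One random character insertion, deletion, or substitution."""
    i = rng.randrange(len(word))
    op = rng.choice("ids")
    if op == "i":
        return word[:i] + rng.choice(_LETTERS) + word[i:]
    if op == "d":
        return word[:i] + word[i + 1:]
    repl = rng.choice([c for c in _LETTERS if c != word[i].lower()])
    return word[:i] + repl + word[i + 1:]


def _safe_nickname(patient: SyntheticPatient, rng: random.Random) -> str:
    """A nickname no scrubber pattern for *patient* can match: outside the
    edit-distance-1 neighbourhood of every identifier chunk and not a
    suffix form of one."""
    chunks = patient.identifier_chunks()
    candidates = list(NICKNAMES)
    rng.shuffle(candidates)
    for nick in candidates:
        low = nick.lower()
        if any(_levenshtein(low, c) <= 1 or low == c + "s" for c in chunks):
            continue
        return nick
    raise RuntimeError("no safe nickname available")   # pragma: no cover


# ---------------------------------------------------------------------------
# Corpus generation

@dataclass
class CorpusBundle:
    source_dir: Path
    patients: list[SyntheticPatient]
    gold: list[GoldSpan]
    spec: CorpusSpec
    note_pids: dict[str, int] = field(default_factory=dict)


def _known_identifier(identity: SyntheticPatient, rng: random.Random,
                      typo_rate: float) -> str:
    """Render one structured-identifier occurrence for insertion."""
    kinds = ["forename", "surname", "fullname", "dob", "address",
             "postcode", "phone", "mpid", "email"]
    if identity.alias:
        kinds.append("alias")
    if identity.third_parties:
        kinds.append("thirdparty")
    kind = rng.choice(kinds)
    if kind in ("forename", "surname", "alias", "fullname"):
        if kind == "fullname":
            words = [identity.forename, identity.surname]
        elif kind == "alias":
            words = [identity.alias]           # type: ignore[list-item]
        else:
            words = [getattr(identity, kind)]
        if typo_rate > 0:
            words = [_inject_typo(w, rng)
                     if len(w) >= 4 and rng.random() < typo_rate else w
                     for w in words]
        return " ".join(words)
    if kind == "dob":
        return rng.choice(date_variants(identity.dob))
    if kind == "address":
        return identity.address.replace(",", "")
    if kind == "postcode":
        return rng.choice(_postcode_variants(identity.postcode))
    if kind == "phone":
        return rng.choice(_phone_variants(identity.phone))
    if kind == "mpid":
        return rng.choice(_mpid_variants(identity.mpid))
    if kind == "email":
        return identity.email
    return identity.third_parties[rng.randrange(
        len(identity.third_parties))][0]


def generate_corpus(patients: Sequence[SyntheticPatient], spec: CorpusSpec,
                    out_dir: "str | Path") -> CorpusBundle:
    """Write the synthetic source database and gold annotations.

    Emits ``patients``, ``relatives``, ``notes`` and ``lookup`` tables in
    the TSV dialect plus ``gold.tsv`` beside them. Gold spans exactly
    cover every embedded identifier occurrence; occurrences belonging to a
    misfiled identity or to an unrecorded nickname carry subclass
    ``unknown``.
    """
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    db = TsvDatabase(out, create=True)
    gold: list[GoldSpan] = []
    note_rows: list[dict] = []
    note_pids: dict[str, int] = {}
    nicknames = {p.pid: _safe_nickname(p, rng) for p in patients}
    any_unknown = False
    note_id = 0

    for patient in patients:
        for _ in range(spec.notes_per_patient):
            note_id += 1
            doc_id = str(note_id)
            misfiled = (spec.misfile_rate > 0 and len(patients) > 1
                        and rng.random() < spec.misfile_rate)
            identity = patient
            if misfiled:
                identity = rng.choice([p for p in patients if p is not patient])
            subclass = "unknown" if misfiled else "known"
            parts: list[str] = []
            pos = 0
            words = 0
            while words < spec.words_per_note:
                r = rng.random()
                if r < spec.identifier_density:
                    token = _known_identifier(identity, rng, spec.typo_rate)
                    span_class = subclass
                elif r < spec.identifier_density + spec.unknown_identifier_rate:
                    token = nicknames[identity.pid]
                    span_class = "unknown"
                    any_unknown = True
                else:
                    token = rng.choice(FILLER_WORDS)
                    span_class = None
                if parts:
                    pos += 1                       # joining space
                if span_class is not None:
                    gold.append(GoldSpan(doc_id, pos, pos + len(token),
                                         span_class, necessity=True))
                parts.append(token)
                pos += len(token)
                words += len(token.split())
            text = " ".join(parts)
            note_rows.append({
                "note_id": str(note_id), "pid": str(patient.pid),
                "note_date": (datetime.date(2015, 1, 1) + datetime.timedelta(
                    days=rng.randrange(3000))).isoformat(),
                "note_text": text,
            })
            note_pids[doc_id] = patient.pid

    # Guarantee the unknown-identifier condition produces at least one
    # unknown span (tiny corpora could otherwise miss it by chance).
    if spec.unknown_identifier_rate > 0 and not any_unknown and note_rows:
        last = note_rows[-1]
        pid = int(last["pid"])
        nick = nicknames[pid]
        base = last["note_text"]
        gold.append(GoldSpan(last["note_id"], len(base) + 1,
                             len(base) + 1 + len(nick), "unknown", True))
        last["note_text"] = base + " " + nick

    db.write_rows("patients",
                  ("pid", "nhs_number", "forename", "surname", "alias",
                   "dob", "address", "postcode", "phone", "email"),
                  [{
                      "pid": str(p.pid), "nhs_number": p.mpid,
                      "forename": p.forename, "surname": p.surname,
                      "alias": p.alias, "dob": p.dob.isoformat(),
                      "address": p.address, "postcode": p.postcode,
                      "phone": p.phone, "email": p.email,
                  } for p in patients])
    rel_rows = []
    rel_id = 0
    for p in patients:
        for name, relationship in p.third_parties:
            rel_id += 1
            rel_rows.append({"rel_id": str(rel_id), "pid": str(p.pid),
                             "rel_name": name, "relationship": relationship})
    db.write_rows("relatives", ("rel_id", "pid", "rel_name", "relationship"),
                  rel_rows)
    db.write_rows("notes", ("note_id", "pid", "note_date", "note_text"),
                  note_rows)
    db.write_rows("lookup", ("code", "description"),
                  [{"code": c, "description": d} for c, d in LOOKUP_ROWS])
    (out / "gold.tsv").write_text(write_gold_tsv(gold), encoding="utf-8")
    return CorpusBundle(source_dir=out, patients=list(patients), gold=gold,
                        spec=spec, note_pids=note_pids)


# ---------------------------------------------------------------------------
# The matching data dictionary

def _row(table: str, fld: str, dtype: str = "VARCHAR(255)", **kw
         ) -> DataDictionaryRow:
    dest = kw.pop("dest", fld)
    if kw.pop("omit", False):
        kw["alterations"] = kw.get("alterations", ()) + (Alteration("omit"),)
        return DataDictionaryRow(src_db="source", src_table=table,
                                 src_field=fld, src_datatype=dtype, **kw)
    return DataDictionaryRow(src_db="source", src_table=table, src_field=fld,
                             src_datatype=dtype, dest_table=table,
                             dest_field=dest, dest_datatype=dtype, **kw)


def fixture_data_dictionary(address_method: str = "words") -> DataDictionary:
    """Reviewed (non-draft) dictionary for the synthetic EMR schema.

    Scrub-source order puts the numeric identifiers (health number, phone)
    before the date of birth so that, at a shared text position, the more
    specific digit patterns win.
    """
    rows = [
        _row("patients", "pid", "INTEGER", is_pid=True, is_pk=True,
             is_master_pid_column=True, dest="rid", index_kind="normal"),
        _row("patients", "nhs_number", "VARCHAR(10)", is_mpid=True,
             scrub_src_kind="patient", scrub_method="number", dest="mrid"),
        _row("patients", "phone", omit=True,
             scrub_src_kind="patient", scrub_method="number"),
        _row("patients", "forename", omit=True,
             scrub_src_kind="patient", scrub_method="words"),
        _row("patients", "surname", omit=True,
             scrub_src_kind="patient", scrub_method="words"),
        _row("patients", "alias", omit=True,
             scrub_src_kind="patient", scrub_method="words"),
        _row("patients", "email", omit=True,
             scrub_src_kind="patient", scrub_method="code"),
        _row("patients", "postcode", omit=True,
             scrub_src_kind="patient", scrub_method="code"),
        _row("patients", "address", omit=True,
             scrub_src_kind="patient", scrub_method=address_method),
        _row("patients", "dob", "DATE", scrub_src_kind="patient",
             scrub_method="date", alterations=(Alteration("truncate_date"),)),
        _row("notes", "note_id", "INTEGER", is_pk=True),
        _row("notes", "pid", "INTEGER", is_pid=True, dest="rid",
             index_kind="normal"),
        _row("notes", "note_date", "DATE"),
        _row("notes", "note_text", "TEXT",
             alterations=(Alteration("scrub"),), index_kind="fulltext"),
        _row("relatives", "rel_id", "INTEGER", is_pk=True),
        _row("relatives", "pid", "INTEGER", is_pid=True, dest="rid"),
        _row("relatives", "rel_name", omit=True,
             scrub_src_kind="thirdparty", scrub_method="words"),
        _row("relatives", "relationship"),
        _row("lookup", "code", "VARCHAR(8)", is_pk=True),
        _row("lookup", "description"),
    ]
    dd = DataDictionary(rows=rows, draft_flag=False)
    dd.validate()
    return dd


def condition_preset(name: str) -> tuple[str, frozenset[str]]:
    """(address scrub method, whitelist) pairs for the tuning storyline:
    ``strict`` masks addresses word-by-word with nothing whitelisted;
    ``tuned`` switches addresses to phrase matching and whitelists the
    town names that recur in clinic correspondence."""
    if name == "strict":
        return "words", frozenset()
    if name == "tuned":
        return "phrase", frozenset(t.lower() for t in TOWNS)
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Brute-force expected-destination oracle

def expected_destination(source_dir: "str | Path", dd: DataDictionary,
                         cfg: ScrubberConfig, keys: KeyConfig
                         ) -> dict[str, tuple[list[str], list[dict]]]:
    """Independently derive the expected destination for a generated corpus.

    A deliberately plain re-derivation used as the engine's end-to-end
    oracle: it reads the fixture schema directly, builds each patient's
    scrubber by straightforward loops over the structured fields (in the
    dictionary's scrub-source order), scrubs every note, and assembles the
    destination tables with RID/MRID/TRID columns — no incremental logic,
    no sharding, no caching.
    """
    db = TsvDatabase(source_dir)
    patients = db.read_rows("patients")
    relatives = db.read_rows("relatives")
    notes = db.read_rows("notes")
    lookup = db.read_rows("lookup")

    address_method = next(r.scrub_method for r in dd.rows
                          if r.src_field == "address")

    pids = sorted((p["pid"] for p in patients), key=lambda v: int(v))
    trids: dict[str, int] = {}
    used: set[int] = set()
    for pid in pids:
        rng = random.Random(f"{keys.trid_seed}:{pid}")
        while True:
            t = rng.randint(1, 2 ** 31 - 1)
            if t not in used:
                used.add(t)
                trids[pid] = t
                break

    by_pid = {p["pid"]: p for p in patients}
    scrubbers = {}
    for pid in pids:
        p = by_pid[pid]
        values = []
        for fld, method in (("nhs_number", "number"), ("phone", "number"),
                            ("forename", "words"), ("surname", "words"),
                            ("alias", "words"), ("email", "code"),
                            ("postcode", "code"), ("address", address_method),
                            ("dob", "date")):
            v = p.get(fld)
            if v:
                values.append(ScrubSourceValue(v, method, "patient"))
        for rel in relatives:
            if rel["pid"] == pid and rel.get("rel_name"):
                values.append(ScrubSourceValue(rel["rel_name"], "words",
                                               "thirdparty"))
        scrubbers[pid] = assemble_scrubber(values, cfg)

    def rid(pid: str) -> str:
        return make_rid(pid, keys.pid_key, keys.algorithm)

    dest: dict[str, tuple[list[str], list[dict]]] = {}
    patient_rows = []
    for pid in pids:
        p = by_pid[pid]
        dob = datetime.date.fromisoformat(p["dob"])
        patient_rows.append({
            "trid": str(trids[pid]), "rid": rid(pid),
            "mrid": make_mrid(p["nhs_number"], keys.mpid_key, keys.algorithm),
            "dob": dob.replace(day=1).isoformat(),
        })
    patient_rows.sort(key=lambda r: r["rid"])
    dest["patients"] = (["trid", "rid", "mrid", "dob"], patient_rows)

    note_rows = []
    for n in notes:
        pid = n["pid"]
        note_rows.append({
            "trid": str(trids[pid]), "note_id": n["note_id"],
            "rid": rid(pid), "note_date": n["note_date"],
            "note_text": scrubbers[pid].scrub(n["note_text"] or ""),
        })
    note_rows.sort(key=lambda r: int(r["note_id"]))
    dest["notes"] = (["trid", "note_id", "rid", "note_date", "note_text"],
                     note_rows)

    rel_rows = []
    for rel in relatives:
        pid = rel["pid"]
        rel_rows.append({"trid": str(trids[pid]), "rel_id": rel["rel_id"],
                         "rid": rid(pid),
                         "relationship": rel["relationship"]})
    rel_rows.sort(key=lambda r: int(r["rel_id"]))
    dest["relatives"] = (["trid", "rel_id", "rid", "relationship"], rel_rows)

    dest["lookup"] = (["code", "description"],
                      sorted(lookup, key=lambda r: r["code"]))
    return dest


def load_destination(dest_dir: "str | Path"
                     ) -> dict[str, tuple[list[str], list[dict]]]:
    """Load an engine destination into the oracle's comparison form
    (bookkeeping tables excluded)."""
    db = TsvDatabase(dest_dir)
    out = {}
    for name in db.table_names():
        if name.startswith("_"):
            continue
        out[name] = (db.columns(name), db.read_rows(name))
    return out
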