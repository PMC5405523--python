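"""Research pseudonyms: HMAC digests, transient integer IDs, secret store.

A patient ID (PID) is mapped to a research ID (RID) as the hexadecimal
digest of an HMAC over the PID's canonical byte serialization under a
secret institutional key. HMAC keeps the mapping one-way, collision
resistant, reproducible, and safe against known-pair attacks, and a shared
key lets independently de-identified databases be linked on the digest of a
common master identifier (MPID → MRID).

Because 32–128-character digests are clumsy in queries, each RID also gets
a transient integer research ID (TRID) drawn pseudorandomly (one-time-pad
style) from a seeded generator; the RID↔TRID mapping is 1:1, survives
incremental runs, and is destroyed and regenerated on a full rebuild.

The PID↔RID↔TRID mapping lives in a separate secret store (a single
restricted-permission TSV file) that also carries each patient's scrubber
hash and opt-out flag for incremental processing.
"""

from __future__ import annotations

import hashlib
import hmac
import os
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

ALGORITHMS = {
    "HMAC-MD5": (hashlib.md5, 32),
    "HMAC-SHA-256": (hashlib.sha256, 64),
    "HMAC-SHA-512": (hashlib.sha512, 128),
}

TRID_MIN = 1
TRID_MAX = 2 ** 31 - 1   # fits a signed 32-bit database integer column


class KeyConfigError(ValueError):
    pass


class UnknownRidError(KeyError):
    pass


@dataclass(frozen=True)
class KeyConfig:
    """Secret keys and algorithm choice.

    Separate keys for the PID and the MPID mean that knowing one mapping
    sheds no light on the other; a warning is issued if they coincide.
    ``hash_key`` keys the row-content digests used for incremental change
    detection (defaults to a key derived from ``pid_key``).
    """
    pid_key: str
    mpid_key: str
    algorithm: str = "HMAC-SHA-256"
    trid_seed: int | None = None
    hash_key: str = ""

    def __post_init__(self):
        if not self.pid_key or not self.mpid_key:
            raise KeyConfigError("pid_key and mpid_key must be non-empty")
        if self.algorithm not in ALGORITHMS:
            raise KeyConfigError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose one of {sorted(ALGORITHMS)}")
        if self.pid_key == self.mpid_key:
            import warnings
            warnings.warn("pid_key and mpid_key are identical; separate keys "
                          "are strongly recommended", stacklevel=2)

    @property
    def effective_hash_key(self) -> str:
        return self.hash_key or (self.pid_key + "/row-content")


def canonical_pid_bytes(pid: "int | str") -> bytes:
    """Canonical serialization hashed by make_rid: decimal text for
    integers, verbatim UTF-8 for text (stable across runs and platforms)."""
    if isinstance(pid, bool):
        raise TypeError("boolean is not a patient identifier")
    if isinstance(pid, int):
        return str(pid).encode("ascii")
    if isinstance(pid, str):
        return pid.encode("utf-8")
    raise TypeError(f"cannot serialize PID of type {type(pid).__name__}")


def make_rid(pid: "int | str", key: str,
             algorithm: str = "HMAC-SHA-256") -> str:
    """HMAC hex digest of the PID under *key*: the research identifier."""
    if not key:
        raise KeyConfigError("empty secret key")
    try:
        digestmod, _ = ALGORITHMS[algorithm]
    except KeyError:
        raise KeyConfigError(f"unknown algorithm {algorithm!r}") from None
    return hmac.new(key.encode("utf-8"), canonical_pid_bytes(pid),
                    digestmod).hexdigest()


def make_mrid(mpid: "int | str", mpid_key: str,
              algorithm: str = "HMAC-SHA-256") -> str:
    """Master research identifier: HMAC digest of the master patient ID.

    Two sites hashing a shared identifier under a shared key produce equal
    MRIDs, enabling linkage of separately de-identified databases.
    """
    return make_rid(mpid, mpid_key, algorithm)


def content_hash(parts: "list[str | None]", key: str) -> str:
    """Keyed digest of a row's copied content, for change detection."""
    h = hmac.new(key.encode("utf-8"), digestmod=hashlib.sha256)
    for part in parts:
        if part is None:
            h.update(b"\x00N")
        else:
            h.update(b"\x00V" + part.encode("utf-8"))
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Secret store

@dataclass
class PseudonymRecord:
    pid: str
    rid: str
    trid: int
    mpid: str | None = None
    mrid: str | None = None
    scrubber_hash: str | None = None
    opted_out: bool = False


_STORE_HEADER = ("pid", "rid", "trid", "mpid", "mrid", "scrubber_hash",
                 "opted_out")


class SecretStore:
    """Single-file bidirectional PID↔RID↔TRID mapping with audit fields.

    Stored as a restricted-permission TSV; ordering on disk is canonical
    (sorted by PID) so repeated runs are byte-stable.
    """

    def __init__(self, path: "str | os.PathLike"):
        self.path = Path(path)
        self._by_pid: dict[str, PseudonymRecord] = {}
        self._by_rid: dict[str, PseudonymRecord] = {}
        self._trids: set[int] = set()
        if self.path.exists():
            self._load()

    # -- persistence ----------------------------------------------------------

    def _load(self) -> None:
        with self.path.open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != list(_STORE_HEADER):
                raise ValueError(f"bad secret store header in {self.path}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rec = PseudonymRecord(
                    pid=f[0], rid=f[1], trid=int(f[2]),
                    mpid=f[3] or None, mrid=f[4] or None,
                    scrubber_hash=f[5] or None, opted_out=f[6] == "Y")
                self._index(rec)

    def _index(self, rec: PseudonymRecord) -> None:
        self._by_pid[rec.pid] = rec
        self._by_rid[rec.rid] = rec
        self._trids.add(rec.trid)

    def save(self) -> None:
        def sort_key(pid: str):
            return (0, int(pid)) if pid.lstrip("-").isdigit() else (1, pid)
        lines = ["\t".join(_STORE_HEADER)]
        for pid in sorted(self._by_pid, key=sort_key):
            r = self._by_pid[pid]
            lines.append("\t".join([
                r.pid, r.rid, str(r.trid), r.mpid or "", r.mrid or "",
                r.scrubber_hash or "", "Y" if r.opted_out else ""]))
        self.path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        try:
            os.chmod(self.path, 0o600)
        except OSError:                                     # pragma: no cover
            pass

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_pid)

    def records(self) -> Iterator[PseudonymRecord]:
        return iter(self._by_pid.values())

    def get(self, pid: "int | str") -> PseudonymRecord | None:
        return self._by_pid.get(str(pid))

    def reverse_lookup(self, rid: str) -> str:
        """Privileged RID → PID lookup (the point of keeping the store)."""
        try:
            return self._by_rid[rid].pid
        except KeyError:
            raise UnknownRidError(rid) from None

    def trid_for(self, rid: str) -> int:
        try:
            return self._by_rid[rid].trid
        except KeyError:
            raise UnknownRidError(rid) from None

    def is_opted_out(self, pid: "int | str") -> bool:
        rec = self.get(pid)
        return rec is not None and rec.opted_out

    # -- mutation -------------------------------------------------------------

    def _trid_rng(self, pid: str, seed: "int | None") -> random.Random:
        # Per-patient generator: the TRID for a given (seed, pid) does not
        # depend on how many other patients exist or on registration
        # order, so incremental runs and fresh rebuilds agree.
        if seed is None:
            return random.Random()
        return random.Random(f"{seed}:{pid}")

    def _draw_trid(self, rng: random.Random) -> int:
        for _ in range(10_000_000):
            trid = rng.randint(TRID_MIN, TRID_MAX)
            if trid not in self._trids:
                return trid
        raise RuntimeError("TRID space exhausted")          # pragma: no cover

    def register(self, pid: "int | str", keys: KeyConfig,
                 mpid: "int | str | None" = None) -> PseudonymRecord:
        """Return the record for *pid*, creating RID/TRID (and MRID if an
        MPID is supplied) on first sight. Existing TRIDs are reused, which
        is what keeps them stable across incremental runs."""
        pid_s = str(pid)
        rec = self._by_pid.get(pid_s)
        if rec is None:
            rid = make_rid(pid, keys.pid_key, keys.algorithm)
            trid = self._draw_trid(self._trid_rng(pid_s, keys.trid_seed))
            rec = PseudonymRecord(pid=pid_s, rid=rid, trid=trid)
            self._index(rec)
        if mpid is not None and rec.mrid is None:
            rec.mpid = str(mpid)
            rec.mrid = make_mrid(mpid, keys.mpid_key, keys.algorithm)
        return rec

    def set_scrubber_hash(self, pid: "int | str", digest: str) -> None:
        rec = self._by_pid[str(pid)]
        rec.scrubber_hash = digest

    def scrubber_hash(self, pid: "int | str") -> str | None:
        rec = self.get(pid)
        return rec.scrubber_hash if rec else None

    def mark_opted_out(self, pid: "int | str") -> None:
        rec = self.get(pid)
        if rec is not None:
            rec.opted_out = True

    def rebuild_trids(self, seed: int | None) -> None:
        """Destroy and pseudorandomly regenerate every TRID (full rebuild)."""
        self._trids.clear()
        def sort_key(pid: str):
            return (0, int(pid)) if pid.lstrip("-").isdigit() else (1, pid)
        for pid in sorted(self._by_pid, key=sort_key):
            rec = self._by_pid[pid]
            rec.trid = self._draw_trid(self._trid_rng(pid, seed))


def allocate_trid(rid: str, store: SecretStore) -> int:
    """TRID for a RID already registered in *store* (stable 1:1 mapping)."""
    return store.trid_for(rid)


# ---------------------------------------------------------------------------
# Didactic brute-force inversion

MAX_BRUTEFORCE_BOUND = 10 ** 6


def demo_bruteforce_attack(target_rid: str, key: str,
                           id_space_bound: int,
                           algorithm: str = "HMAC-SHA-256") -> "int | None":
    """Invert a digest by exhaustively hashing the PID space [0, bound).

    Demonstrates why key secrecy matters when PIDs come from a small space
    (a 10-digit health number leaves < 10^9 candidates). Refuses bounds
    beyond a demonstration size.
    """
    if id_space_bound > MAX_BRUTEFORCE_BOUND:
        raise ValueError(
            f"bound {id_space_bound} exceeds demonstration limit "
            f"{MAX_BRUTEFORCE_BOUND}")
    for pid in range(id_space_bound):
        if hmac.compare_digest(make_rid(pid, key, algorithm), target_rid):
            return pid
    return None
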