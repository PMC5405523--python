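# Methods

## The model

The de-identifier assumes that what identifies a patient inside their free
text is, overwhelmingly, information the EMR also holds in structured form:
names and recorded aliases, dates of birth, addresses and postcodes,
telephone and health numbers, e-mail addresses, and the names of recorded
third-party contacts. Under that assumption, de-identification is a
per-patient pattern-matching problem: compile the patient's structured
values into regular expressions and mask every match in that patient's
documents. The converse is the method's stated principal weakness, which
the package models explicitly rather than hides: identifiers that exist
*only* in free text (nicknames, names of unrecorded friends, notes misfiled
under the wrong patient) cannot be masked, and the evaluation stratifies
them as *unknown* identifiers so their cost is measured, not ignored.

## Pattern construction

Source values are chunked on every non-alphanumeric character (underscore
is treated as a separator, see Idempotence). Builders:

* **words** — one pattern per chunk, word-boundary anchored,
  case-insensitive, with optional suffixes (default `s`) appended as an
  optional group. Chunks shorter than `min_string_length` (default 2) or on
  the whitelist yield no pattern.
* **phrase** — the chunks in order, joined by `\W+`, boundary-anchored.
  Exact (no typo tolerance): the method exists precisely to be restrictive.
* **number** — the value's digit string joined by `\W*`, guarded by
  `(?<!\d) … (?!\d)` rather than `\b` (a digit run inside `M123456` has no
  word boundary before it; the lookaround form masks it anyway while
  refusing to fire inside a longer digit run). `anchor_numbers_at_boundaries`
  switches to `\b` anchoring for stricter behaviour.
* **code** — as number over the full alphanumeric sequence, `\b`-anchored;
  no semantic rules (postcodes, e-mail addresses, NI-style codes).
* **date** — day/month/year components, each with its written equivalents
  (numeric with optional leading zeros, 3-letter and full month names,
  2- and 4-digit years, ordinal day suffixes), composed in day-month-year,
  month-day-year and year-month-day orders with `\W*` separators — which
  also covers compact forms (`20130107`) — plus an optional `T\d+`
  timestamp suffix on the year-first order. Dates are points in time only:
  no temporal inference, so "Easter Day in 1950" is (documentedly) missed.

### Typo tolerance

Tolerance of typographical errors in the *words* method is implemented by
explicitly enumerating the edit-distance-1 neighbourhood of a chunk as a
regex alternation (exact | substitution at each position | deletion at each
position | insertion at each gap), with substituted/inserted characters
drawn from the alphanumeric class. This is exact — a property test checks
agreement with a brute-force Levenshtein oracle — but combinatorial in the
edit bound, so `max_typos` supports 0 and 1; 1 is the default and the
conventional operating point, and the tolerance only applies to chunks of
`min_word_length_for_typos` (default 4) or more, so that a patient named
"Ian" does not swallow the word "in". Whether suffixes stack on top of a
fuzzy match is genuinely underdetermined; both behaviours are available
(`suffixes_with_typos`, default on).

## Scrubber assembly and application

Patient and third-party patterns are agglomerated per category into single
alternations, in data-dictionary order (the dictionary is the
administrator's statement of priority); nonspecific patterns — fixed-length
digit runs with optional horizontal whitespace, the six UK postcode
letter/digit layouts, and blacklist words — are shared across patients.
Application order is nonspecific → patient → third party, so a word that is
both blacklisted and whitelisted is removed (the blacklist is a nonspecific
scrubber and runs first); within the patient pass a whitelist guard
additionally refuses to replace a whitelisted word. Matching is
case-insensitive throughout.

### Idempotence

Placeholders (`[___]`, `[…]`, `[~~~]`) must contain no alphanumeric
characters (validated at configuration time), and the fuzzy character class
excludes the underscore, so no generated pattern can match inside a
placeholder. One subtlety remains: masking can bring two fragments of
another identifier into adjacency across a placeholder that contains no
word characters, so the category passes are iterated to a fixpoint rather
than run once. Termination is guaranteed — every replacement strictly
removes at least one alphanumeric character and inserts none — and the
fixpoint makes `scrub(scrub(t)) == scrub(t)` hold unconditionally; in
practice the loop runs twice (the second pass confirming no change).

## Pseudonymisation

RIDs are hex HMAC digests of the PID's canonical byte serialization
(decimal text for integers, verbatim UTF-8 for text) under a secret key;
MD5/SHA-256/SHA-512 variants give 32/64/128-character digests. Separate
keys for the PID and the master patient ID keep the two mappings
independent; a shared master key across institutions makes equal master
IDs hash to equal MRIDs, enabling linkage without sharing identifiers.
TRIDs are drawn from `[1, 2^31 − 1]` (fits a signed 32-bit integer column)
by a generator seeded per patient from `(trid_seed, pid)`, with rejection
on collision. The per-patient derivation is deliberate: allocation is then
independent of registration order and of which other patients exist, so an
incremental run and a fresh rebuild with the same seed agree exactly —
collision-resolution order is the one residual order dependence, with
probability ~n²/2³² of mattering at all. A full rebuild regenerates TRIDs
(with a new seed they all change); incremental runs reuse stored ones. The
secret store is a single 0600-permission TSV, written in sorted-PID order
for byte stability, and keeps scrubber hashes and opt-out flags alongside
the mapping; opted-out patients stay in the store (flagged) so they remain
suppressed and auditable after wiping.

## Engine

The destination is rebuilt table by table: non-patient tables copy (with
alterations but no scrubber); patient tables — those with a PID column in
the dictionary — process row by row under the row's patient's scrubber,
keyed by TRID, with the PID column replaced by the RID (or dropped
entirely when pseudonym storage is suppressed) and the master-ID column by
the MRID. NULLs pass through every alteration untouched. Destination rows
are written in canonical order (by primary key, numeric-aware; source
order for keyless tables), which is what makes three different execution
strategies — full, incremental, and sharded across workers — byte-identical.
`workers` shards patient rows by integer PID modulo the worker count and
processes shard by shard; the canonical sort is the deterministic merge.

Incremental change detection uses a keyed HMAC-SHA-256 over all of a row's
dictionary-listed source values in dictionary order. Hashing all listed
columns (not only copied ones) slightly over-triggers rework — a change in
an omitted column rewrites the row — which is harmless because the
correctness criterion is equality with a fresh full run, and deliberately
conservative. Tables without a primary key are dropped and recreated.
Tables declared immutable skip hash bookkeeping.

## The synthetic EMR

The generator emulates the identifier inventory above: a patient master
table (with 10-digit health numbers carrying a modulus-11 check digit —
weights 10..2 over nine value digits, remainder 11 → 0, remainder 10
regenerated), a relatives table, free-text notes, and a non-patient lookup
table. Notes are streams of filler words into which identifier renderings
are injected at `identifier_density` (default 0.03 of words — the same
order as the ~3% identifier share of a published 50,274-word clinical
evaluation corpus), drawn across all identifier kinds and written forms
(twelve date formats, three phone/postcode formats, etc.), with exact gold
spans recorded at insertion. Controlled imperfections:

* `typo_rate` — an eligible name occurrence (≥ 4 characters) is perturbed
  by one random edit; still masked by construction of the fuzzy contract.
* `unknown_identifier_rate` — a nickname never present in structured data
  is inserted; nicknames are screened to lie outside the edit-distance-1
  neighbourhood (and suffix forms) of every chunk the patient's scrubber
  could know, so they are unmaskable by construction.
* `misfile_rate` — a note draws its identifiers from a different patient;
  those spans are gold-labelled *unknown*.

The size defaults (1000 patients × 100 notes × 1000 words) mirror the
conventional large-scale timing corpus for this class of system; tests and
the acceptance script pass smaller shapes (tens of patients, a few notes of
~100 words) chosen to exercise every code path with multiple occurrences of
every identifier kind.

All lexicons are fictional and pairwise disjoint from the filler
vocabulary, so on a clean corpus every mask is attributable: known-identifier
sensitivity 1.0 and precision 1.0 are *structural* results there. What
passing these tests does **not** show: performance on real clinical
language, where identifier/vocabulary overlap ("March" the town vs the
month), abbreviation, and formatting noise make precision strictly
empirical. The package therefore treats published corpus figures as inputs
to verify the metric arithmetic against, not as numbers a synthetic corpus
could legitimately reproduce. The `condition_preset` pairs ("strict":
addresses as words, nothing whitelisted; "tuned": addresses as phrases,
towns whitelisted) reproduce the structure of precision tuning, not its
numbers.

## Evaluation

Scoring aligns raw and scrubbed text character-wise (difflib), maps each
placeholder occurrence to its raw span, and counts conventionally
whitespace-split source tokens, with each mask counting as one word: a
multi-word identifier masked by one placeholder is one hit; masked
per-word, several hits; partially masked, one hit per masked word and one
miss per unmasked word. Hits and false alarms are independent of the
known/unknown stratification (a masked word either was or was not
identifying), which is why precision is provably identical between strata
— asserted as an invariant. Spans a human judged not to require removal in
context (`necessity = false`) count as non-targets. The four cells sum to
the word count on every document, and corpus aggregation is additive.

## Numerical and design choices

* TSV dialect: `\N` encodes NULL (distinct from the empty string); the
  csv module's quoting handles embedded tabs/newlines.
* Data-dictionary TSV: fixed canonical header, unknown columns rejected;
  a `#draft` comment line carries the review flag; removed columns are
  flagged, never silently dropped. The engine refuses any draft.
* Drafting heuristics are ordered regexes over column names with a shipped
  default set; only tables containing a PID-like column receive scrub
  defaults, so lookup tables draft as plain copies.
* The master-PID invariant (exactly one column enumerating all patients)
  is enforced whenever the dictionary contains any patient table.
* HTML stripping uses the stdlib parser with entity decoding; document
  text extraction is a registry (plain text, HTML/XML built in; binary
  office formats are deployment-supplied, with skip-with-warning or hard
  error on absence).
* Undefined metrics (zero denominators) raise rather than return a
  sentinel.

## Known limitations

* `max_typos` ≤ 1 (see Typo tolerance); multi-error misspellings of an
  identifier are missed, mirroring the documented single miss of the
  method class at its default threshold.
* Non-ASCII letters count as word characters in chunks, but regex
  word-boundary behaviour at non-ASCII punctuation is engine-dependent and
  not part of the tested contract.
* The evaluation aligner requires that scrubbed text differ from raw only
  by placeholder substitution; it rejects pairs with other edits rather
  than guessing.
* Only the directory-of-TSV dialect is implemented as a database backend;
  live-engine connectivity is out of scope for this artifact.
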