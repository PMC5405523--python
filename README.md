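# deident

De-identification of relational patient data, driven by a TSV data
dictionary: free text is scrubbed with regular expressions generated from
each patient's *structured* identifiers, patient IDs become
cryptographically derived research pseudonyms, updates are incremental,
and de-identification accuracy is scored with signal-detection metrics.

## Who this is for

Research-database teams who hold an electronic medical record (EMR) —
especially one rich in free text, as psychiatric records are — and need a
de-identified copy that researchers can query without consent for each
patient. Structured fields (names, dates of birth, addresses, phone and
health numbers, named relatives) are exactly what leaks into the free
text, so they are also the best available scrubbing dictionary: the system
turns each patient's own recorded identifiers into masking patterns for
that patient's documents.

## The method

**Data dictionary.** A TSV file with one row per source column instructs
the engine: which columns are *scrub-source* (values used to build
patterns, with a method per column), which are *sensitive free text*
(masked on the way through), which carry the patient ID (PID), the master
patient ID (e.g. a national health number), and the primary key, plus
per-column alteration chains (omit, scrub, truncate dates to the first of
the month, strip HTML, skip rows by value) and index declarations.
Dictionaries can be auto-drafted from a schema by column-name heuristics
but must be human-reviewed (`accept-dd`) before the engine will run.

**Scrubbing.** Five pattern builders: *words* (each alphanumeric chunk,
with optional suffixes and tolerance of one typographical error on chunks
of ≥ 4 characters — `Jakob` also masks `Jacob`, but a patient named `Ian`
does not take the word `in`), *phrase* (chunks in order, any
non-alphanumeric separators — `4 Privet Drive` leaves `risperidone 4
mg/day` alone), *number* (digit string, punctuation-insensitive, guarded
by digit lookarounds), *code* (as number but alphanumeric; postcodes), and
*date* (day/month/year decomposition covering `07 Jan 2013`, `7/1/13`,
`1/7/13`, `2013-01-07`, `7th January 13`, `20130107T0123`, …). Patterns
agglomerate into a personalized scrubber per patient; application order is
nonspecific (fixed-length digit runs, UK postcode shapes, blacklist), then
patient (`[___]`), then third party (`[…]`); nonspecific masks use `[~~~]`.
All matching is case-insensitive, and scrubbing is idempotent.

**Pseudonyms.** RID = hex HMAC digest of the PID under a secret key
(HMAC-MD5 / HMAC-SHA-256 / HMAC-SHA-512 → 32 / 64 / 128 hex chars). HMAC
keeps the mapping one-way, collision-resistant, reproducible, and safe
against known PID/RID pairs; hashing a shared master identifier under a
shared key (MRID) links independently de-identified databases. A
pseudorandom transient integer ID (TRID) per patient keys the destination
tables; the secret PID↔RID↔TRID store supports privileged reverse lookup.
`demo_bruteforce_attack` shows why key secrecy matters for small ID
spaces.

**Incremental updates.** Every copied row gets a keyed content hash in the
destination, and each patient's scrubber gets a hash in the secret store.
Incremental runs delete rows that vanished from the source, rework a
patient in full when their scrubber changed (a new alias, say), process
new/changed rows, and reuse the rest — producing byte-for-byte the same
destination as a fresh full run. Opt-out lists (file, admin table, or
source marker field) exclude patients and can retrospectively wipe them.

**Evaluation.** Scrubbed output is scored against gold spans: a *hit*
masks a target, a *miss* leaves one, a *false alarm* masks a non-target,
a *correct rejection* leaves a non-target; each mask counts as one word.
Sensitivity (recall) = hits/(hits+misses); precision = hits/(hits+false
alarms). Identifiers are stratified into *known* (recorded in structured
fields) and *unknown* (nicknames, misfiled notes — invisible to this
method by construction); precision is identical between strata.

**Synthetic EMR.** Because no real clinical text can ship with the
package, `deident.synthetic` generates a fictional EMR (patient master
table with checksummed 10-digit health numbers, relatives, free-text
notes, a lookup table) with exact gold spans, and controlled rates of
typos, unknown nicknames, and misfiled notes.

## Worked example

```bash
deident genfixture --patients 3 --notes 2 --words 60 --seed 11 \
    --identifier-density 0.1 --out src
# write job.ini pointing [source] at src, with secret keys — see docs
deident anonymise --config job.ini
```

which prints the run report

```
table   rows_src  rows_dest  rows_transformed  rows_reused  rows_skipped  rows_deleted
lookup  8         8          8                 0            0             0
notes   6         6          6                 0            0             0
patients 3        3          3                 0            0             0
relatives 2       2          2                 0            0             0
patients: 3/3 processed, 0 opted out
```

A source note

```
... situation review Cosimo Kingsmead appointment mild of ongoing about mood Kingsmead ...
```

becomes, in `dst/notes.tsv`, keyed by TRID and RID instead of the PID:

```
trid       note_id  rid               note_date   note_text
567375895  2        25afcf69a689ab37…  2020-01-20  ... situation review [___] [___] appointment mild of ongoing about mood [___] ...
```

(the patient's recorded relative is masked as `[…]` where mentioned), and
`dst/patients.tsv` holds only pseudonyms and month-truncated birth dates:

```
trid       rid                mrid               dob
805843871  0e9e9aef1f193ab8…  176e4284b8da5026…  1999-11-01
567375895  25afcf69a689ab37…  79a49e825478041c…  2000-02-01
```

Scoring the run against the generated gold spans (`deident eval --raw …
--scrubbed … --gold src/gold.tsv`) reports, on this clean corpus,
`known:sensitivity 1.000` — every identifier the source database knows
about is masked; sensitivity on *all* identifiers falls below 1 exactly
when the corpus contains nicknames or misfiled notes the structured data
never mentions.

## Layout

| module                | role |
|-----------------------|------|
| `deident.datadict`    | parse/validate/draft/merge the TSV data dictionary |
| `deident.scrub`       | pattern builders and the personalized scrubber |
| `deident.pseudonym`   | HMAC RIDs/MRIDs, TRIDs, secret store, brute-force demo |
| `deident.alterations` | per-column alteration chains |
| `deident.engine`      | full/incremental runs, opt-outs, audit sampling |
| `deident.evaluate`    | gold-span scoring and stratified reports |
| `deident.synthetic`   | fictional EMR generator and the end-to-end oracle |
| `deident.tsvdb`       | the directory-of-TSV table dialect |
| `deident.config`, `deident.cli` | INI job configuration and the `deident` command |

Not in scope: NLP pipelines over the de-identified text, web front ends,
consent-to-contact workflows, and binary document text extraction (an
extractor registry exists; handlers for office formats are deployment
configuration).
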