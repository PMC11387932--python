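# Methods

This note documents the data model, the checks, the mapping rules, and the
deliberate design choices behind them, in the order a curator meets them.

## The table dialect

Tables are UTF-8 TSV with LF line endings, a mandatory header row, a tab
separator, a trailing newline, and *no* quoting or escaping: tabs and
newlines are forbidden inside cells and rejected at serialisation time.
The payoff is byte-stability — `write(read(x)) == x` for every conforming
file — which keeps version-control diffs of curated tables minimal and
makes "did anything change?" a byte comparison.  The cost, accepted
deliberately, is that cell values cannot contain tabs or newlines; curated
metadata never needs them.

Line numbers throughout the toolkit are 1-based counting the header as
line 1, so the first data row is line 2 — what a user sees in a text
editor, and what `awk NR` counts.

Missing data is the token `unknown`, never an empty cell, in
enum/categorical columns that permit it.  Numeric columns accept `unknown`
only where their spec flags it (e.g. `sample_age`), so a blank or
`unknown` read count is an error rather than silently unparseable.

## Schemas as data

Column contracts are shipped as JSON documents under
`src/amdir/resources/schemas/`, one per (dataset kind, table type), with
JSON enum vocabularies under `resources/enums/`.  A column spec carries a
1-based position, a required flag, a value kind (free text, integer,
number, DOI, accession/URL/md5/byte-size list, or enum), an optional
vocabulary reference, and a missing-token flag.  Positions must form a
contiguous 1..N permutation, and dangling vocabulary references are fatal
at load time.  New columns therefore never require code changes, and a
schema regression test pins the positions shell one-liners rely on
(`publication_year` = 2, `geo_loc_name` = 7 in host-associated samples).

The three dataset categories ship fixed directory names
(`ancientmetagenome-hostassociated`, `ancientsinglegenome-hostassociated`,
`ancientmetagenome-environmental`); the registry is a mutable mapping so a
deployment tracking a renamed upstream directory can override entries.
`geo_loc_name` is free text in the shipped schemas rather than a country
vocabulary; validation and filtering do not depend on it being enum-typed.

Release assets are named `<dir_name>_<table_type>_<tag>.tsv` with tags of
the form `v<YY>.<MM>[.<patch>]`, comparable chronologically.  Remote
retrieval is a single HTTPS GET from a configurable base URL; a local
directory source mirrors the same naming for offline work and tests.

## Validation

`validate_dataset` concatenates, in a canonical order: per-cell schema
checks on both tables, duplicate-row checks on both, DOI checks on the
samples table, and the cross-table accession checks.  Reports are sorted
by (table, line, column position) and render as TSV or aligned text with
five fields: error type, line, column, a one-sentence explanation, and a
one-sentence fix hint.  Repeated validation of identical bytes yields
identical reports.

Two structural decisions keep reports clean:

* **One error per cell.**  Within the schema pass, checks run in the order
  required/missing → type → vocabulary → token shape, and the first hit
  wins, so a single typo does not cascade.
* **One owner per cross-cutting kind.**  DOI syntax is checked only by the
  DOI check (pattern `^10\.\d{4,9}/\S+$`, case-insensitive), and accession
  shape only by the accession check (project `^PRJ[EDN][A-Z]\d+$`,
  biosample `^SAM(EA|N|D)\w?\d+$`, run `^[EDS]RR\d{6,}$` — deliberately
  simplified INSDC namespaces kept as module config so they can evolve).
  The per-cell schema pass leaves those kinds alone.  Without this, one
  mangled DOI would surface as both a schema violation and an invalid DOI,
  and the fixture-oracle identity ("k planted defects ⇒ exactly k errors")
  could not hold.

Relationship checks use a fixed linkage rule: a library links to its
sample by archive sample accession when that column exists, else by exact
sample-name match.  A library matching no sample is an orphan (the
classic upload error of depositing every library under its own fresh
sample accession); a linked library whose project accession shares no
token with its sample's project accession is a mismatch.  Cells already
flagged as malformed are excluded from the relationship checks — again,
one defect, one error.  A run accession seen on more than one library row
is flagged on each later row.

DOI checking is offline and purely syntactic by default, so CI needs no
network; online resolution (HEAD against doi.org) is opt-in, and a network
failure there degrades to a warning, never to an invalid-DOI verdict.

## ENA autofill

The ENA portal API's `filereport` endpoint returns, per run, the study /
sample / run accessions, library name, instrument, layout, strategy, read
count, and semicolon-separated FASTQ URLs / md5s / sizes.  The client
requests an explicit field list (module config, not contract) and parses
the TSV response into run records with parallel, equal-length file lists.

Drafting maps archive-derivable columns directly and sets everything the
archive cannot know — construction method, indexing polymerase, UDG
pretreatment, plus the publication columns — to `unknown`, returning that
list so a submitter knows exactly what is left.  Drafts therefore pass
schema validation except in the declared unfilled columns.  Multiple
accessions concatenate in input order with run-accession de-duplication.

Network access lives behind a transport object: `recorded` mode replays
`<accession>.tsv` files byte-for-byte and never opens a connection (every
test uses it; a test asserts this with a blocking stub); `live` mode does
HTTPS GETs with 3 attempts and exponential backoff on 5xx responses.

## Filtering and joining

Filter semantics mirror a spreadsheet-style column menu: within one
column, predicate clauses chain left-to-right through explicit AND/OR
connectives; across columns, AND.  There is no parenthesised grammar —
the chosen semantics are documented and tested rather than guessed, and
the brute-force row-scan oracle in the tests is the reference.  Numeric
operators parse the cell as a number; `unknown` (or any unparseable cell)
never satisfies them.  Equality and containment are case-sensitive string
operations.  The empty expression selects all rows, and filtering is
idempotent.

A tiny expression syntax (`geo_loc_name=Spain & publication_year>=2020`,
operators `= != >= <= > < ~`) serves the CLI `filter` subcommand.  The
worked example reproduces the shell filter
`awk -F "\t" 'NR==1 || $2 >= 2020 && $7 == "Spain"'` exactly.

Joins return the library rows whose linkage key (same rule as validation)
matches a retained sample, preserving library order; selection summaries
report row count, run count, and the exact byte total of all files, which
equals the download-script manifest total by construction.

## Converters

**Download scripts** are frozen POSIX templates — `#!/usr/bin/env bash`,
`set -euo pipefail`, one `curl -L -o '<file>' '<url>'` (or `wget -O`) per
FASTQ file in row-then-list order, then a single `md5sum -c` here-document
covering every file exactly once.  Local filenames are URL basenames.  A
golden-file test pins the template; generation is deterministic, and
converting a pre-filtered libraries table is byte-identical to filtering
then converting.

**nf-core/eager sheets** target the 2.x input contract with the fixed
column order Sample_Name, Library_ID, Lane, Colour_Chemistry, SeqType,
Organism, Strandedness, UDG_Treatment, R1, R2, BAM.  Mappings: PAIRED →
PE with R1/R2 from the first two URLs, SINGLE → SE with R2 = NA; UDG
none/half/full pass through; colour chemistry from a substring lookup
(NextSeq/NovaSeq → 2; HiSeq/MiSeq/Genome Analyzer → 4), user-extendable
per call because instrument naming drifts — an unlisted model is a hard
error suggesting the override rather than a silent guess.  Lanes number
sequentially per sample in library order starting at 1, since archives do
not expose lane structure.  R1/R2 reference the archive URLs verbatim so
the sheet pairs with the download script; a flag switches to local
basenames.  Two conservative defaults, each with a logged warning:
unknown UDG treatment maps to `none` (wrongly trimming an untreated
library destroys real sequence; wrongly *not* trimming is recoverable),
and unknown strand type maps to `double` (the overwhelmingly more common
construction).  The sheet is explicitly a template requiring review,
never guaranteed runnable.

**Bibliographies** emit one BibTeX entry per distinct publication DOI,
sorted by key (the DOI with non-key characters replaced).  Offline mode
(default) writes minimal `@misc` entries with doi and url fields; online
mode fills entries via DOI content negotiation and degrades per-DOI to the
minimal entry on failure.

**Merging** appends new rows after existing ones, requires identical
headers and individually valid inputs, and refuses any new row whose key
tuple already exists, naming the offending keys.  Key columns are
`sample_name` (samples) and `library_name` (libraries): human-facing
identifiers that are independent of the accession checks, so a duplicate
key is exactly one report line.

## The fixture generator

The generator emulates the directory's structure, not its content: samples
grouped into projects of 1–3 (shared publication year, synthetic DOI,
project accession), 1–3 libraries per sample by default, realistic enum
draws (60% paired-end; 15% single-stranded; UDG treatment none/none/half/
full/unknown with equal weight; instruments drawn from the shipped
vocabulary), valid INSDC-shaped accessions, parallel URL/md5/size lists,
and per-project run reports consistent with the library rows.  Defaults
fix the walkthrough's study conditions: publication years span 2015–2024
and 25% of samples carry `geo_loc_name` "Spain", so a published-since-2020
Spanish subset is always non-empty at moderate n.  Synthetic DOIs use the
reserved-looking prefix `10.99999/…` — syntactically valid but
unresolvable, so an accidental online check cannot pass; URLs use the
reserved `.invalid` TLD for the same reason.  A single explicitly threaded
`random.Random(seed)` drives everything: no global state, identical seed ⇒
identical bytes.

What the generator does **not** emulate — free-prose metadata, archive
field drift, mixed-archive accessions (SRR/DRR), multi-run libraries,
non-UTF-8 mojibake — bounds what passing tests show: the validator is
exact on the modelled error classes, not certified against arbitrary
real-world files.

`corrupt_dataset` plants the eight row-scoped error kinds (the two
table-level kinds, header mismatch and structural breakage, cannot be
expressed as cell edits): non-integer read counts, out-of-vocabulary
treatments, duplicated sample keys, duplicated run accessions, mangled
DOIs, malformed run accessions, fresh mismatching project accessions, and
fresh orphaned sample accessions.  Each mutation touches distinct cells,
reserves the neighbouring cells whose reuse could mask or compound it
(e.g. both ends of a duplicated accession pair, and the project/sample
accession pair of a mismatch or orphan row), and is recorded in a
manifest.  The oracle identity — validation of a corrupted bundle reports
exactly the manifest on (table, line, column, error type) — is asserted
over 20 seeds in the acceptance tests and recomputed by
`scripts/acceptance.py`.

## Problem sizes and numerical choices

Tests and the acceptance script run on generated datasets of 10–200
samples (up to one 1000-sample validity check), sizes at which every
oracle (quadratic duplicate scan, nested-loop join, flat summation) is
exact and the whole suite completes in seconds; the behaviours checked are
size-independent invariants, so larger tables add runtime, not coverage.
Byte totals use exact integer arithmetic; the human-readable size uses
binary (1024) units to one decimal.  Ties never arise: ordering is always
the input's own row order.

## Known limitations

* The live ENA transport and online DOI/BibTeX resolution are exercised
  only through their recorded/offline counterparts in tests.
* Accession patterns are simplified INSDC namespaces; exotic historical
  accessions may need the configurable patterns widened.
* The release-census acceptance tests require one small download of the
  pinned v24.03 release and fail fast when offline.
* Converters cover curl/wget scripts, nf-core/eager 2.x sheets and
  BibTeX; other pipelines are an extension point, not implemented.
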