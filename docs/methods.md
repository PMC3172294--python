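# Methods

## The problem and the pipeline

MIxS checklists (MIGS, MIMS, MIMARKS and their environmental packages)
specify which contextual data (CD) should accompany a sequence submission
to the INSDC archives. `mixsfuse` merges such CD into (Multi)FASTA files in
the two channels the NCBI submission tools consume:

1. **FASTA definition-line qualifiers** — the subset of checklist fields
   that are recognised GenBank source modifiers is appended to each header
   as `[name=value]` tokens, the convention Sequin and tbl2asn parse.
2. **Structured comments** — every remaining field goes into a
   tab-delimited `.cmt` block framed by `StructuredCommentPrefix` /
   `StructuredCommentSuffix` lines, loadable in Sequin or mergeable with
   tbl2asn.

The pipeline for one run is: validate the FASTA → resolve the submission
scenario from (record count, CD-set count) → assign sequence-ID ranges →
validate every CD set against the checklist → stream-rewrite the FASTA
headers → emit one `.cmt` per CD set → ZIP the comment files when there is
more than one → write a manifest. Any failure anywhere aborts the run with
no partial outputs (everything is staged in a temporary directory and
published only on success).

## Streaming FASTA parser

The parser is event-driven: it reads the input in fixed-size chunks
(default 64 KiB) and emits `record_start`, `sequence_chunk`, `record_end`
and `file_end` events to a handler. Its memory contract is that no event
payload exceeds the chunk size and only one header line is buffered at a
time, so memory use is independent of file size; the test suite asserts
this with a probe handler, including on a ~100 MB multi-contig file (the
size used for the scalability smoke run; 200 contigs).

Content problems never raise — they are collected as coded violations
(`NO_HEADER`, `EMPTY_ID`, `DUPLICATE_ID`, `BAD_CHAR` with record ordinal
and residue offset, `EMPTY_SEQUENCE`, `EMPTY_FILE`) in a validation report
whose `ok` flag is true exactly when the violation list is empty. Blank
lines inside a file are tolerated and recorded in a separate warning list,
so they do not fail validation. I/O errors raise normally.

Numerical/representation choices: the record id is the first
whitespace-delimited token after `>` (INSDC convention) and a header whose
first character is whitespace has an *empty* id; the permitted alphabet is
the IUPAC nucleotide set including ambiguity codes, `-` and `.`,
case-insensitive, switchable to amino acids; LF and CRLF line endings are
both accepted (a CR split across a chunk boundary is carried over, and an
over-long carried segment is re-sliced so the payload bound stays exact);
duplicate ids are a hard error because range addressing requires unique
ids. The writer wraps at 70 columns by default (0 disables wrapping);
wrapping is presentation only — residue content is preserved byte-exactly,
which the tests check by concatenation.

## Checklist registry

Checklist definitions ship as a versioned, human-editable YAML file
(`src/mixsfuse/data/mixs_registry.yaml`) validated structurally at load: a
curated subset of the 2011-era MIxS field lists covering seven report types
(`migs_ba`, `migs_eu`, `migs_vi`, `migs_org`, `mims`, `mimarks_s`,
`mimarks_c`) and seven environmental packages (water, sediment, soil, air,
host-associated, microbial mat/biofilm, miscellaneous). A registry file
rather than a database or web service makes standard updates a data
change. The bundled lists are best-effort, not exhaustive, and the
requirement flags (mandatory/conditional/optional) mirror common
submission practice; `conditional` is treated as optional during
validation because condition evaluation is out of scope.

Each parameter carries full name, definition, expected value, a syntax
rule, an example, a requirement level and a destination
(`header_qualifier` or `structured_comment`). Syntax rules are either
named (`latlon` — decimal degrees with hemisphere letters, up to 8
decimals; `date` — ISO 8601 at year/month/day precision or `DD-Mmm-YYYY`;
`unitful` — number plus unit token; `numeric`; `integer`; `freetext`), an
enumeration, or an inline regular expression. The registry is
self-consistent by construction and by test: every parameter's example
must satisfy its own rule.

`compose_parameter_set(report_type, package)` returns the ordered union —
report-type parameters first, duplicates collapsed to their first
occurrence — and caches the result per pair; `parameter_info` lookups are
cached too, with near-miss suggestions on unknown names.

## CD sets, ranges and scenarios

A CD set binds one (report type, package) pair to a value mapping and
optionally to a contiguous range of sequence ids (`first_sequence_id` ..
`last_sequence_id` in file order); absent bounds mean "all sequences".
Scenario resolution is a total function on its valid domain: (1, 1) →
one-to-one, (n>1, 1) → one-to-many, (n>1, m>1) → many-to-many; several CD
sets on a single-sequence file is an error.

Ranges are positional, not lexicographic. Range assignment must be a total
partition: inverted ranges, overlaps, uncovered ids and unknown bound ids
each raise a distinct error (`RANGE_INVERTED`, `RANGE_OVERLAP`,
`RANGE_GAP`, `RANGE_UNKNOWN_ID`). Treating gaps as errors rather than
warnings is a deliberate design choice — silently dropping sequences from
a submission would corrupt it; whether overlapping or partial annotation
should ever be allowed was genuinely open, and strictness won.

The MIxS→INSDC qualifier map ships as config
(`src/mixsfuse/data/qualifier_map.yaml`; defaults: `lat_lon`,
`collection_date`, `geo_loc_name`→`country`, `isolation_source`, `host`,
`strain`). Its domain defines the header-destined fields; a header-destined
field missing from the map is a configuration error. The split is
conservative: header qualifiers plus the comment remainder reproduce the
CD values exactly — no field lost, none duplicated (tested by complement).

## Outputs

Enrichment appends one `[name=value]` token per qualifier, in registry
order, after the original description. Input headers that already contain
such a token abort with `ALREADY_ENRICHED` — re-running fusion on its own
output is refused rather than double-annotated. Structured comment files
use the MIxS short names by default (full names via `--field-names full`);
the prefix defaults to the checklist family plus `-Data` (e.g.
`MIGS-Data`, `MIMARKS-Data`), matching structured-comment practice of the
Sequin/tbl2asn era. Tabs inside values would break the format and are
replaced by spaces with a warning. A CD set with no comment-destined
values is refused (`EMPTY_COMMENT`). The ZIP archive is created only when
more than one CD set is involved; single-set runs emit a bare `.cmt`.

CSV templates carry five reserved columns (`label`, `first_sequence_id`,
`last_sequence_id`, `report_type`, `package`) followed by the composed
checklist columns; one row per CD set, so a single file describes an
n-to-m run. Export always writes the canonical dialect (comma, RFC 4180
quoting, UTF-8, LF) making export→import→export byte-stable; import also
accepts CRLF and semicolon-delimited files from locale-quirky spreadsheet
software. Rows with values but no label are auto-labelled `set_001`, … with
a warning; labels become `.cmt` filenames and are sanitised to
`[A-Za-z0-9_-]`.

## Synthetic fixtures

`generate_fixture(scenario, seed, out_dir)` emulates the three submission
scenarios with fully deterministic outputs per seed:

* `single` — one 16S rRNA-like record (1400–1550 nt) with one
  MIMARKS-survey + water CD set (a coastal seawater survey isolate);
* `genome` — a multi-contig draft genome (default 25 contigs, 500 kb
  total, both configurable) with one MIGS-ba + sediment CD set covering
  all contigs;
* `clonelib` — 99 clone-library 16S records (750–900 nt) in four
  contiguous subgroups with distinct MIMARKS-survey + sediment CD sets,
  delivered as a filled CSV template. The record and subgroup counts are
  the study conditions of this scenario and do not vary with the seed;
  the seed varies residues and the partition cut points.

Residues are uniform random nucleotides and CD values are the registry's
own example strings (hence checklist-valid), with per-subgroup depth and
collection date varied so the four CD sets are distinct. The fixtures
emulate the *structure* of real submissions, not their biology: there is
no phylogenetic signal, no chimeras, no quality artefacts, and the
metadata is internally consistent by construction. Passing tests therefore
demonstrate correctness of parsing, partitioning, validation and fusion
mechanics — not robustness to semantically inconsistent real-world
metadata, which the checklist validator only catches at the syntax level.

## Verification strategy

Independent oracles back every non-trivial path: Bio.SeqIO as the naive
whole-file parser the streaming parser must agree with (randomised files
up to ~1 MB); a brute-force per-id membership check for range partitions
(random partitions of up to 1,000 ids); a regex-based modifier-token
reader and a line-splitting `.cmt` reader for the two output formats; and
set-union recomputation for checklist composition. Property tests are
seeded/derandomised for reproducibility. The problem sizes used in the
default suite (10,000 records for the bounded-memory check, ~1 MB oracle
files, a 100 MB scalability smoke) were chosen to exercise the streaming
machinery while keeping the suite fast.

## Known limitations

* The bundled registry is a curated subset of MIxS 2011-era fields, and
  its mandatory/optional flags are best-effort; submissions to a specific
  archive may require fields it does not list.
* `conditional` requirements are not evaluated.
* Date validation is calendar-light (month 1–12, day 1–31); February 31
  passes.
* The tool prepares inputs for Sequin/tbl2asn; it does not run them, build
  `.sqn` files, or submit anywhere.
* Non-contiguous subgroup annotation is unsupported by design (ranges are
  contiguous runs in file order).

## CLI exit codes

0 success · 1 unexpected error · 2 usage · 3 FASTA validation ·
4 scenario/range · 5 CD validation · 6 template · 7 registry/qualifier-map ·
8 already-enriched/empty-comment · 10 I/O.
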