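# mixsfuse

Sequence data submitted to the INSDC archives (DDBJ / ENA / GenBank) is
routinely stripped of its context: where the sample came from, when it was
taken, what the habitat was, how the DNA was processed. The Genomic
Standards Consortium's MIxS checklists (MIGS for genomes, MIMS for
metagenomes, MIMARKS for marker-gene surveys, plus habitat-specific
*environmental packages*) define the minimum contextual data (CD) that
should travel with every sequence — but filling them in and getting them
into a submission is tedious.

`mixsfuse` fuses MIxS-compliant contextual data directly into (Multi)FASTA
files, producing submission-ready outputs for the NCBI preparation tools
Sequin and tbl2asn:

* an **enriched FASTA** whose definition lines carry `[name=value]`
  source-modifier qualifiers (`lat_lon`, `collection_date`, `country`, …),
* one tab-delimited **structured comment file** (`.cmt`) per CD set, holding
  every checklist field that is not a GenBank qualifier,
* a **ZIP archive** bundling the comment files when several CD sets apply,
* a JSON **manifest** describing the run.

Three submission scenarios are supported: a single sequence with one CD set
(1-to-1), a MultiFASTA file with one CD set for all records (1-to-m), and a
MultiFASTA file whose contiguous subgroups each get their own CD set
(n-to-m), addressed by first/last sequence ID ranges. The FASTA layer is an
event-driven streaming parser with a bounded-memory contract (at most one
chunk plus one header in flight), so files with millions of records pass
through in constant memory.

It is a tool for anyone preparing microbial genome, metagenome or amplicon
submissions who wants the metadata to survive the trip.

## Worked example: a 99-clone 16S library in four subgroups

Generate a synthetic clone library (99 16S rRNA-like records, four
contiguous subgroups with distinct CD sets on the MIMARKS-survey checklist
and the sediment package), then fuse:

```bash
mixsfuse fixture clonelib --seed 42 -o fix/
mixsfuse fuse fix/clonelib.fasta --cd fix/clonelib_cd.csv -o out/
```

The fuse command prints the manifest:

```json
{
  "scenario": "many_to_many",
  "enriched_fasta": "out/clonelib.enriched.fasta",
  "comment_files": [
    {
      "label": "subgroup_1",
      "path": "out/subgroup_1.cmt"
    },
    {
      "label": "subgroup_2",
      "path": "out/subgroup_2.cmt"
    },
    {
      "label": "subgroup_3",
      "path": "out/subgroup_3.cmt"
    },
    {
      "label": "subgroup_4",
      "path": "out/subgroup_4.cmt"
    }
  ],
  "archive": "out/structured_comments.zip",
  "counts": {
    "records_read": 99,
    "records_enriched": 99,
    "cd_sets_applied": 4
  }
}
```

All 99 records were read and all 99 headers enriched; each of the four CD
sets produced one structured comment file, packaged together in one ZIP.
The first enriched header looks like:

```
>clone_001 16S rRNA gene clone [lat_lon=38.98 N 77.11 W] [country=Germany: Sylt, Wadden Sea] [collection_date=2010-03-15] [isolation_source=coastal sea water]
```

and the comment files start with the `StructuredCommentPrefix` line Sequin's
"Advanced Table Readers" option expects:

```
StructuredCommentPrefix	MIMARKS-Data
investigation_type	mimarks-survey
project_name	Wadden Sea coastal water diversity survey
...
StructuredCommentSuffix	MIMARKS-Data
```

Other useful commands: `mixsfuse validate` (streaming FASTA validation),
`mixsfuse registry list` / `registry info lat_lon` (checklist metadata),
`mixsfuse template-export mimarks_s water -o t.csv` and `template-import`
(the offline CSV metadata loop). Exit codes are one per error class; see
`mixsfuse.cli.EXIT_CODES` and `docs/methods.md`.

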