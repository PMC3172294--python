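"""Fuse contextual data with FASTA files into submission-ready outputs.

Produces, for one run:

* an enriched FASTA whose definition lines carry ``[name=value]``
  source-modifier tokens in the convention understood by Sequin/tbl2asn,
* one tab-delimited structured-comment file (``.cmt``) per CD set, framed by
  ``StructuredCommentPrefix`` / ``StructuredCommentSuffix`` lines,
* for multi-CD-set runs, a ZIP archive bundling the comment files,
* a manifest describing every emitted file.

Output is all-or-nothing: everything is staged in a temporary directory next
to the destination and only published once the whole run has succeeded, so a
failed run never leaves partial submission files behind.
"""

from __future__ import annotations

import json
import shutil
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import fasta_stream
from .cd_model import (
    CDElement,
    CDFastaHeader,
    RangeAssignment,
    assign_ranges,
    comment_values,
    derive_header_qualifiers,
    resolve_scenario,
    validate_cd_set,
)
from .checklist_model import Registry, load_qualifier_map
from .errors import (
    AlreadyEnrichedError,
    CDValidationError,
    EmptyCommentError,
    FastaError,
    RangeError,
)
from .fasta_stream import ParseEvent, ParseHandler, parse_fasta, validate_fasta

__all__ = [
    "StructuredCommentBlock",
    "FusionManifest",
    "enrich_headers",
    "emit_structured_comment",
    "fuse",
]

import re

# A bracketed name=value token anywhere in a description marks a header that
# has been enriched before (or hand-annotated); refusing it prevents silent
# double annotation.
_MODIFIER_TOKEN_RE = re.compile(r"\[[^\s=\]]+=[^\]]*\]")

COMMENT_PREFIX_KEY = "StructuredCommentPrefix"
COMMENT_SUFFIX_KEY = "StructuredCommentSuffix"


@dataclass
class StructuredCommentBlock:
    """One structured comment: a prefix name plus ordered (field, value) rows."""

    prefix_name: str
    rows: list[tuple[str, str]]

    def to_text(self) -> str:
        lines = [f"{COMMENT_PREFIX_KEY}\t{self.prefix_name}"]
        lines += [f"{name}\t{value}" for name, value in self.rows]
        lines.append(f"{COMMENT_SUFFIX_KEY}\t{self.prefix_name}")
        return "\n".join(lines) + "\n"


@dataclass
class FusionManifest:
    """Description of all files emitted by one fusion run."""

    enriched_fasta: Path
    comment_files: list[tuple[str, Path]]
    archive: Path | None
    records_read: int
    records_enriched: int
    cd_sets_applied: int
    scenario: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "enriched_fasta": str(self.enriched_fasta),
                "comment_files": [
                    {"label": label, "path": str(path)} for label, path in self.comment_files
                ],
                "archive": str(self.archive) if self.archive else None,
                "counts": {
                    "records_read": self.records_read,
                    "records_enriched": self.records_enriched,
                    "cd_sets_applied": self.cd_sets_applied,
                },
            },
            indent=2,
        )


class _EnrichingHandler(ParseHandler):
    """Streams records to a sink, rewriting each definition line."""

    def __init__(self, sink, by_id: dict[str, str], headers: dict[str, CDFastaHeader], wrap: int):
        self.sink = sink
        self.by_id = by_id
        self.headers = headers
        self.wrap = wrap
        self.count = 0
        self._col = 0

    def record_start(self, event: ParseEvent) -> None:
        rid, desc, _ordinal = event.payload
        if _MODIFIER_TOKEN_RE.search(desc):
            raise AlreadyEnrichedError(
                f"record {rid!r} already carries a [name=value] token in its header"
            )
        label = self.by_id.get(rid)
        if label is None:
            raise RangeError("RANGE_GAP", f"record {rid!r} is not covered by any CD set")
        tokens = self.headers[label].format_tokens()
        header = rid
        if desc:
            header += f" {desc}"
        if tokens:
            header += f" {tokens}"
        self.sink.write(f">{header}\n")
        self._col = 0

    def sequence_chunk(self, event: ParseEvent) -> None:
        seg = event.payload
        if not self.wrap:
            self.sink.write(seg)
            return
        pos = 0
        while pos < len(seg):
            room = self.wrap - self._col
            piece = seg[pos : pos + room]
            self.sink.write(piece)
            pos += len(piece)
            self._col += len(piece)
            if self._col == self.wrap:
                self.sink.write("\n")
                self._col = 0

    def record_end(self, event: ParseEvent) -> None:
        if self._col or not self.wrap:
            self.sink.write("\n")
            self._col = 0
        self.count += 1


def enrich_headers(
    fasta_in,
    assignment: RangeAssignment,
    headers: dict[str, CDFastaHeader],
    fasta_out,
    *,
    wrap: int = 70,
    chunk_size: int = fasta_stream.DEFAULT_CHUNK_SIZE,
) -> int:
    """Stream *fasta_in* to *fasta_out*, appending qualifier tokens to headers.

    Residue content passes through byte-identically (re-wrapped at *wrap*
    columns; 0 preserves no wrapping). Returns the number of records
    enriched.  Expects a pre-validated input; headers already carrying
    modifier tokens or ids outside the assignment abort the run.
    """
    own = isinstance(fasta_out, (str, Path))
    sink = open(fasta_out, "w", encoding="latin-1", newline="") if own else fasta_out
    try:
        handler = _EnrichingHandler(sink, assignment.by_id, headers, wrap)
        parse_fasta(fasta_in, handler, chunk_size=chunk_size)
        return handler.count
    finally:
        if own:
            sink.close()


def default_prefix_name(registry: Registry, report_type: str) -> str:
    """Structured-comment prefix, e.g. 'MIGS-Data' for any MIGS variant."""
    display = registry.report_type(report_type).display_name
    return display.split()[0] + "-Data"


def emit_structured_comment(
    cd: CDElement,
    registry: Registry,
    sink,
    *,
    prefix_name: str | None = None,
    field_names: str = "short",
) -> StructuredCommentBlock:
    """Write one CD set as a tab-delimited structured-comment file.

    Layout: a ``StructuredCommentPrefix`` line, one ``name<TAB>value`` row per
    comment-destined field in registry order, and a matching suffix line.
    ``field_names`` selects ``short`` (MIxS short_name, default) or ``full``
    names for the rows.  Tabs inside values are the delimiter, so they are
    replaced by single spaces with a warning.  A CD set with no
    comment-destined values is refused.
    """
    pairs = comment_values(cd, registry)
    if not pairs:
        raise EmptyCommentError(
            f"CD set {cd.label!r} has no comment-destined values; nothing to emit"
        )
    if prefix_name is None:
        prefix_name = default_prefix_name(registry, cd.report_type)
    rows: list[tuple[str, str]] = []
    for short_name, value in pairs:
        name = (
            registry.parameter_info(short_name).full_name
            if field_names == "full"
            else short_name
        )
        if "\t" in value or "\t" in name:
            warnings.warn(
                f"tab character in {short_name!r} replaced by space", stacklevel=2
            )
            value = value.replace("\t", " ")
            name = name.replace("\t", " ")
        rows.append((name, value))
    block = StructuredCommentBlock(prefix_name, rows)
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        fh.write(block.to_text())
    finally:
        if own:
            fh.close()
    return block


def fuse(
    fasta_in: str | Path,
    cd_sets: list[CDElement],
    registry: Registry,
    out_dir: str | Path,
    *,
    qualifier_map: dict[str, str] | None = None,
    wrap: int = 70,
    prefix_name: str | None = None,
    field_names: str = "short",
    strict: bool = True,
    chunk_size: int = fasta_stream.DEFAULT_CHUNK_SIZE,
) -> FusionManifest:
    """Run the full fusion workflow for one FASTA file and its CD sets.

    Validates the FASTA and every CD set, resolves the submission scenario,
    assigns sequence-ID ranges, then writes the enriched FASTA, the
    structured-comment file(s) and — when more than one CD set is involved —
    a ZIP archive bundling them.  With ``strict=False`` checklist violations
    are reported as warnings instead of aborting.

    All outputs are staged in a temporary directory and published to
    *out_dir* only on success.
    """
    fasta_in = Path(fasta_in)
    out_dir = Path(out_dir)
    if qualifier_map is None:
        qualifier_map = load_qualifier_map()

    report = validate_fasta(fasta_in, chunk_size=chunk_size)
    if not report.ok:
        raise FastaError(report)

    scenario = resolve_scenario(report.record_count, len(cd_sets))
    assignment = assign_ranges(cd_sets, report.ids)

    all_violations = []
    for cd in cd_sets:
        for v in validate_cd_set(cd, registry):
            all_violations.append(v)
    if all_violations:
        if strict:
            raise CDValidationError(all_violations)
        for v in all_violations:
            warnings.warn(f"{v.code}: {v.message}", stacklevel=2)

    headers = {
        cd.label: derive_header_qualifiers(cd, registry, qualifier_map) for cd in cd_sets
    }

    stage_parent = out_dir.parent if out_dir.parent.is_dir() else Path(".")
    stage = Path(tempfile.mkdtemp(prefix=".mixsfuse-", dir=stage_parent))
    try:
        enriched_name = fasta_in.stem + ".enriched.fasta"
        enriched_path = stage / enriched_name
        count = enrich_headers(
            fasta_in, assignment, headers, enriched_path, wrap=wrap, chunk_size=chunk_size
        )

        comment_names: list[tuple[str, str]] = []
        for cd in cd_sets:
            cmt_name = f"{cd.label}.cmt"
            emit_structured_comment(
                cd,
                registry,
                stage / cmt_name,
                prefix_name=prefix_name,
                field_names=field_names,
            )
            comment_names.append((cd.label, cmt_name))

        archive_name: str | None = None
        if len(cd_sets) > 1:
            archive_name = "structured_comments.zip"
            with zipfile.ZipFile(
                stage / archive_name, "w", compression=zipfile.ZIP_DEFLATED
            ) as zf:
                for _label, cmt_name in comment_names:
                    zf.write(stage / cmt_name, arcname=cmt_name)

        manifest = FusionManifest(
            enriched_fasta=out_dir / enriched_name,
            comment_files=[(label, out_dir / name) for label, name in comment_names],
            archive=out_dir / archive_name if archive_name else None,
            records_read=report.record_count,
            records_enriched=count,
            cd_sets_applied=len(cd_sets),
            scenario=scenario,
        )
        (stage / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")

        # Publish: only now does out_dir gain files.
        out_dir.mkdir(parents=True, exist_ok=True)
        for item in stage.iterdir():
            target = out_dir / item.name
            if target.exists():
                target.unlink()
            shutil.move(str(item), str(target))
    finally:
        shutil.rmtree(stage, ignore_errors=True)
    return manifest
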