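"""Event-driven, bounded-memory FASTA parsing and validation.

The parser reads the input in fixed-size chunks and emits a stream of
:class:`ParseEvent` objects to a handler.  At no point does it hold more than
one chunk of residue data plus one header line in memory, which makes it
suitable for MultiFASTA files of millions of records (metagenomes, amplicon
libraries, draft genomes) on ordinary hardware.

Event protocol for a well-formed file::

    record_start(header)  sequence_chunk(text)*  record_end(summary)
    ... repeated per record ...                  file_end(report)

All content problems are reported as :class:`Violation` entries in the
returned :class:`ValidationReport` — malformed input never raises.  I/O
failures on the underlying stream do raise (``OSError``), since they are not
properties of the FASTA content.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, TextIO

__all__ = [
    "DEFAULT_CHUNK_SIZE",
    "NUCLEOTIDE_ALPHABET",
    "AMINO_ACID_ALPHABET",
    "SequenceRecord",
    "ParseEvent",
    "Violation",
    "ValidationReport",
    "ParseHandler",
    "CollectingHandler",
    "parse_fasta",
    "validate_fasta",
    "count_and_list_ids",
    "write_fasta",
]

DEFAULT_CHUNK_SIZE = 64 * 1024

# IUPAC nucleotide codes incl. ambiguity codes, gap and unknown-position
# characters; case-insensitive.
NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVNacgturyswkmbdhvn-.")
AMINO_ACID_ALPHABET = frozenset(
    "ABCDEFGHIKLMNPQRSTUVWXYZabcdefghiklmnpqrstuvwxyz*-."
)

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "amino_acid": AMINO_ACID_ALPHABET}

# Violation codes
NO_HEADER = "NO_HEADER"
EMPTY_ID = "EMPTY_ID"
DUPLICATE_ID = "DUPLICATE_ID"
BAD_CHAR = "BAD_CHAR"
EMPTY_FILE = "EMPTY_FILE"
EMPTY_SEQUENCE = "EMPTY_SEQUENCE"
BLANK_LINE = "BLANK_LINE"  # warning-level


@dataclass
class SequenceRecord:
    """One FASTA record.

    ``id`` is the first whitespace-delimited token after ``>``; the remainder
    of the definition line is ``description``.  ``ordinal`` is the 1-based
    position of the record in its file.
    """

    id: str
    description: str
    residues: str
    ordinal: int = 1

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()


class RecordSummary(NamedTuple):
    """Payload of a ``record_end`` event: the record minus its residues."""

    id: str
    description: str
    length: int
    ordinal: int


@dataclass
class ParseEvent:
    kind: str  # record_start | sequence_chunk | record_end | file_end
    payload: object = None


class Violation(NamedTuple):
    ordinal: int  # record ordinal; 0 = file level
    code: str
    message: str


@dataclass
class ValidationReport:
    record_count: int = 0
    ids: list[str] = field(default_factory=list)
    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class ParseHandler:
    """No-op event handler; subclass and override the events of interest."""

    def record_start(self, event: ParseEvent) -> None: ...

    def sequence_chunk(self, event: ParseEvent) -> None: ...

    def record_end(self, event: ParseEvent) -> None: ...

    def file_end(self, event: ParseEvent) -> None: ...


class CollectingHandler(ParseHandler):
    """Accumulates whole records in memory — for small files and tests only."""

    def __init__(self) -> None:
        self.events: list[ParseEvent] = []
        self.records: list[SequenceRecord] = []
        self._parts: list[str] = []
        self._header: tuple[str, str, int] | None = None

    def record_start(self, event: ParseEvent) -> None:
        self.events.append(event)
        rid, desc, ordinal = event.payload
        self._header = (rid, desc, ordinal)
        self._parts = []

    def sequence_chunk(self, event: ParseEvent) -> None:
        self.events.append(event)
        self._parts.append(event.payload)

    def record_end(self, event: ParseEvent) -> None:
        self.events.append(event)
        rid, desc, ordinal = self._header
        self.records.append(SequenceRecord(rid, desc, "".join(self._parts), ordinal))

    def file_end(self, event: ParseEvent) -> None:
        self.events.append(event)


def _open_source(source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="latin-1", newline=""), True
    if isinstance(source, bytes):
        return io.StringIO(source.decode("latin-1")), True
    if not hasattr(source, "read"):
        raise TypeError(f"unreadable source: {source!r}")
    return source, False


def _read_chunk(fh, chunk_size: int) -> str:
    data = fh.read(chunk_size)
    if isinstance(data, bytes):
        data = data.decode("latin-1")
    return data


def parse_fasta(
    source,
    handler: ParseHandler | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    *,
    alphabet: str | frozenset = "nucleotide",
    strip_whitespace: bool = False,
    allow_empty_records: bool = False,
) -> ValidationReport:
    """Parse *source* as FASTA, dispatching events to *handler*.

    Parameters
    ----------
    source:
        Path, text stream or binary stream.
    handler:
        Receives the event stream; ``None`` means validate only.
    chunk_size:
        Upper bound on the payload of any single ``sequence_chunk`` event
        (and on the read granularity). Must be >= 1.
    alphabet:
        ``"nucleotide"`` (default), ``"amino_acid"`` or an explicit frozenset
        of permitted residue characters.
    strip_whitespace:
        Silently drop spaces/tabs inside sequence lines instead of flagging
        them as ``BAD_CHAR``.
    allow_empty_records:
        Tolerate records with zero residues.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    allowed = _ALPHABETS[alphabet] if isinstance(alphabet, str) else frozenset(alphabet)
    if handler is None:
        handler = ParseHandler()
    fh, close = _open_source(source)
    try:
        return _parse(fh, handler, chunk_size, allowed, strip_whitespace, allow_empty_records)
    finally:
        if close:
            fh.close()


def _parse(fh, handler, chunk_size, allowed, strip_ws, allow_empty) -> ValidationReport:
    report = ValidationReport()
    seen: set[str] = set()

    in_header = False        # accumulating a definition line
    header_parts: list[str] = []
    have_record = False      # between record_start and record_end
    at_line_start = True
    saw_leading_garbage = False
    ordinal = 0
    length = 0               # residues of current record
    cur_id = ""
    cur_desc = ""
    carry_cr = False         # chunk ended with '\r'; possible CRLF split

    def finish_header() -> None:
        nonlocal in_header, have_record, ordinal, length, cur_id, cur_desc
        text = "".join(header_parts)
        header_parts.clear()
        in_header = False
        ordinal += 1
        if not text or text[0].isspace():
            # ">" followed by whitespace: a description with no identifier
            cur_id, cur_desc = "", text.strip()
        else:
            parts = text.split(None, 1)
            cur_id = parts[0]
            cur_desc = parts[1] if len(parts) > 1 else ""
        if not cur_id:
            report.violations.append(
                Violation(ordinal, EMPTY_ID, "header line has no sequence identifier")
            )
        elif cur_id in seen:
            report.violations.append(
                Violation(ordinal, DUPLICATE_ID, f"duplicate sequence id {cur_id!r}")
            )
        else:
            seen.add(cur_id)
        report.ids.append(cur_id)
        have_record = True
        length = 0
        handler.record_start(ParseEvent("record_start", (cur_id, cur_desc, ordinal)))

    def finish_record() -> None:
        nonlocal have_record
        if not have_record:
            return
        if length == 0 and not allow_empty:
            report.violations.append(
                Violation(ordinal, EMPTY_SEQUENCE, f"record {cur_id!r} has no residues")
            )
        report.record_count += 1
        handler.record_end(
            ParseEvent("record_end", RecordSummary(cur_id, cur_desc, length, ordinal))
        )
        have_record = False

    def emit_residues(seg: str) -> None:
        nonlocal length
        if strip_ws:
            seg = seg.replace(" ", "").replace("\t", "")
        # A carried CR can make a segment one char longer than chunk_size;
        # slicing keeps the bounded-payload contract exact.
        for start in range(0, len(seg), chunk_size):
            piece = seg[start : start + chunk_size]
            if not (set(piece) <= allowed):
                for off, ch in enumerate(piece):
                    if ch not in allowed:
                        report.violations.append(
                            Violation(
                                ordinal,
                                BAD_CHAR,
                                f"character {ch!r} at residue offset {length + off} "
                                f"of record {cur_id!r} is outside the permitted alphabet",
                            )
                        )
                        break
            length += len(piece)
            handler.sequence_chunk(ParseEvent("sequence_chunk", piece))

    while True:
        chunk = _read_chunk(fh, chunk_size)
        if not chunk:
            break
        if carry_cr:
            chunk = "\r" + chunk
            carry_cr = False
        if chunk.endswith("\r"):
            chunk = chunk[:-1]
            carry_cr = True
        parts = chunk.split("\n")
        last = len(parts) - 1
        for i, part in enumerate(parts):
            ends_line = i < last
            if ends_line and part.endswith("\r"):
                part = part[:-1]
            if in_header:
                header_parts.append(part)
                if ends_line:
                    finish_header()
            elif at_line_start and part.startswith(">"):
                finish_record()
                in_header = True
                header_parts.append(part[1:])
                if ends_line:
                    finish_header()
            elif part == "" and ends_line and at_line_start:
                # A completely blank line; tolerated with a warning.
                report.warnings.append(
                    Violation(ordinal, BLANK_LINE, "blank line in FASTA body")
                )
            elif have_record:
                emit_residues(part)
            elif part:
                if not saw_leading_garbage:
                    report.violations.append(
                        Violation(0, NO_HEADER, "stream does not begin with '>'")
                    )
                    saw_leading_garbage = True
            at_line_start = ends_line or (part == "" and i == last and at_line_start)
    # EOF: a trailing '\r' acts as a line terminator.
    if in_header:
        finish_header()
    finish_record()
    if report.record_count == 0:
        report.violations.append(Violation(0, EMPTY_FILE, "no FASTA records found"))
    handler.file_end(ParseEvent("file_end", report))
    return report


def validate_fasta(source, **kwargs) -> ValidationReport:
    """Validate without consuming events; equals ``parse_fasta`` with a no-op
    handler. Never raises on malformed content."""
    return parse_fasta(source, handler=None, **kwargs)


def count_and_list_ids(source, **kwargs) -> list[str]:
    """Return record ids in file order; raises :class:`FastaError` if the
    file does not validate."""
    from .errors import FastaError

    report = validate_fasta(source, **kwargs)
    if not report.ok:
        raise FastaError(report)
    return list(report.ids)


def write_fasta(records: Iterable[SequenceRecord | tuple], sink, wrap: int = 70) -> int:
    """Write records as Pearson FASTA; ``wrap=0`` disables line wrapping.

    Returns the number of records written.
    """
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="latin-1", newline="") if own else sink
    n = 0
    try:
        for rec in records:
            if isinstance(rec, tuple):
                rec = SequenceRecord(*rec)
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.residues), wrap):
                    fh.write(rec.residues[i : i + wrap])
                    fh.write("\n")
                if not rec.residues:
                    pass
            else:
                fh.write(rec.residues)
                fh.write("\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n
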