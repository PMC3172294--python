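"""CSV template export and import — the offline metadata editing loop.

A template is one CSV document per (report type, environmental package)
pair: a header row of reserved columns followed by the composed checklist
short_names, then one row per CD set.  Users download a blank template, fill
it in a spreadsheet, and re-import it; the file doubles as a local backup
and a way to share metadata between collaborators.

Export always writes the canonical dialect (comma-delimited, RFC 4180
quoting, UTF-8, LF line endings) so that export -> import -> export is
byte-stable.  Import additionally tolerates CRLF endings and
semicolon-delimited files, which spreadsheet software in some locales
produces.
"""

from __future__ import annotations

import csv
import io
import warnings
from pathlib import Path

from .cd_model import CDElement, default_label
from .checklist_model import Registry
from .errors import TemplateError

__all__ = ["RESERVED_COLUMNS", "export_template", "export_cd_sets", "import_template"]

# Reserved columns precede the checklist columns; their names double as the
# template-format signature and must never collide with MIxS short_names.
RESERVED_COLUMNS = ("label", "first_sequence_id", "last_sequence_id", "report_type", "package")


def template_columns(registry: Registry, report_type: str, package: str) -> list[str]:
    params = registry.compose_parameter_set(report_type, package)
    return list(RESERVED_COLUMNS) + [p.short_name for p in params]


def _write_rows(rows: list[list[str]], path: str | Path) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerows(rows)
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="")


def export_template(
    registry: Registry,
    report_type: str,
    package: str,
    n_rows: int,
    path: str | Path,
) -> Path:
    """Write a blank template with *n_rows* empty CD-set rows.

    ``report_type`` and ``package`` are pre-filled in every row; all
    checklist cells are left empty for offline editing.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    columns = template_columns(registry, report_type, package)
    blank = [""] * (len(columns) - len(RESERVED_COLUMNS))
    rows = [columns]
    for _ in range(n_rows):
        rows.append(["", "", "", report_type, package] + blank)
    _write_rows(rows, path)
    return Path(path)


def export_cd_sets(registry: Registry, cd_sets: list[CDElement], path: str | Path) -> Path:
    """Write filled CD sets back to template form (canonical dialect).

    All sets must share one (report_type, package) pair so the checklist
    columns are well-defined.
    """
    if not cd_sets:
        raise ValueError("no CD sets to export")
    pair = {(cd.report_type, cd.package) for cd in cd_sets}
    if len(pair) > 1:
        raise TemplateError(
            "TEMPLATE_MALFORMED",
            f"cannot export CD sets with mixed checklist pairs: {sorted(pair)}",
        )
    report_type, package = next(iter(pair))
    columns = template_columns(registry, report_type, package)
    short_names = columns[len(RESERVED_COLUMNS):]
    rows = [columns]
    for cd in cd_sets:
        rows.append(
            [
                cd.label,
                cd.first_sequence_id or "",
                cd.last_sequence_id or "",
                cd.report_type,
                cd.package,
            ]
            + [cd.values.get(name, "") for name in short_names]
        )
    _write_rows(rows, path)
    return Path(path)


def _sniff_delimiter(sample: str) -> str:
    # Semicolon fallback for spreadsheet locales; comma is canonical.
    header = sample.splitlines()[0] if sample else ""
    if ";" in header and "," not in header:
        return ";"
    return ","


def import_template(registry: Registry, path: str | Path) -> list[CDElement]:
    """Read a filled template back into CD sets.

    One :class:`CDElement` per non-empty data row; empty cells are omitted
    from ``values``; the checklist pair is read per row.  Unknown columns and
    missing reserved columns raise :class:`TemplateError`; rows with values
    but no label are auto-labelled with a warning.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    reader = csv.reader(io.StringIO(text), delimiter=_sniff_delimiter(text))
    try:
        header = next(reader)
    except StopIteration:
        raise TemplateError("TEMPLATE_MALFORMED", f"{path}: empty template") from None
    header = [h.strip() for h in header]
    for col in RESERVED_COLUMNS:
        if col not in header:
            raise TemplateError(
                "TEMPLATE_MALFORMED", f"{path}: missing reserved column {col!r}"
            )
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise TemplateError("TEMPLATE_MALFORMED", f"{path}: duplicated column {dup!r}")

    cd_sets: list[CDElement] = []
    for row_no, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        cells = dict(zip(header, (c.strip() for c in row)))
        report_type = cells.pop("report_type", "")
        package = cells.pop("package", "")
        label = cells.pop("label", "")
        first = cells.pop("first_sequence_id", "") or None
        last = cells.pop("last_sequence_id", "") or None
        params = registry.compose_parameter_set(report_type, package)  # validates pair
        known = {p.short_name for p in params}
        values: dict[str, str] = {}
        for name, value in cells.items():
            if name not in known:
                raise TemplateError(
                    "UNKNOWN_FIELD",
                    f"{path}: row {row_no}: column {name!r} is not part of "
                    f"checklist ({report_type}, {package})",
                )
            if value:
                values[name] = value
        if not label:
            label = default_label(len(cd_sets))
            warnings.warn(
                f"{path}: row {row_no} has values but no label; using {label!r}",
                stacklevel=2,
            )
        cd_sets.append(
            CDElement(
                report_type=report_type,
                package=package,
                values=values,
                first_sequence_id=first,
                last_sequence_id=last,
                label=label,
            )
        )
    return cd_sets
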