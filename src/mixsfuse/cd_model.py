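"""Contextual-data (CD) sets and their binding to sequence-ID ranges.

A :class:`CDElement` couples one checklist report type and one environmental
package with a mapping of field values, and optionally a contiguous range of
sequence identifiers (``first_sequence_id`` .. ``last_sequence_id`` in file
order) that the set annotates.  Absent range bounds mean "all sequences".

Three submission scenarios are distinguished:

* ``one_to_one``   — a single sequence with one CD set,
* ``one_to_many``  — a MultiFASTA file annotated with one CD set,
* ``many_to_many`` — subgroups of a MultiFASTA file with distinct CD sets.

Ranges are positional: they address runs of records in file order, must not
overlap, and must jointly cover every record — silently dropping sequences
from a submission is treated as an error, not a warning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .checklist_model import (
    Registry,
    ValueViolation,
    load_qualifier_map,
    validate_value,
)
from .errors import QualifierMapError, RangeError, ScenarioError

__all__ = [
    "CDElement",
    "CDFastaHeader",
    "RangeAssignment",
    "resolve_scenario",
    "assign_ranges",
    "derive_header_qualifiers",
    "validate_cd_set",
    "sanitize_label",
    "ONE_TO_ONE",
    "ONE_TO_MANY",
    "MANY_TO_MANY",
]

ONE_TO_ONE = "one_to_one"
ONE_TO_MANY = "one_to_many"
MANY_TO_MANY = "many_to_many"

UNKNOWN_FIELD = "UNKNOWN_FIELD"

_LABEL_BAD = re.compile(r"[^A-Za-z0-9_-]+")


def sanitize_label(label: str) -> str:
    """Labels become output filenames; restrict to [A-Za-z0-9_-]."""
    clean = _LABEL_BAD.sub("_", label).strip("_")
    return clean or "set"


def default_label(index: int) -> str:
    return f"set_{index + 1:03d}"


@dataclass
class CDElement:
    """One contextual-data set, optionally bound to a sequence-ID range."""

    report_type: str
    package: str
    values: dict[str, str] = field(default_factory=dict)
    first_sequence_id: str | None = None
    last_sequence_id: str | None = None
    label: str = "set"

    def __post_init__(self) -> None:
        if (self.first_sequence_id is None) != (self.last_sequence_id is None):
            raise ValueError(
                "first_sequence_id and last_sequence_id must both be set or both absent"
            )
        self.label = sanitize_label(self.label)

    @property
    def covers_all(self) -> bool:
        return self.first_sequence_id is None


@dataclass
class CDFastaHeader:
    """Header-destined subset of a CD set, renamed to INSDC qualifiers."""

    qualifiers: dict[str, str] = field(default_factory=dict)  # insertion-ordered

    def format_tokens(self) -> str:
        return " ".join(f"[{name}={value}]" for name, value in self.qualifiers.items())


@dataclass
class RangeAssignment:
    """Total partition of sequence ids over CD-set labels."""

    by_id: dict[str, str]  # sequence id -> CD-set label
    scenario: str
    counts: dict[str, int] = field(default_factory=dict)  # label -> run length


def resolve_scenario(record_count: int, cd_set_count: int) -> str:
    """Classify a (record count, CD-set count) pair into a workflow scenario."""
    if record_count < 1 or cd_set_count < 1:
        raise ScenarioError("need at least one sequence and one CD set")
    if record_count == 1 and cd_set_count > 1:
        raise ScenarioError(
            f"{cd_set_count} CD sets cannot partition a single-sequence file"
        )
    if record_count == 1:
        return ONE_TO_ONE
    return ONE_TO_MANY if cd_set_count == 1 else MANY_TO_MANY


def assign_ranges(cd_sets: list[CDElement], ids: list[str]) -> RangeAssignment:
    """Map every sequence id to exactly one CD set.

    Each CD set claims the contiguous run of ids from its first to its last
    sequence id inclusive, in file order; a set without bounds claims the
    whole file.  Inverted or overlapping ranges, ids left unclaimed and
    unknown bound ids all raise :class:`RangeError` with a specific code.
    """
    if len(set(ids)) != len(ids):
        raise RangeError("RANGE_UNKNOWN_ID", "sequence ids are not unique")
    scenario = resolve_scenario(len(ids), len(cd_sets))
    index = {sid: i for i, sid in enumerate(ids)}
    owner: list[str | None] = [None] * len(ids)
    counts: dict[str, int] = {}
    for cd in cd_sets:
        if cd.covers_all:
            lo, hi = 0, len(ids) - 1
        else:
            for bound in (cd.first_sequence_id, cd.last_sequence_id):
                if bound not in index:
                    raise RangeError(
                        "RANGE_UNKNOWN_ID",
                        f"CD set {cd.label!r}: id {bound!r} not present in the FASTA file",
                    )
            lo, hi = index[cd.first_sequence_id], index[cd.last_sequence_id]
            if lo > hi:
                raise RangeError(
                    "RANGE_INVERTED",
                    f"CD set {cd.label!r}: first id {cd.first_sequence_id!r} occurs "
                    f"after last id {cd.last_sequence_id!r} in file order",
                )
        for pos in range(lo, hi + 1):
            if owner[pos] is not None:
                raise RangeError(
                    "RANGE_OVERLAP",
                    f"sequence {ids[pos]!r} claimed by both {owner[pos]!r} and {cd.label!r}",
                )
            owner[pos] = cd.label
        counts[cd.label] = counts.get(cd.label, 0) + (hi - lo + 1)
    orphans = [ids[i] for i, lab in enumerate(owner) if lab is None]
    if orphans:
        shown = ", ".join(repr(o) for o in orphans[:10])
        raise RangeError(
            "RANGE_GAP",
            f"{len(orphans)} sequence(s) claimed by no CD set: {shown}"
            + (", ..." if len(orphans) > 10 else ""),
        )
    return RangeAssignment(
        by_id={sid: owner[i] for i, sid in enumerate(ids)},
        scenario=scenario,
        counts=counts,
    )


def derive_header_qualifiers(
    cd: CDElement,
    registry: Registry,
    qualifier_map: dict[str, str] | None = None,
) -> CDFastaHeader:
    """Split off the header-destined values of a CD set as INSDC qualifiers.

    Header-destined parameters (destination ``header_qualifier``) are renamed
    through the MIxS->INSDC qualifier map and kept in registry order; the
    remaining values stay behind for the structured comment.  A header
    parameter missing from the map is a configuration error, not a silent
    drop.
    """
    if qualifier_map is None:
        qualifier_map = load_qualifier_map()
    params = registry.compose_parameter_set(cd.report_type, cd.package)
    qualifiers: dict[str, str] = {}
    for param in params:
        value = cd.values.get(param.short_name)
        if not value or param.destination != "header_qualifier":
            continue
        if param.short_name not in qualifier_map:
            raise QualifierMapError(
                f"header-destined parameter {param.short_name!r} has no entry in "
                "the MIxS->INSDC qualifier map"
            )
        qualifiers[qualifier_map[param.short_name]] = value
    return CDFastaHeader(qualifiers)


def comment_values(cd: CDElement, registry: Registry) -> list[tuple[str, str]]:
    """Comment-destined (short_name, value) pairs in registry order."""
    params = registry.compose_parameter_set(cd.report_type, cd.package)
    return [
        (p.short_name, cd.values[p.short_name])
        for p in params
        if p.destination == "structured_comment" and cd.values.get(p.short_name)
    ]


def validate_cd_set(cd: CDElement, registry: Registry) -> list[ValueViolation]:
    """All checklist violations for one CD set; empty list == submission-ready.

    Concatenates per-field syntax checks, MISSING_MANDATORY for absent
    mandatory fields and UNKNOWN_FIELD for values outside the composed
    parameter set.
    """
    params = registry.compose_parameter_set(cd.report_type, cd.package)
    known = {p.short_name for p in params}
    violations: list[ValueViolation] = []
    for param in params:
        violations.extend(validate_value(param, cd.values.get(param.short_name, "")))
    for name in cd.values:
        if name not in known:
            violations.append(
                ValueViolation(
                    name,
                    UNKNOWN_FIELD,
                    f"field {name!r} is not part of checklist "
                    f"({cd.report_type}, {cd.package})",
                )
            )
    return violations
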