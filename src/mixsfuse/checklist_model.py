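"""Machine-readable MIxS checklist registry.

Loads a versioned definition file describing checklist parameters, report
types (MIGS/MIMS/MIMARKS variants) and environmental packages, and exposes
lookup, composition and value validation.  The registry replaces a live
checklist database with bundled, human-editable YAML: updating to a newer
MIxS release is a data change, not a code change.

Value syntax is expressed either as a named rule (``latlon``, ``date``,
``unitful``, ``numeric``, ``integer``, ``freetext``), an enumeration
(``enum:a|b|c``) or an inline pattern (``regex:...``).  Every parameter's
``example`` must satisfy its own rule; this self-consistency is checked by
the test suite over the whole bundled registry.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml

from .errors import RegistryError, RegistryLookupError

__all__ = [
    "ChecklistParameter",
    "ReportType",
    "EnvironmentalPackage",
    "Registry",
    "load_registry",
    "default_registry_path",
    "validate_value",
    "SYNTAX_MISMATCH",
    "MISSING_MANDATORY",
]

REQUIREMENTS = frozenset({"mandatory", "conditional", "optional"})
DESTINATIONS = frozenset({"header_qualifier", "structured_comment"})

SYNTAX_MISMATCH = "SYNTAX"
MISSING_MANDATORY = "MISSING_MANDATORY"


class ValueViolation(NamedTuple):
    field: str
    code: str
    message: str


@dataclass(frozen=True)
class ChecklistParameter:
    short_name: str
    full_name: str
    definition: str
    expected_value: str
    syntax: str
    example: str
    requirement: str  # mandatory | conditional | optional
    destination: str  # header_qualifier | structured_comment


@dataclass(frozen=True)
class ReportType:
    identifier: str
    display_name: str
    parameters: tuple[ChecklistParameter, ...]


@dataclass(frozen=True)
class EnvironmentalPackage:
    name: str
    parameters: tuple[ChecklistParameter, ...]


# --- syntax rules -----------------------------------------------------------

_LATLON_RE = re.compile(r"\d{1,2}(?:\.\d{1,8})? [NS] \d{1,3}(?:\.\d{1,8})? [EW]")
_ISO_DATE_RE = re.compile(r"\d{4}(?:-\d{2}(?:-\d{2})?)?")
_DMY_DATE_RE = re.compile(
    r"\d{1,2}-(?:Jan|Feb|Mar|Apr|May|Jun|Jul|Aug|Sep|Oct|Nov|Dec)-\d{4}"
)
_UNITFUL_RE = re.compile(r"[+-]?\d+(?:\.\d+)?\s*[^\s0-9+-]\S*")
_NUMERIC_RE = re.compile(r"[+-]?\d+(?:\.\d+)?")
_INTEGER_RE = re.compile(r"\d+")


def _match_date(value: str) -> bool:
    if _ISO_DATE_RE.fullmatch(value):
        # reject impossible months/days without pulling in a calendar
        parts = value.split("-")
        if len(parts) >= 2 and not 1 <= int(parts[1]) <= 12:
            return False
        if len(parts) == 3 and not 1 <= int(parts[2]) <= 31:
            return False
        return True
    return bool(_DMY_DATE_RE.fullmatch(value))


def _rule_matches(syntax: str, value: str) -> bool:
    if syntax == "latlon":
        return bool(_LATLON_RE.fullmatch(value))
    if syntax == "date":
        return _match_date(value)
    if syntax == "unitful":
        return bool(_UNITFUL_RE.fullmatch(value))
    if syntax == "numeric":
        return bool(_NUMERIC_RE.fullmatch(value))
    if syntax == "integer":
        return bool(_INTEGER_RE.fullmatch(value))
    if syntax == "freetext":
        return bool(value.strip())
    if syntax.startswith("enum:"):
        return value in syntax[5:].split("|")
    if syntax.startswith("regex:"):
        return bool(re.fullmatch(syntax[6:], value))
    raise RegistryError(f"unknown syntax rule {syntax!r}")


def validate_value(param: ChecklistParameter, value: str) -> list[ValueViolation]:
    """Check *value* against the parameter's syntax and requirement level.

    An empty value is a ``MISSING_MANDATORY`` violation for mandatory
    parameters and no violation otherwise (conditional is treated as
    optional; condition evaluation is out of scope). Violations are data,
    never exceptions.
    """
    if value == "" or value is None:
        if param.requirement == "mandatory":
            return [
                ValueViolation(
                    param.short_name,
                    MISSING_MANDATORY,
                    f"mandatory parameter {param.short_name!r} has no value",
                )
            ]
        return []
    if not _rule_matches(param.syntax, value):
        return [
            ValueViolation(
                param.short_name,
                SYNTAX_MISMATCH,
                f"value {value!r} does not match the {param.syntax!r} rule for "
                f"{param.short_name!r} (example: {param.example!r})",
            )
        ]
    return []


# --- registry ---------------------------------------------------------------

def default_registry_path() -> Path:
    return Path(str(resources.files("mixsfuse").joinpath("data/mixs_registry.yaml")))


def default_qualifier_map_path() -> Path:
    return Path(str(resources.files("mixsfuse").joinpath("data/qualifier_map.yaml")))


def load_qualifier_map(path: str | Path | None = None) -> dict[str, str]:
    """MIxS short_name -> INSDC source-modifier name map (bundled default)."""
    p = Path(path) if path is not None else default_qualifier_map_path()
    data = yaml.safe_load(p.read_text(encoding="utf-8"))
    if not isinstance(data, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in data.items()
    ):
        raise RegistryError(f"qualifier map {p} must map names to names")
    return data


@dataclass
class Registry:
    """Loaded checklist registry with memoised lookups."""

    version: str
    provenance: str
    parameters: dict[str, ChecklistParameter]
    report_types: dict[str, ReportType]
    environmental_packages: dict[str, EnvironmentalPackage]
    source: Path | None = None
    source_read_count: int = 1  # how many times the definition file was read
    _compose_cache: dict[tuple[str, str], tuple[ChecklistParameter, ...]] = field(
        default_factory=dict, repr=False
    )
    _info_cache: dict[str, ChecklistParameter] = field(default_factory=dict, repr=False)

    def parameter_info(self, short_name: str) -> ChecklistParameter:
        """Full metadata for one parameter; cached after first lookup."""
        try:
            return self._info_cache[short_name]
        except KeyError:
            pass
        param = self.parameters.get(short_name)
        if param is None:
            near = difflib.get_close_matches(short_name, self.parameters, n=3)
            raise RegistryLookupError(f"unknown parameter {short_name!r}", near)
        self._info_cache[short_name] = param
        return param

    def report_type(self, identifier: str) -> ReportType:
        rt = self.report_types.get(identifier)
        if rt is None:
            near = difflib.get_close_matches(identifier, self.report_types, n=3)
            raise RegistryLookupError(f"unknown report type {identifier!r}", near)
        return rt

    def environmental_package(self, name: str) -> EnvironmentalPackage:
        pkg = self.environmental_packages.get(name)
        if pkg is None:
            near = difflib.get_close_matches(name, self.environmental_packages, n=3)
            raise RegistryLookupError(f"unknown environmental package {name!r}", near)
        return pkg

    def compose_parameter_set(
        self, report_type: str, package: str
    ) -> tuple[ChecklistParameter, ...]:
        """Ordered union of report-type and package parameters.

        Report-type parameters come first; duplicates (same short_name)
        collapse to their first occurrence. The result is cached per pair, so
        repeated form/template builds never re-derive it.
        """
        key = (report_type, package)
        cached = self._compose_cache.get(key)
        if cached is not None:
            return cached
        rt = self.report_type(report_type)
        pkg = self.environmental_package(package)
        seen: set[str] = set()
        combined: list[ChecklistParameter] = []
        for param in (*rt.parameters, *pkg.parameters):
            if param.short_name not in seen:
                seen.add(param.short_name)
                combined.append(param)
        result = tuple(combined)
        self._compose_cache[key] = result
        return result

    def to_document(self) -> dict:
        """Serialise back to the definition-file structure (canonical form)."""
        core = [p.short_name for p in next(iter(self.report_types.values())).parameters]
        # core = longest common prefix shared by all report types
        for rt in self.report_types.values():
            names = [p.short_name for p in rt.parameters]
            n = 0
            while n < min(len(core), len(names)) and core[n] == names[n]:
                n += 1
            core = core[:n]
        core_set = core
        return {
            "registry": {"version": self.version, "provenance": self.provenance},
            "parameters": [vars(p).copy() for p in self.parameters.values()],
            "core_parameters": list(core_set),
            "report_types": [
                {
                    "identifier": rt.identifier,
                    "display_name": rt.display_name,
                    "parameters": [
                        p.short_name for p in rt.parameters[len(core_set):]
                    ],
                }
                for rt in self.report_types.values()
            ],
            "environmental_packages": [
                {"name": pkg.name, "parameters": [p.short_name for p in pkg.parameters]}
                for pkg in self.environmental_packages.values()
            ],
        }


def _require(mapping: dict, key: str, where: str) -> object:
    if key not in mapping:
        raise RegistryError(f"{where}: missing required key {key!r}")
    return mapping[key]


def _check_registry_document(doc: object) -> dict:
    if not isinstance(doc, dict):
        raise RegistryError("registry document must be a mapping")
    for section in ("registry", "parameters", "report_types", "environmental_packages"):
        _require(doc, section, "registry document")
    return doc


def load_registry(definitions_path: str | Path | None = None) -> Registry:
    """Load a checklist registry from a YAML definition file.

    ``None`` loads the bundled MIxS-2011-era registry. Loading is idempotent:
    the same path always yields an equivalent registry. Structural problems
    raise :class:`RegistryError` naming the offending entry.
    """
    path = Path(definitions_path) if definitions_path is not None else default_registry_path()
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise RegistryError(f"cannot parse {path}: {exc}") from exc
    doc = _check_registry_document(doc)

    meta = doc["registry"]
    params: dict[str, ChecklistParameter] = {}
    for entry in doc["parameters"]:
        where = f"parameter {entry.get('short_name', '<unnamed>')!r}"
        fields = {
            k: str(_require(entry, k, where))
            for k in (
                "short_name",
                "full_name",
                "definition",
                "expected_value",
                "syntax",
                "example",
                "requirement",
                "destination",
            )
        }
        if fields["requirement"] not in REQUIREMENTS:
            raise RegistryError(f"{where}: unknown requirement {fields['requirement']!r}")
        if fields["destination"] not in DESTINATIONS:
            raise RegistryError(f"{where}: unknown destination {fields['destination']!r}")
        if fields["short_name"] in params:
            raise RegistryError(f"duplicate parameter short_name {fields['short_name']!r}")
        # fail fast on rule typos
        _rule_matches(fields["syntax"], fields["example"])
        params[fields["short_name"]] = ChecklistParameter(**fields)

    def resolve(names: list[str], where: str) -> tuple[ChecklistParameter, ...]:
        out = []
        for name in names:
            if name not in params:
                raise RegistryError(f"{where}: references unknown parameter {name!r}")
            out.append(params[name])
        return tuple(out)

    core = resolve(doc.get("core_parameters", []), "core_parameters")

    report_types: dict[str, ReportType] = {}
    for entry in doc["report_types"]:
        ident = str(_require(entry, "identifier", "report type"))
        if ident in report_types:
            raise RegistryError(f"duplicate report type {ident!r}")
        own = resolve(entry.get("parameters", []), f"report type {ident!r}")
        all_params = core + tuple(p for p in own if p not in core)
        if not all_params:
            raise RegistryError(f"report type {ident!r} has no parameters")
        report_types[ident] = ReportType(
            ident, str(_require(entry, "display_name", f"report type {ident!r}")), all_params
        )

    packages: dict[str, EnvironmentalPackage] = {}
    for entry in doc["environmental_packages"]:
        name = str(_require(entry, "name", "environmental package"))
        if name in packages:
            raise RegistryError(f"duplicate environmental package {name!r}")
        plist = resolve(entry.get("parameters", []), f"package {name!r}")
        if not plist:
            raise RegistryError(f"package {name!r} has no parameters")
        packages[name] = EnvironmentalPackage(name, plist)

    return Registry(
        version=str(meta.get("version", "unversioned")),
        provenance=str(meta.get("provenance", "")),
        parameters=params,
        report_types=report_types,
        environmental_packages=packages,
        source=path,
    )
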