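"""Exception hierarchy shared across the package.

Every error class carries a stable ``code`` string so the CLI can map error
classes to distinct exit statuses and machine-readable messages.
"""

from __future__ import annotations


class MixsFuseError(Exception):
    """Base class for all package errors."""

    code = "ERROR"


class FastaError(MixsFuseError):
    """A FASTA file failed validation; carries the full report."""

    code = "FASTA_INVALID"

    def __init__(self, report, message: str | None = None):
        self.report = report
        if message is None:
            first = report.violations[0] if report.violations else None
            message = (
                f"FASTA validation failed with {len(report.violations)} violation(s)"
                + (f"; first: {first.code} at record {first.ordinal}: {first.message}" if first else "")
            )
        super().__init__(message)


class RegistryError(MixsFuseError):
    """Malformed checklist definition file."""

    code = "REGISTRY_MALFORMED"


class RegistryLookupError(MixsFuseError, KeyError):
    """Unknown parameter, report type or package name."""

    code = "NOT_FOUND"

    def __init__(self, message: str, near_misses: list[str] | None = None):
        self.near_misses = near_misses or []
        if self.near_misses:
            message += " (did you mean: " + ", ".join(self.near_misses) + "?)"
        super().__init__(message)

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class ScenarioError(MixsFuseError):
    """Impossible record-count / CD-set-count combination."""

    code = "SCENARIO_INVALID"


class RangeError(MixsFuseError):
    """Sequence-ID range assignment failure; ``code`` names the kind."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(message)


class QualifierMapError(MixsFuseError):
    """A header-destined parameter has no INSDC qualifier mapping."""

    code = "QUALIFIER_MAP"


class CDValidationError(MixsFuseError):
    """One or more contextual-data sets failed checklist validation."""

    code = "CD_INVALID"

    def __init__(self, violations, message: str | None = None):
        self.violations = list(violations)
        if message is None:
            message = "; ".join(f"{v.code}: {v.message}" for v in self.violations[:5])
            message = f"{len(self.violations)} contextual-data violation(s): {message}"
        super().__init__(message)


class TemplateError(MixsFuseError):
    """CSV template import failure; ``code`` names the kind."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(message)


class AlreadyEnrichedError(MixsFuseError):
    """Input header already carries a [name=value] source-modifier token."""

    code = "ALREADY_ENRICHED"


class EmptyCommentError(MixsFuseError):
    """A CD set has no comment-destined values; nothing to submit."""

    code = "EMPTY_COMMENT"
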